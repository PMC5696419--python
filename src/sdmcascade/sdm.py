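"""Base suitability learners behind a uniform fit/predict contract.

Eight algorithms mirror the classic ensemble-platform lineup: a GLM
(logistic regression with stepwise AIC term selection), boosted trees
(GBM), a classification tree (CTA), a
small feed-forward network (ANN), the bespoke surface range envelope (SRE),
a hinge-feature additive spline model (MARS-style), a random forest (RF) and
a MaxEnt-style penalized logistic model on polynomial features.  Each learner
is fitted on the calibration cells of one split and scores every cell of any
predictor stack with a suitability in [0, 1].

Seeds fan out deterministically per (algorithm, split) from one master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .evaluation import EvaluationScores
from .occurrence import CalibrationSplit, OccurrenceLayer
from .predictors import PredictorStack

ALGORITHMS = ("glm", "gbm", "cta", "ann", "sre", "mars", "rf", "maxent")


def derive_seed(master_seed: int, algorithm: str, run: int) -> int:
    """Deterministic per-(algorithm, run) seed below 2**31."""
    a = ALGORITHMS.index(algorithm)
    return (master_seed * 100_003 + a * 131_071 + run * 8191) % (2**31 - 1)


# ---------------------------------------------------------------------------
# surface range envelope


@dataclass(frozen=True)
class SreEnvelope:
    """Rectilinear environmental envelope of the calibration presences.

    Bounds are the [q, 1-q] empirical quantiles of presence-cell predictor
    values; with q = 0 the envelope is the presence min/max box.
    """

    lower: np.ndarray
    upper: np.ndarray
    q: float

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("envelope lower bounds exceed upper bounds")


def fit_sre(presence_values: np.ndarray, q: float = 0.025) -> SreEnvelope:
    """Fit the envelope from a presences × predictors value matrix."""
    X = np.asarray(presence_values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 presence cells")
    if not 0 <= q < 0.5:
        raise ValueError("q must lie in [0, 0.5)")
    lower = np.quantile(X, q, axis=0)
    upper = np.quantile(X, 1.0 - q, axis=0)
    return SreEnvelope(lower=lower, upper=upper, q=q)


def predict_sre(env: SreEnvelope, X: np.ndarray) -> np.ndarray:
    """1 where every predictor lies inside its bounds (inclusive), else 0."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != env.lower.size:
        raise ValueError("predictor count does not match the envelope")
    inside = (X >= env.lower) & (X <= env.upper)
    return inside.all(axis=1).astype(float)


# ---------------------------------------------------------------------------
# learner registry


def _hinge_features(X: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Linear + paired hinge basis per predictor (MARS-style expansion)."""
    parts = [X]
    for k in range(knots.shape[0]):
        parts.append(np.maximum(X - knots[k], 0.0))
        parts.append(np.maximum(knots[k] - X, 0.0))
    return np.concatenate(parts, axis=1)


class _SklearnLearner:
    """Standardize-then-fit wrapper giving every learner one contract."""

    def __init__(self, make_model, feature_map=None):
        self._make_model = make_model
        self._feature_map = feature_map
        self._model = None
        self._mean = None
        self._sd = None
        self._fit_extra = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> None:
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Z = (X - self._mean) / self._sd
        if self._feature_map is not None:
            Z, self._fit_extra = self._feature_map(Z, None)
        self._model = self._make_model(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._model.fit(Z, y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self._mean) / self._sd
        if self._feature_map is not None:
            Z, _ = self._feature_map(Z, self._fit_extra)
        proba = self._model.predict_proba(Z)[:, 1]
        return np.clip(proba, 0.0, 1.0)


class _StepwiseGlm:
    """Logistic GLM with forward stepwise predictor selection by AIC.

    Starting from the intercept-only model, the predictor whose addition
    lowers AIC most is added until no candidate improves AIC or
    ``max_terms`` is reached.  Selection by deviance lets the model settle
    on the genuinely informative predictor among collinear alternatives and
    mirrors how classical distribution-model GLMs drop redundant variables.
    A tiny ridge (C=1e4) keeps fits finite on separable data.
    """

    def __init__(self, max_terms: int = 8):
        self.max_terms = max_terms
        self.selected: list[int] = []

    @staticmethod
    def _loglik(model, Z, y) -> float:
        p = np.clip(model.predict_proba(Z)[:, 1], 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> None:
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Z = (X - self._mean) / self._sd
        n, p = Z.shape
        prev = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        best_aic = 2.0 - 2.0 * (
            y.sum() * np.log(prev) + (n - y.sum()) * np.log(1 - prev)
        )
        self.selected, self._model = [], None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            while len(self.selected) < self.max_terms:
                best = None
                for j in range(p):
                    if j in self.selected:
                        continue
                    cols = self.selected + [j]
                    m = LogisticRegression(C=1e4, max_iter=300).fit(Z[:, cols], y)
                    aic = 2.0 * (len(cols) + 1) - 2.0 * self._loglik(m, Z[:, cols], y)
                    if best is None or aic < best[0]:
                        best = (aic, j, m)
                if best is None or best[0] >= best_aic - 1e-9:
                    break
                best_aic, j, self._model = best
                self.selected.append(j)
            if self._model is None:  # nothing beat the null model
                self._model = LogisticRegression(C=1e4, max_iter=300).fit(Z, y)
                self.selected = list(range(p))

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self._mean) / self._sd
        return np.clip(self._model.predict_proba(Z[:, self.selected])[:, 1], 0.0, 1.0)


class _SreLearner:
    def __init__(self, q: float = 0.0):
        self.q = q
        self._env = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> None:
        self._env = fit_sre(X[y.astype(bool)], q=self.q)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_sre(self._env, X)


def _mars_map(Z: np.ndarray, extra):
    if extra is None:
        extra = np.quantile(Z, [1 / 3, 2 / 3], axis=0)
    return _hinge_features(Z, extra), extra


def _maxent_map(Z: np.ndarray, extra):
    return np.concatenate([Z, Z**2], axis=1), extra


def make_learner(algorithm: str, seed: int, sre_q: float = 0.0):
    """Instantiate one of the eight registered learners."""
    if algorithm == "glm":
        return _StepwiseGlm()
    if algorithm == "gbm":
        return _SklearnLearner(lambda s: GradientBoostingClassifier(random_state=s))
    if algorithm == "cta":
        return _SklearnLearner(lambda s: DecisionTreeClassifier(random_state=s, min_samples_leaf=5))
    if algorithm == "ann":
        return _SklearnLearner(
            lambda s: MLPClassifier(
                hidden_layer_sizes=(16,), max_iter=300, random_state=s, tol=1e-3
            )
        )
    if algorithm == "sre":
        return _SreLearner(q=sre_q)
    if algorithm == "mars":
        return _SklearnLearner(
            lambda s: LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0, max_iter=200),
            feature_map=_mars_map,
        )
    if algorithm == "rf":
        return _SklearnLearner(
            lambda s: RandomForestClassifier(n_estimators=100, random_state=s, n_jobs=1)
        )
    if algorithm == "maxent":
        return _SklearnLearner(
            lambda s: LogisticRegression(C=1.0, max_iter=500),
            feature_map=_maxent_map,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# run container


@dataclass
class SdmRun:
    """One calibrated learner on one calibration split."""

    algorithm: str
    species: str
    run: int
    seed: int
    split: CalibrationSplit
    learner: object
    suitability: np.ndarray  # full-grid score field in [0, 1]
    scores: EvaluationScores | None = dataclass_field(default=None)

    def predict_stack(self, stack: PredictorStack) -> np.ndarray:
        """Score every cell of a predictor stack (any climate, same predictors)."""
        flat = self.learner.predict(stack.as_matrix())
        return flat.reshape(stack.shape)


def fit_predict_learner(
    algorithm: str,
    split: CalibrationSplit,
    layer: OccurrenceLayer,
    stack: PredictorStack,
    seed: int,
    sre_q: float = 0.0,
) -> SdmRun:
    """Fit one learner on the calibration cells and score the whole grid."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    X_all = stack.as_matrix()
    y_all = layer.binary.ravel().astype(int)
    X_cal, y_cal = X_all[split.calibration], y_all[split.calibration]
    if len(np.unique(y_cal)) < 2:
        raise ValueError("calibration data must contain both classes")

    learner = make_learner(algorithm, seed, sre_q=sre_q)
    learner.fit(X_cal, y_cal, seed)
    suit = np.asarray(learner.predict(X_all), dtype=float)
    if not np.all(np.isfinite(suit)):
        raise RuntimeError(f"{algorithm} produced non-finite suitability scores")
    return SdmRun(
        algorithm=algorithm,
        species=layer.species,
        run=split.run,
        seed=seed,
        split=split,
        learner=learner,
        suitability=suit.reshape(stack.shape),
    )
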