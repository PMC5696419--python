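"""Model evaluation: confusion-matrix metrics, AUC, thresholds, importance.

Implements the classification-accuracy toolkit of ensemble distribution
modelling: sensitivity/specificity and their relatives, the True Skill
Statistic (TSS = sens + spec - 1), Cohen's kappa, Matthews correlation, a
rank-based (Mann-Whitney) AUC, the ROC-optimal (Youden) binarization
threshold, the dual ROC/TSS run filter, and permutation variable importance
expressed as (1 - Pearson correlation) x 100.

Undefined quantities (zero denominators, single-class inputs) are returned
as NaN rather than silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvaluationScores:
    """Threshold-dependent accuracy metrics plus (optionally) AUC.

    ``ppp``/``npp`` are the positive/negative predictive values ("Predicted
    Present/Absent correctly Predicted").  Metrics with an undefined
    denominator are NaN.
    """

    sens: float
    spec: float
    ppp: float
    npp: float
    pcc: float
    tss: float
    kappa: float
    mcc: float
    auc: float = math.nan


def confusion(observed: np.ndarray, scores: np.ndarray, threshold: float) -> ConfusionMatrix:
    """Tabulate the confusion matrix at ``threshold`` (present iff score >= threshold)."""
    observed = np.asarray(observed).astype(bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if observed.size == 0:
        raise ValueError("empty input")
    if observed.shape != scores.shape:
        raise ValueError("observed and scores must have equal length")
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & observed)),
        fp=int(np.sum(pred & ~observed)),
        fn=int(np.sum(~pred & observed)),
        tn=int(np.sum(~pred & ~observed)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def scores_from_confusion(cm: ConfusionMatrix) -> EvaluationScores:
    """All threshold-dependent metrics from one confusion matrix."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    n = cm.total
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppp = _ratio(cm.tp, cm.tp + cm.fp)
    npp = _ratio(cm.tn, cm.tn + cm.fn)
    pcc = (cm.tp + cm.tn) / n

    po = pcc
    pe = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / (n * n)
    kappa = _ratio(po - pe, 1.0 - pe) if pe < 1.0 else math.nan

    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = (
        (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom) if denom > 0 else math.nan
    )
    tss = sens + spec - 1.0
    return EvaluationScores(
        sens=sens, spec=spec, ppp=ppp, npp=npp, pcc=pcc, tss=tss, kappa=kappa, mcc=mcc
    )


def auc(observed: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count half."""
    observed = np.asarray(observed).astype(bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    n_pos = int(observed.sum())
    n_neg = observed.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[observed].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def optimal_threshold(
    observed: np.ndarray, scores: np.ndarray, criterion: str = "roc"
) -> float:
    """Binarization threshold maximizing the chosen criterion.

    ``"roc"`` (and its affine equivalent ``"tss"``) maximizes sens + spec,
    the point of the ROC plot closest to perfect discrimination (Youden);
    ``"kappa"`` maximizes Cohen's kappa.  Candidates are midpoints between
    consecutive sorted unique scores plus the extremes; ties keep the lowest
    candidate.
    """
    observed = np.asarray(observed).astype(bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if observed.all() or not observed.any():
        raise ValueError("threshold selection requires both classes")
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0] - 1e-9], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1e-9]])

    def objective(th: float) -> float:
        s = scores_from_confusion(confusion(observed, scores, th))
        if criterion in ("roc", "tss", "youden"):
            return s.sens + s.spec
        if criterion == "kappa":
            return s.kappa if math.isfinite(s.kappa) else -math.inf
        raise ValueError(f"unknown criterion {criterion!r}")

    values = np.array([objective(th) for th in candidates])
    return float(candidates[int(np.argmax(values))])


# ---------------------------------------------------------------------------
# run filtering


def filter_runs(
    runs: list,
    roc_min: float = 0.85,
    tss_min: float = 0.75,
    roc_overrides: dict[str, float] | None = None,
    species: str | None = None,
) -> list:
    """Dual ROC/TSS filter selecting the runs admitted to the ensemble.

    A run passes iff its validation AUC >= the ROC minimum for its species
    AND its validation TSS >= ``tss_min``; both bounds inclusive.  Per-species
    ROC overrides tighten (or relax) the default.  An empty result is a valid
    outcome — some species simply support no trustworthy model.
    """
    roc_overrides = roc_overrides or {}
    passing = []
    for run in runs:
        sp = species if species is not None else getattr(run, "species", None)
        bar = roc_overrides.get(sp, roc_min)
        if run.scores.auc >= bar and run.scores.tss >= tss_min:
            passing.append(run)
    return passing


# ---------------------------------------------------------------------------
# permutation variable importance


@dataclass
class ImportanceTable:
    """Per-(predictor, run) permutation importances and their summaries."""

    table: pd.DataFrame  # rows: predictor, columns: run label
    standardized: bool = True
    dropped: dict[str, list[str]] = field(default_factory=dict)

    def mean(self) -> pd.Series:
        return self.table.mean(axis=1)

    def sd(self) -> pd.Series:
        return self.table.std(axis=1, ddof=1)

    def variance_across_predictors(self) -> float:
        """Spread of the mean importance across predictors (concentration index)."""
        return float(self.table.mean(axis=1).var(ddof=1))


def permutation_importance(
    predict,
    X: np.ndarray,
    predictor_ids: list[str],
    n_permutations: int = 3,
    seed: int = 0,
    standardize: bool = True,
) -> pd.Series:
    """Permutation importance of each predictor for one fitted run.

    For each predictor the column is shuffled across cells, the model
    re-predicts, and importance is (1 - Pearson correlation between the
    standard and shuffled prediction) x 100, averaged over permutations.
    A constant baseline prediction leaves every importance NaN (flagged,
    not zeroed).  With ``standardize`` the importances are scaled to sum to
    100 across predictors, the form suitable for cross-run averaging.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    base = np.asarray(predict(X), dtype=float).ravel()
    if base.std() == 0:
        return pd.Series(np.nan, index=predictor_ids, name="importance")

    raw = np.zeros(len(predictor_ids))
    for j in range(len(predictor_ids)):
        acc = 0.0
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            pred = np.asarray(predict(Xp), dtype=float).ravel()
            if pred.std() == 0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(base, pred)[0, 1])
            acc += (1.0 - corr) * 100.0
        raw[j] = acc / n_permutations

    out = pd.Series(raw, index=predictor_ids, name="importance")
    if standardize:
        total = out.sum()
        if total > 0:
            out = out / total * 100.0
    return out
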