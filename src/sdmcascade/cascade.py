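"""Weighted consensus ensembles, future projection and likelihood mapping.

The cascade couples the SDM ensemble to the climate-scenario ensemble: the
passing runs are combined into one skill-weighted consensus, binarized at
the ROC-optimal threshold, and re-applied to each perturbed future climate.
Each (pseudo-GCM, scenario, horizon) projection is one *cascade ensemble
member* (CEM); per-cell agreement among the members is translated into IPCC
AR5 calibrated likelihood language, and per-(scenario, horizon) averages of
the member binaries form the sub-CEMs used by the change analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import optimal_threshold
from .occurrence import OccurrenceLayer
from .predictors import PredictorStack, TOPO_IDS
from .sdm import SdmRun

#: likelihood classes in increasing order of agreement
LIKELIHOOD_LABELS = (
    "not suitable",
    "extremely unlikely",
    "unlikely",
    "about as likely as not",
    "likely",
    "extremely likely",
)

#: reference bin upper edges on a 10-member scale: 1 | 2-3 | 4-6 | 7-8 | 9-10
_REFERENCE_UPPER = (1, 3, 6, 8, 10)


@dataclass
class EnsembleModel:
    """Skill-weighted consensus of the passing runs for one species."""

    species: str
    runs: list[SdmRun]
    weights: np.ndarray
    threshold: float
    consensus: np.ndarray  # historical consensus score field
    binary: np.ndarray  # historical presence/absence map

    def __post_init__(self) -> None:
        if len(self.runs) == 0:
            raise ValueError("an ensemble needs at least one passing run")
        if not np.isclose(self.weights.sum(), 1.0) or np.any(self.weights < 0):
            raise ValueError("weights must be non-negative and sum to 1")

    def predict_consensus(self, stack: PredictorStack) -> np.ndarray:
        fields = np.stack([run.predict_stack(stack) for run in self.runs])
        return np.tensordot(self.weights, fields, axes=1)


@dataclass(frozen=True)
class CascadeMember:
    """One binary future suitability map for a (model, scenario, horizon)."""

    species: str
    model_id: str
    scenario_id: str
    horizon_id: str
    binary: np.ndarray


@dataclass
class LikelihoodMap:
    """Per-cell member agreement and its likelihood class."""

    species: str
    horizon_id: str
    counts: np.ndarray
    classes: np.ndarray  # indices into LIKELIHOOD_LABELS
    member_count: int
    historical: np.ndarray | None = None


@dataclass
class SubCem:
    """Per-(scenario, horizon) mean of member binaries across climate models."""

    species: str
    scenario_id: str
    horizon_id: str
    fraction: np.ndarray
    binary: np.ndarray
    model_count: int


class NoEnsemble(RuntimeError):
    """Raised when no run passed the dual ROC/TSS filter for a species."""


def build_ensemble(
    passing_runs: list[SdmRun],
    layer: OccurrenceLayer,
    stack: PredictorStack,
) -> EnsembleModel:
    """Combine passing runs into a weighted consensus with a ROC threshold.

    Weights are proportional to skill above chance, auc - 0.5 (floored at
    zero), normalized to sum to 1; a chance-level run therefore contributes
    nothing.  The consensus score is the weighted mean of the run scores and
    is binarized at the threshold maximizing sensitivity + specificity
    against the observed occurrence.
    """
    if not passing_runs:
        raise NoEnsemble(f"no run passed the filter for species {layer.species!r}")
    skill = np.array([max(run.scores.auc - 0.5, 0.0) for run in passing_runs])
    weights = skill / skill.sum() if skill.sum() > 0 else np.full(len(passing_runs), 1.0 / len(passing_runs))

    fields = np.stack([run.suitability for run in passing_runs])
    consensus = np.tensordot(weights, fields, axes=1)

    valid = layer.valid.ravel()
    threshold = optimal_threshold(
        layer.binary.ravel()[valid], consensus.ravel()[valid], criterion="roc"
    )
    return EnsembleModel(
        species=layer.species,
        runs=list(passing_runs),
        weights=weights,
        threshold=threshold,
        consensus=consensus,
        binary=consensus >= threshold,
    )


def project_member(
    ensemble: EnsembleModel,
    future_stack: PredictorStack,
    historical_stack: PredictorStack,
    model_id: str,
    scenario_id: str,
    horizon_id: str,
) -> CascadeMember:
    """Project the consensus onto one future climate and binarize it.

    Topographic predictors are taken unchanged from the historical stack;
    the future stack needs to carry (at least) the 19 bioclim surfaces.
    """
    data = {pid: historical_stack.get(pid) for pid in TOPO_IDS if pid in historical_stack.data}
    for pid in historical_stack.ids:
        if pid not in data:
            data[pid] = future_stack.get(pid)
    merged = PredictorStack(historical_stack.grid, data)
    score = ensemble.predict_consensus(merged)
    return CascadeMember(
        species=ensemble.species,
        model_id=model_id,
        scenario_id=scenario_id,
        horizon_id=horizon_id,
        binary=score >= ensemble.threshold,
    )


def likelihood_bins(member_count: int = 10) -> list[tuple[int, int]]:
    """(lower, upper) inclusive count bins per non-absent class.

    The 10-member reference scale is 1 | 2-3 | 4-6 | 7-8 | 9-10; for other
    member counts the bin edges scale proportionally (ceil of the reference
    edge fraction), preserving a gap-free partition of 1..member_count.
    """
    if member_count < 1:
        raise ValueError("member_count must be >= 1")
    uppers = [int(np.ceil(u / 10.0 * member_count)) for u in _REFERENCE_UPPER]
    uppers[-1] = member_count
    bins, lo = [], 1
    for u in uppers:
        u = max(u, lo - 1)
        bins.append((lo, u))
        lo = u + 1
    return bins


def classify_likelihood(
    members: list[CascadeMember],
    species: str,
    horizon_id: str,
    expected_count: int | None = None,
    historical: np.ndarray | None = None,
) -> LikelihoodMap:
    """Count member agreement per cell and map counts to likelihood classes."""
    if not members:
        raise ValueError("empty member set")
    if expected_count is not None and len(members) != expected_count:
        raise ValueError(
            f"incomplete member set: got {len(members)}, expected {expected_count}"
        )
    m = len(members)
    counts = np.sum([mem.binary.astype(int) for mem in members], axis=0)

    classes = np.zeros(counts.shape, dtype=int)  # 0 = not suitable
    for k, (lo, hi) in enumerate(likelihood_bins(m), start=1):
        classes[(counts >= lo) & (counts <= hi)] = k
    return LikelihoodMap(
        species=species,
        horizon_id=horizon_id,
        counts=counts,
        classes=classes,
        member_count=m,
        historical=historical,
    )


def build_sub_cems(members: list[CascadeMember]) -> list[SubCem]:
    """Average member binaries across climate models per (scenario, horizon).

    The sub-CEM binary is the majority vote: fraction >= 0.5.
    """
    if not members:
        raise ValueError("empty member set")
    groups: dict[tuple[str, str], list[CascadeMember]] = {}
    for mem in members:
        groups.setdefault((mem.scenario_id, mem.horizon_id), []).append(mem)
    model_counts = {len(g) for g in groups.values()}
    if len(model_counts) != 1:
        raise ValueError("incomplete member set: unequal model counts across scenarios")
    out = []
    for (scen, hz), group in sorted(groups.items()):
        frac = np.mean([mem.binary.astype(float) for mem in group], axis=0)
        out.append(
            SubCem(
                species=group[0].species,
                scenario_id=scen,
                horizon_id=hz,
                fraction=frac,
                binary=frac >= 0.5,
                model_count=len(group),
            )
        )
    return out
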