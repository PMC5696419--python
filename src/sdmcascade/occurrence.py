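"""Presence/absence layers and calibration/validation splits.

Fractional presence (the share of a cell occupied by a category) becomes
binary occurrence through a strict threshold: a cell is a presence only when
its fraction is strictly above the cutoff (default 2%), which screens out
relict or planted stands occupying a sliver of a cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OccurrenceLayer:
    """Binary occurrence derived from a fractional presence field."""

    species: str
    fraction: np.ndarray
    binary: np.ndarray
    threshold: float  # as a fraction, e.g. 0.02
    valid: np.ndarray  # cells with a defined fraction

    @property
    def n_presence(self) -> int:
        return int(self.binary[self.valid].sum())

    @property
    def n_absence(self) -> int:
        return int(self.valid.sum()) - self.n_presence

    @property
    def prevalence(self) -> float:
        return self.n_presence / int(self.valid.sum())


@dataclass(frozen=True)
class CalibrationSplit:
    """One random partition of valid cells into calibration and validation."""

    run: int
    calibration: np.ndarray  # flat cell indices
    validation: np.ndarray
    seed: int


def binarize_presence(
    fraction: np.ndarray, threshold_percent: float = 2.0, species: str = "species"
) -> OccurrenceLayer:
    """Convert fractional presence to presence/absence.

    Cells with fraction strictly above ``threshold_percent``/100 are
    presences; cells at or below it (including exactly the threshold) are
    absences.  NaN cells are marked invalid.
    """
    if not 0 <= threshold_percent < 100:
        raise ValueError("threshold_percent must lie in [0, 100)")
    fraction = np.asarray(fraction, dtype=float)
    valid = np.isfinite(fraction)
    if np.any((fraction[valid] < 0) | (fraction[valid] > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    thr = threshold_percent / 100.0
    binary = np.zeros(fraction.shape, dtype=bool)
    binary[valid] = fraction[valid] > thr
    return OccurrenceLayer(
        species=species, fraction=fraction, binary=binary, threshold=thr, valid=valid
    )


def make_splits(
    layer: OccurrenceLayer,
    calibration_fraction: float = 0.7,
    n_runs: int = 10,
    seed: int = 0,
) -> list[CalibrationSplit]:
    """Draw ``n_runs`` independent stratified calibration/validation splits.

    Each run partitions the valid cells so the calibration part holds
    ``calibration_fraction`` of each class (rounded per class), guaranteeing
    both classes appear on both sides whenever the layer has at least two
    cells of each.
    """
    if not 0 < calibration_fraction < 1:
        raise ValueError("calibration_fraction must lie in (0, 1)")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    idx = np.flatnonzero(layer.valid.ravel())
    y = layer.binary.ravel()[idx]
    for label, name in ((True, "presence"), (False, "absence")):
        if (y == label).sum() < 2:
            raise ValueError(f"class {name!r} has fewer than 2 cells; cannot stratify")

    rng = np.random.default_rng(seed)
    splits: list[CalibrationSplit] = []
    for run in range(n_runs):
        cal_parts, val_parts = [], []
        for label in (True, False):
            members = idx[y == label]
            n_cal = int(round(calibration_fraction * len(members)))
            n_cal = min(max(n_cal, 1), len(members) - 1)  # both sides keep the class
            perm = rng.permutation(members)
            cal_parts.append(perm[:n_cal])
            val_parts.append(perm[n_cal:])
        splits.append(
            CalibrationSplit(
                run=run,
                calibration=np.sort(np.concatenate(cal_parts)),
                validation=np.sort(np.concatenate(val_parts)),
                seed=seed,
            )
        )
    return splits
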