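"""Bioclimatic (Bio1-Bio19) and topographic (Top1-Top9) predictor surfaces.

Bioclim definitions follow the WorldClim/ANUCLIM conventions: quarters are 3
consecutive calendar months with December-January wrap-around, ties broken by
the earliest starting month.  Temperatures are carried internally in °C as
floats; the °C×10 integer convention of legacy distributions is an output
option only.

The collinearity half of the module provides the standard diagnostics used
before calibrating distribution models — pairwise Pearson r, variance
inflation factors, and a Wilcoxon signed-rank comparison of two correlation
structures (e.g. historical vs. a future scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import DomainGrid, block_reduce

BIOCLIM_IDS = tuple(f"bio{i}" for i in range(1, 20))
TOPO_IDS = tuple(f"top{i}" for i in range(1, 10))
ALL_PREDICTOR_IDS = BIOCLIM_IDS + TOPO_IDS

#: predictors measured in °C (scaled by 10 under the "c10" unit convention)
TEMPERATURE_IDS = frozenset(
    ["bio1", "bio2", "bio4", "bio5", "bio6", "bio7", "bio8", "bio9", "bio10", "bio11"]
)

PREDICTOR_NAMES = {
    "bio1": "Annual mean temperature",
    "bio2": "Mean diurnal range",
    "bio3": "Isothermality",
    "bio4": "Temperature seasonality",
    "bio5": "Max temperature of warmest month",
    "bio6": "Min temperature of coldest month",
    "bio7": "Temperature annual range",
    "bio8": "Mean temperature of wettest quarter",
    "bio9": "Mean temperature of driest quarter",
    "bio10": "Mean temperature of warmest quarter",
    "bio11": "Mean temperature of coldest quarter",
    "bio12": "Annual precipitation",
    "bio13": "Precipitation of wettest month",
    "bio14": "Precipitation of driest month",
    "bio15": "Precipitation seasonality",
    "bio16": "Precipitation of wettest quarter",
    "bio17": "Precipitation of driest quarter",
    "bio18": "Precipitation of warmest quarter",
    "bio19": "Precipitation of coldest quarter",
    "top1": "Prevalent aspect",
    "top2": "Easting",
    "top3": "Latitude",
    "top4": "Max altitude",
    "top5": "Max slope",
    "top6": "Mean altitude",
    "top7": "Mean slope",
    "top8": "Min altitude",
    "top9": "Min slope",
}

# aspect classes: 1..8 = compass octants N, NE, E, SE, S, SW, W, NW;
# 9 = flat, 10 = undefined (NaN elevation)
ASPECT_FLAT = 9
ASPECT_UNDEFINED = 10

_M_PER_DEG = 111_320.0  # meridian meters per degree of latitude


@dataclass
class PredictorStack:
    """Named predictor surfaces on one working grid.

    ``data`` maps lower-case predictor ids to 2-D fields.  ``as_matrix``
    flattens the stack to a cells × predictors design matrix in the canonical
    bio1..bio19, top1..top9 order (restricted to the ids present).
    """

    grid: DomainGrid
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, arr in self.data.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"predictor {pid!r} shape {arr.shape} != grid {self.grid.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def ids(self) -> list[str]:
        order = {pid: i for i, pid in enumerate(ALL_PREDICTOR_IDS)}
        return sorted(self.data, key=lambda p: order.get(p, len(order)))

    def get(self, pid: str) -> np.ndarray:
        if pid not in self.data:
            raise KeyError(f"unknown predictor id {pid!r}")
        return self.data[pid]

    def as_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Cells × predictors matrix; ``mask`` selects cells (default all)."""
        cols = [self.data[pid].ravel() for pid in self.ids]
        m = np.column_stack(cols)
        if mask is not None:
            m = m[np.asarray(mask).ravel()]
        return m

    def with_units(self, units: str = "c") -> "PredictorStack":
        """Return a copy in °C ("c") or the legacy integer °C×10 ("c10")."""
        if units == "c":
            return PredictorStack(self.grid, {k: v.copy() for k, v in self.data.items()})
        if units != "c10":
            raise ValueError("units must be 'c' or 'c10'")
        out = {}
        for pid, arr in self.data.items():
            out[pid] = np.round(arr * 10.0) if pid in TEMPERATURE_IDS else arr.copy()
        return PredictorStack(self.grid, out)


# ---------------------------------------------------------------------------
# bioclimatic variables


def _quarter_sums(stack: np.ndarray) -> np.ndarray:
    """Sums over the 12 wrap-around 3-month quarters, indexed by start month."""
    ext = np.concatenate([stack, stack[:2]], axis=0)
    return np.stack([ext[s : s + 3].sum(axis=0) for s in range(12)])


def compute_bioclim(climate) -> dict[str, np.ndarray]:
    """Compute Bio1..Bio19 from a 12-month climate (°C, mm).

    Quarter variables (Bio8-Bio11, Bio16-Bio19) use 3-consecutive-month
    wrap-around quarters; ``argmax``/``argmin`` tie-breaking selects the
    earliest starting month.  Bio3 and Bio15 are flagged NaN where their
    denominators (Bio7, mean monthly precipitation) vanish.
    """
    tmean, tmin, tmax, prec = climate.tmean, climate.tmin, climate.tmax, climate.prec
    if tmean.shape[0] != 12:
        raise ValueError("climate must contain 12 months")

    bio: dict[str, np.ndarray] = {}
    bio["bio1"] = tmean.mean(axis=0)
    bio["bio2"] = (tmax - tmin).mean(axis=0)
    bio["bio4"] = 100.0 * tmean.std(axis=0)
    bio["bio5"] = tmax.max(axis=0)
    bio["bio6"] = tmin.min(axis=0)
    bio["bio7"] = bio["bio5"] - bio["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio["bio3"] = np.where(bio["bio7"] != 0, 100.0 * bio["bio2"] / bio["bio7"], np.nan)

    prec_q = _quarter_sums(prec)
    temp_q = _quarter_sums(tmean) / 3.0
    wettest_q = prec_q.argmax(axis=0)
    driest_q = prec_q.argmin(axis=0)
    warmest_q = temp_q.argmax(axis=0)
    coldest_q = temp_q.argmin(axis=0)

    take = np.take_along_axis
    bio["bio8"] = take(temp_q, wettest_q[None], axis=0)[0]
    bio["bio9"] = take(temp_q, driest_q[None], axis=0)[0]
    bio["bio10"] = take(temp_q, warmest_q[None], axis=0)[0]
    bio["bio11"] = take(temp_q, coldest_q[None], axis=0)[0]

    bio["bio12"] = prec.sum(axis=0)
    bio["bio13"] = prec.max(axis=0)
    bio["bio14"] = prec.min(axis=0)
    pmean = prec.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bio["bio15"] = np.where(pmean > 0, 100.0 * prec.std(axis=0) / pmean, np.nan)
    bio["bio16"] = take(prec_q, wettest_q[None], axis=0)[0]
    bio["bio17"] = take(prec_q, driest_q[None], axis=0)[0]
    bio["bio18"] = take(prec_q, warmest_q[None], axis=0)[0]
    bio["bio19"] = take(prec_q, coldest_q[None], axis=0)[0]
    return bio


# ---------------------------------------------------------------------------
# topographic variables


def _slope_aspect(elev: np.ndarray, cell_m: float, lat_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect class per fine cell from elevation gradients."""
    dy, dx = np.gradient(elev, cell_m, cell_m * np.cos(np.deg2rad(lat_deg)))
    # row axis points north (row 0 is south), so +dy is the northward gradient
    grad = np.hypot(dx, dy)
    slope = np.degrees(np.arctan(grad))

    aspect = np.full(elev.shape, ASPECT_FLAT, dtype=int)
    sloped = grad > 0
    # downslope direction as compass azimuth (0 = north, clockwise)
    az = np.degrees(np.arctan2(-dx, -dy)) % 360.0
    octant = (np.round(az / 45.0).astype(int) % 8) + 1
    aspect[sloped] = octant[sloped]
    aspect[~np.isfinite(elev)] = ASPECT_UNDEFINED
    return slope, aspect


def compute_topographic(
    elevation_fine: np.ndarray,
    grid: DomainGrid,
    fine_factor: int | None = None,
) -> dict[str, np.ndarray]:
    """Compute Top1..Top9 from a fine-resolution elevation model.

    Per working cell: max/mean/min of fine-cell altitude (Top4/Top6/Top8) and
    slope (Top5/Top7/Top9), the modal aspect class (Top1, octants 1-8 plus
    flat=9 and undefined=10), easting in degrees east of the western cell
    center (Top2) and cell-center latitude (Top3).
    """
    elev = np.asarray(elevation_fine, dtype=float)
    nr, nc = grid.shape
    if elev.shape[0] % nr or elev.shape[1] % nc:
        raise ValueError("fine elevation does not nest integrally in the working grid")
    f = elev.shape[0] // nr
    if fine_factor is not None and fine_factor != f:
        raise ValueError("fine_factor inconsistent with elevation shape")
    if elev.shape[1] // nc != f:
        raise ValueError("fine elevation must use the same nesting factor on both axes")

    cell_m = grid.cell_size / f * _M_PER_DEG
    mid_lat = float(np.mean(grid.lats))
    slope, aspect = _slope_aspect(elev, cell_m, mid_lat)

    top: dict[str, np.ndarray] = {}
    top["top4"] = block_reduce(elev, grid, np.max)
    top["top6"] = block_reduce(elev, grid, np.mean)
    top["top8"] = block_reduce(elev, grid, np.min)
    top["top5"] = block_reduce(slope, grid, np.max)
    top["top7"] = block_reduce(slope, grid, np.mean)
    top["top9"] = block_reduce(slope, grid, np.min)

    blocks = aspect.reshape(nr, f, nc, f).transpose(0, 2, 1, 3).reshape(nr, nc, f * f)
    modal = np.empty((nr, nc), dtype=float)
    for i in range(nr):
        for j in range(nc):
            counts = np.bincount(blocks[i, j], minlength=ASPECT_UNDEFINED + 1)
            modal[i, j] = counts.argmax()  # ties -> lowest class id
    top["top1"] = modal

    lon, lat = grid.mesh()
    top["top2"] = lon - grid.origin_lon
    top["top3"] = lat
    return top


def make_predictor_stack(climate, elevation_fine: np.ndarray, grid: DomainGrid) -> PredictorStack:
    """Assemble the full 28-predictor stack from climate and topography."""
    data = compute_bioclim(climate)
    data.update(compute_topographic(elevation_fine, grid))
    return PredictorStack(grid, data)


# ---------------------------------------------------------------------------
# collinearity diagnostics


@dataclass
class CollinearityReport:
    """Pairwise Pearson correlations and per-predictor VIFs.

    Constant predictors get NaN correlations/VIF and are listed in
    ``undefined`` rather than silently dropped; an exact linear dependence
    yields an infinite VIF.
    """

    ids: list[str]
    r: pd.DataFrame
    vif: pd.Series
    undefined: list[str]

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle correlations in row-major order."""
        m = self.r.to_numpy()
        iu = np.triu_indices(len(self.ids), k=1)
        return m[iu]


@dataclass
class StructureComparison:
    """Wilcoxon signed-rank comparison of two correlation structures."""

    statistic: float
    pvalue: float
    alpha: float
    different: bool
    n_pairs: int


def collinearity_report(stack: PredictorStack, mask: np.ndarray | None = None) -> CollinearityReport:
    """Pearson r matrix and VIFs over the included cells.

    VIF_j = 1/(1 - R²_j) from an OLS regression of predictor j on all other
    non-constant predictors (with intercept).
    """
    ids = stack.ids
    X = stack.as_matrix(mask)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 included cells")
    valid_rows = np.all(np.isfinite(X), axis=1)
    X = X[valid_rows]

    sd = X.std(axis=0)
    constant = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))

    vif = np.full(len(ids), np.nan)
    usable = ~constant
    Xu = X[:, usable]
    u_idx = np.flatnonzero(usable)
    for col, j in enumerate(u_idx):
        y = Xu[:, col]
        others = np.delete(Xu, col, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sst = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst
        vif[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)

    return CollinearityReport(
        ids=list(ids),
        r=pd.DataFrame(r, index=ids, columns=ids),
        vif=pd.Series(vif, index=ids, name="vif"),
        undefined=[pid for pid, c in zip(ids, constant) if c],
    )


def compare_collinearity_structure(
    report_a: CollinearityReport, report_b: CollinearityReport, alpha: float = 0.001
) -> StructureComparison:
    """Wilcoxon signed-rank test on paired off-diagonal correlations.

    Tests whether the collinearity structure differs between two predictor
    sets (e.g. historical vs. one future scenario); identical structures give
    a zero statistic and are reported as not different.
    """
    if report_a.ids != report_b.ids:
        raise ValueError("reports cover different predictor sets")
    a = report_a.upper_triangle()
    b = report_b.upper_triangle()
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return StructureComparison(0.0, 1.0, alpha, False, len(diffs))
    res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return StructureComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        alpha=alpha,
        different=bool(res.pvalue < alpha),
        n_pairs=int(len(diffs)),
    )
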