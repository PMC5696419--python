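"""Synthetic landscapes: topography, monthly climate, virtual species, futures.

This module fabricates every input the suitability analysis needs — a smooth
elevation model, lapse-rate structured monthly climate normals, virtual
species whose occurrence probability is a *known* function of bioclimatic
predictors, per-pseudo-GCM future perturbations and contiguous pseudo
biogeographical regions — so the full pipeline can run and be validated
end-to-end without any external raster.

All generators are pure functions of their parameters and a seed.  Virtual
species keep their noise-free suitability surface alongside the sampled one,
which is what makes niche-recovery tests possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit, logit

from .grid import DomainGrid, block_reduce

DEFAULT_FINE_FACTOR = 8  # fine DEM cells per working-cell edge


# ---------------------------------------------------------------------------
# data containers


@dataclass
class MonthlyClimate:
    """12-month stacks of temperature (°C) and precipitation (mm/month).

    Arrays have shape ``(12, n_rows, n_cols)`` and satisfy
    ``tmin <= tmean <= tmax`` and ``prec >= 0`` in every cell-month.
    """

    tmin: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.tmin, self.tmean, self.tmax, self.prec)}
        if len(shapes) != 1 or self.tmin.shape[0] != 12:
            raise ValueError("climate stacks must share one (12, rows, cols) shape")
        if np.any(self.tmin > self.tmean + 1e-9) or np.any(self.tmean > self.tmax + 1e-9):
            raise ValueError("monthly temperatures must satisfy tmin <= tmean <= tmax")
        if np.any(self.prec < 0):
            raise ValueError("monthly precipitation must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tmean.shape[1:]


@dataclass(frozen=True)
class VirtualSpecies:
    """A virtual species with a Gaussian-bell environmental response.

    ``response_terms`` are ``(predictor_id, optimum, tolerance, weight)``
    tuples combined additively on the logit scale; ``baseline_prevalence`` is
    the fraction of cells intended to end up above the presence threshold.
    """

    name: str
    response_terms: tuple[tuple[str, float, float, float], ...]
    baseline_prevalence: float = 0.3
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        for pid, opt, tol, w in self.response_terms:
            if tol <= 0:
                raise ValueError(f"tolerance for {pid} must be > 0")
            if not np.isfinite(w):
                raise ValueError(f"weight for {pid} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ScenarioPerturbation:
    """One pseudo-GCM × pseudo-RCP × horizon future climate modifier.

    ``temp_offset`` shifts all monthly temperatures (°C), ``precip_factor``
    scales all monthly precipitation, and the optional ``spatial_gradient``
    field modulates the temperature offset per cell.
    """

    model_id: str
    scenario_id: str
    horizon_id: str
    temp_offset: float
    precip_factor: float
    spatial_gradient: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.precip_factor <= 0:
            raise ValueError("precip_factor must be > 0")


# ---------------------------------------------------------------------------
# generators


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Spatially autocorrelated standard field: smoothed, re-standardized noise."""
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def make_topography(
    grid: DomainGrid,
    seed: int,
    relief: float = 2500.0,
    fine_factor: int = DEFAULT_FINE_FACTOR,
    smoothness: float | None = None,
) -> np.ndarray:
    """Generate a smooth non-negative elevation field at fine resolution.

    Smoothed white noise is rescaled to span ``[0, relief]`` meters.  The
    returned array has ``fine_factor`` cells per working-cell edge, so
    topographic statistics at working resolution are nontrivial.
    """
    if relief < 0:
        raise ValueError("relief must be >= 0")
    shape = grid.fine_shape(fine_factor)
    if relief == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    sigma = smoothness if smoothness is not None else 1.5 * fine_factor
    f = _smooth_field(shape, rng, sigma)
    f = f - f.min()
    peak = f.max()
    if peak > 0:
        f = f / peak * relief
    return f


def make_monthly_climate(
    grid: DomainGrid,
    elevation: np.ndarray,
    seed: int,
    sea_level_temp: float = 16.0,
    lapse_rate: float = 6.5,
    lat_gradient: float = 0.6,
    seasonal_amplitude: float = 9.0,
    amplitude_lat_gain: float = 0.25,
    diurnal_range: float = 9.0,
    diurnal_elev_gain: float = 1.5,
    temp_noise: float = 1.0,
    temp_noise_monthly: float = 0.5,
    prec_base: float = 70.0,
    prec_seasonality: float = 0.5,
    prec_orographic: float = 0.5,
    prec_noise: float = 0.3,
    wettest_month: int = 10,
) -> MonthlyClimate:
    """Build 12 monthly temperature/precipitation normals on the working grid.

    Temperature cools with elevation at ``lapse_rate`` °C per km and with
    latitude at ``lat_gradient`` °C per degree north of the grid origin, and
    follows a sinusoidal seasonal cycle peaking in July whose amplitude grows
    inland/northward (``amplitude_lat_gain`` °C per degree, a continentality
    proxy); the diurnal range widens with elevation.  Smooth mesoscale
    anomaly fields (an annual one of ``temp_noise`` °C plus independent
    monthly ones of ``temp_noise_monthly`` °C) emulate the part of observed
    climate normals that topography and latitude do not explain; set both to
    0 for a fully deterministic temperature surface.  Precipitation combines
    a seasonal cycle peaking at ``wettest_month`` (0-based), an orographic
    enhancement and a smooth multiplicative random field.

    Anomalies shift tmin/tmean/tmax alike and the monthly ones are centered
    over the year, so the annual-mean lapse/latitude structure and the
    tmin <= tmean <= tmax ordering are preserved exactly.

    ``elevation`` may be given at working resolution or at any integrally
    nesting fine resolution (it is then block-averaged).
    """
    elev = block_reduce(np.asarray(elevation, dtype=float), grid)
    _, lat = grid.mesh()
    rng = np.random.default_rng(seed)

    months = np.arange(12)
    # annual-mean surface temperature
    t_annual = sea_level_temp - lapse_rate * elev / 1000.0 - lat_gradient * (lat - grid.origin_lat)
    if temp_noise > 0:
        t_annual = t_annual + temp_noise * _smooth_field(grid.shape, rng, sigma=max(grid.shape) / 8)
    amp = seasonal_amplitude + amplitude_lat_gain * (lat - grid.origin_lat)
    season = np.cos(2 * np.pi * (months - 6) / 12.0)
    tmean = t_annual[None, :, :] + season[:, None, None] * amp[None, :, :]
    if temp_noise_monthly > 0:
        monthly_anom = np.stack(
            [
                temp_noise_monthly * _smooth_field(grid.shape, rng, sigma=max(grid.shape) / 8)
                for _ in range(12)
            ]
        )
        monthly_anom -= monthly_anom.mean(axis=0, keepdims=True)  # keep bio1 analytic
        tmean = tmean + monthly_anom
    diurnal = diurnal_range + diurnal_elev_gain * elev / 1000.0
    tmin = tmean - diurnal[None, :, :] / 2.0
    tmax = tmean + diurnal[None, :, :] / 2.0

    wet_season = 1.0 + prec_seasonality * np.cos(2 * np.pi * (months - wettest_month) / 12.0)
    orog = 1.0 + prec_orographic * elev / 1000.0
    wetness = np.exp(prec_noise * _smooth_field(grid.shape, rng, sigma=max(grid.shape) / 8))
    prec = prec_base * wet_season[:, None, None] * orog[None, :, :] * wetness[None, :, :]
    prec = np.clip(prec, 0.0, None)

    return MonthlyClimate(tmin=tmin, tmean=tmean, tmax=tmax, prec=prec)


def sample_species_occurrence(
    species: VirtualSpecies,
    predictors: "PredictorStack",
    seed: int,
    presence_threshold: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a fractional presence field for a virtual species.

    The logit of the fractional presence is a weighted sum of Gaussian-bell
    responses to the named predictors plus i.i.d. noise; an intercept is then
    calibrated so the share of cells strictly above ``presence_threshold``
    matches ``baseline_prevalence``.

    Returns
    -------
    (fraction, true_suitability)
        The sampled fractional presence and the noise-free suitability
        surface on the same calibrated scale (the recoverable ground truth).
    """
    rng = np.random.default_rng(seed)
    eta_true = np.zeros(predictors.shape)
    for pid, opt, tol, w in species.response_terms:
        x = predictors.get(pid)  # raises KeyError for unknown ids
        eta_true = eta_true + w * np.exp(-0.5 * ((x - opt) / tol) ** 2)
    eta = eta_true
    if species.noise_sd > 0:
        eta = eta + rng.normal(0.0, species.noise_sd, size=eta.shape)

    # intercept such that P(fraction > threshold) == baseline_prevalence:
    # sigmoid(eta + c) > thr  <=>  eta > logit(thr) - c
    q = np.quantile(eta, 1.0 - species.baseline_prevalence)
    c = logit(presence_threshold) - q
    return expit(eta + c), expit(eta_true + c)


def perturb_climate(climate: MonthlyClimate, p: ScenarioPerturbation) -> MonthlyClimate:
    """Apply a scenario perturbation: uniform warming and precipitation scaling.

    The optional spatial gradient adds to the temperature offset per cell.
    The tmin <= tmean <= tmax ordering is preserved because all three stacks
    receive the identical shift.
    """
    offset = p.temp_offset
    if p.spatial_gradient is not None:
        g = np.asarray(p.spatial_gradient, dtype=float)
        if g.shape != climate.shape:
            raise ValueError("spatial_gradient shape does not match climate grid")
        offset = offset + g[None, :, :]
    return MonthlyClimate(
        tmin=climate.tmin + offset,
        tmean=climate.tmean + offset,
        tmax=climate.tmax + offset,
        prec=climate.prec * p.precip_factor,
    )


def make_scenario_set(
    model_count: int = 5,
    scenario_specs: Sequence[tuple[str, dict[str, float]]] = (
        ("rcp45", {"h2050": 1.4, "h2070": 1.8}),
        ("rcp85", {"h2050": 2.0, "h2070": 3.7}),
    ),
    model_temp_spread: float = 1.0,
    model_precip_span: float = 0.3,
) -> list[ScenarioPerturbation]:
    """Build the full pseudo-GCM × pseudo-RCP × horizon perturbation set.

    Pseudo-GCMs span a warm/wet to cold/dry gradient: model 0 is the warmest
    and wettest, the last model the coldest and driest, mirroring how real
    CMIP5 ensembles bracket the climate outlook.  Every (scenario, horizon)
    pair gets exactly ``model_count`` members.
    """
    if model_count < 1:
        raise ValueError("model_count must be >= 1")
    perts: list[ScenarioPerturbation] = []
    if model_count == 1:
        rel = np.array([0.0])
    else:
        rel = np.linspace(1.0, -1.0, model_count)  # warm/wet -> cold/dry
    for scen_id, horizons in scenario_specs:
        for hz_id, base_offset in horizons.items():
            for m, r in enumerate(rel):
                perts.append(
                    ScenarioPerturbation(
                        model_id=f"gcm{m + 1}",
                        scenario_id=scen_id,
                        horizon_id=hz_id,
                        temp_offset=base_offset + model_temp_spread * r / 2.0,
                        precip_factor=max(1.0 + model_precip_span * r / 2.0, 1e-6),
                    )
                )
    return perts


def make_region_mask(grid: DomainGrid, k: int, seed: int) -> np.ndarray:
    """Partition the grid into ``k`` contiguous pseudo biogeographical regions.

    Regions are the nearest-seed (Voronoi) cells of ``k`` random centers in
    index space, which are contiguous by convexity.  Labels run 0..k-1 and
    every cell is labeled.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > grid.n_cells:
        raise ValueError("k exceeds the number of grid cells")
    rng = np.random.default_rng(seed)
    flat = rng.choice(grid.n_cells, size=k, replace=False)
    centers = np.column_stack(np.unravel_index(flat, grid.shape)).astype(float)
    rows, cols = np.indices(grid.shape)
    d2 = (rows[..., None] - centers[:, 0]) ** 2 + (cols[..., None] - centers[:, 1]) ** 2
    return np.argmin(d2, axis=-1)
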