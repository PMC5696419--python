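"""Bioclim/topographic predictors and collinearity diagnostics."""

import itertools

import numpy as np
import pytest

from sdmcascade import (
    DomainGrid,
    MonthlyClimate,
    PredictorStack,
    collinearity_report,
    compare_collinearity_structure,
    compute_bioclim,
    compute_topographic,
)
from conftest import random_climate


def brute_force_quarters(tmean, prec):
    """Independent oracle: enumerate all 12 wrap-around 3-month quarters."""
    starts = list(range(12))
    qt = [np.mean([tmean[(s + k) % 12] for k in range(3)], axis=0) for s in starts]
    qp = [np.sum([prec[(s + k) % 12] for k in range(3)], axis=0) for s in starts]
    qt, qp = np.array(qt), np.array(qp)
    out = {}
    wet, dry = qp.argmax(axis=0), qp.argmin(axis=0)
    warm, cold = qt.argmax(axis=0), qt.argmin(axis=0)
    take = np.take_along_axis
    out["bio8"] = take(qt, wet[None], 0)[0]
    out["bio9"] = take(qt, dry[None], 0)[0]
    out["bio10"] = take(qt, warm[None], 0)[0]
    out["bio11"] = take(qt, cold[None], 0)[0]
    out["bio16"] = take(qp, wet[None], 0)[0]
    out["bio17"] = take(qp, dry[None], 0)[0]
    out["bio18"] = take(qp, warm[None], 0)[0]
    out["bio19"] = take(qp, cold[None], 0)[0]
    return out


class TestBioclim:
    def test_constant_climate_identities(self):
        shape = (12, 2, 2)
        clim = MonthlyClimate(
            tmin=np.full(shape, 5.0),
            tmean=np.full(shape, 10.0),
            tmax=np.full(shape, 15.0),
            prec=np.full(shape, 50.0),
        )
        bio = compute_bioclim(clim)
        assert np.all(bio["bio1"] == 10.0)
        assert np.all(bio["bio4"] == 0.0)
        assert np.all(bio["bio5"] == 15.0)
        assert np.all(bio["bio6"] == 5.0)
        assert np.all(bio["bio7"] == 10.0)
        assert np.all(bio["bio12"] == 600.0)
        assert np.all(bio["bio13"] == 50.0)
        assert np.all(bio["bio14"] == 50.0)
        assert np.all(bio["bio15"] == 0.0)

    def test_bio7_definitional_identity(self):
        rng = np.random.default_rng(0)
        clim = random_climate(rng)
        bio = compute_bioclim(clim)
        np.testing.assert_array_equal(bio["bio7"], bio["bio5"] - bio["bio6"])
        assert np.all(bio["bio5"] >= bio["bio6"])
        assert np.all(bio["bio13"] >= bio["bio14"])
        assert np.all(bio["bio14"] >= 0)

    def test_wet_warm_summer_quarters_match_enumeration(self):
        # hand-built single-cell series with one wet, warm summer
        tmean = np.array([0, 1, 4, 8, 14, 19, 22, 21, 16, 10, 5, 1], dtype=float)
        prec = np.array([40, 38, 45, 60, 80, 120, 150, 140, 90, 55, 48, 42], dtype=float)
        clim = MonthlyClimate(
            tmin=(tmean - 4)[:, None, None],
            tmean=tmean[:, None, None],
            tmax=(tmean + 4)[:, None, None],
            prec=prec[:, None, None],
        )
        bio = compute_bioclim(clim)
        oracle = brute_force_quarters(clim.tmean, clim.prec)
        for key in ("bio8", "bio18"):
            np.testing.assert_allclose(bio[key], oracle[key])

    @pytest.mark.parametrize("seed", range(10))
    def test_quarter_variables_match_enumeration_on_random_climates(self, seed):
        clim = random_climate(np.random.default_rng(seed), shape=(3, 3))
        bio = compute_bioclim(clim)
        oracle = brute_force_quarters(clim.tmean, clim.prec)
        for key, expected in oracle.items():
            np.testing.assert_allclose(bio[key], expected, err_msg=key)

    def test_missing_month_rejected(self):
        shape = (11, 2, 2)
        with pytest.raises(ValueError):
            compute_bioclim(
                MonthlyClimate(
                    tmin=np.zeros(shape),
                    tmean=np.zeros(shape),
                    tmax=np.zeros(shape),
                    prec=np.zeros(shape),
                )
            )


class TestTopographic:
    def test_flat_elevation(self):
        grid = DomainGrid(n_rows=4, n_cols=4)
        top = compute_topographic(np.zeros((16, 16)), grid)
        assert np.all(top["top5"] == 0.0)
        assert np.all(top["top7"] == 0.0)
        assert np.all(top["top9"] == 0.0)
        assert np.all(top["top1"] == 9.0)  # flat class

    def test_tilted_plane_slope_is_analytic(self):
        grid = DomainGrid(n_rows=4, n_cols=4, cell_size=0.25, origin_lat=0.0)
        f = 4
        cell_m = grid.cell_size / f * 111_320.0
        dz_per_m = 0.05
        rows = np.arange(grid.n_rows * f)
        elev = np.tile(rows[:, None] * dz_per_m * cell_m, (1, grid.n_cols * f))
        top = compute_topographic(elev, grid)
        expected = np.degrees(np.arctan(dz_per_m))
        mid_lat = np.mean(grid.lats)  # latitude shrinks only the E-W spacing
        np.testing.assert_allclose(top["top5"], expected, rtol=1e-6)
        np.testing.assert_allclose(top["top7"], expected, rtol=1e-6)
        np.testing.assert_allclose(top["top9"], expected, rtol=1e-6)
        # plane rising northward: downslope faces south (class 5)
        assert np.all(top["top1"] == 5.0)
        assert mid_lat == pytest.approx(0.375)

    def test_altitude_order_statistics(self, grid, elevation):
        top = compute_topographic(elevation, grid)
        assert np.all(top["top4"] >= top["top6"])
        assert np.all(top["top6"] >= top["top8"])
        assert np.all(top["top5"] >= top["top7"])
        assert np.all(top["top7"] >= top["top9"])

    def test_easting_and_latitude(self, grid, elevation):
        top = compute_topographic(elevation, grid)
        assert top["top2"][0, 0] == 0.0
        assert top["top2"][0, -1] == pytest.approx((grid.n_cols - 1) * grid.cell_size)
        assert top["top3"][0, 0] == pytest.approx(grid.origin_lat)

    def test_aggregation_commutes_for_altitude_stats(self, grid, elevation):
        from sdmcascade import block_reduce

        top = compute_topographic(elevation, grid)
        np.testing.assert_allclose(top["top4"], block_reduce(elevation, grid, np.max))
        np.testing.assert_allclose(top["top6"], block_reduce(elevation, grid, np.mean))
        np.testing.assert_allclose(top["top8"], block_reduce(elevation, grid, np.min))

    def test_non_nesting_rejected(self, grid):
        with pytest.raises(ValueError):
            compute_topographic(np.zeros((21, 21)), grid)


class TestCollinearity:
    def _stack_from_matrix(self, X, ids):
        n = X.shape[0]
        side = int(np.sqrt(n))
        grid = DomainGrid(n_rows=side, n_cols=side, cell_size=1.0)
        return PredictorStack(grid, {pid: X[:, j].reshape(side, side) for j, pid in enumerate(ids)})

    def test_identical_predictors_have_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        stack = self._stack_from_matrix(np.column_stack([x, x]), ["bio1", "bio2"])
        rep = collinearity_report(stack)
        assert rep.r.loc["bio1", "bio2"] == pytest.approx(1.0)

    def test_independent_predictors_have_vif_near_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2500, 4))
        stack = self._stack_from_matrix(X, ["bio1", "bio2", "bio3", "bio4"])
        rep = collinearity_report(stack)
        assert np.all(rep.vif.to_numpy() < 1.05)
        assert np.all(rep.vif.to_numpy() >= 1.0)

    def test_exact_linear_dependence_flags_infinite_vif(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(64, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        stack = self._stack_from_matrix(X, ["bio1", "bio2", "bio3"])
        rep = collinearity_report(stack)
        assert np.isinf(rep.vif.to_numpy()).any()

    def test_constant_predictor_flagged_not_dropped(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=64), np.full(64, 7.0)])
        stack = self._stack_from_matrix(X, ["bio1", "bio2"])
        rep = collinearity_report(stack)
        assert rep.undefined == ["bio2"]
        assert np.isnan(rep.r.loc["bio1", "bio2"])
        assert "bio2" in rep.ids

    def test_identical_reports_not_different(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 5))
        stack = self._stack_from_matrix(X, [f"bio{i}" for i in range(1, 6)])
        rep = collinearity_report(stack)
        cmp = compare_collinearity_structure(rep, rep, alpha=0.001)
        assert not cmp.different
        assert cmp.statistic == 0.0

    def test_large_shift_detected_as_different(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 7))
        ids = [f"bio{i}" for i in range(1, 8)]
        rep_a = collinearity_report(self._stack_from_matrix(X, ids))
        rep_b = collinearity_report(self._stack_from_matrix(X, ids))
        rep_b.r.iloc[:, :] = np.clip(rep_a.r.to_numpy() + 0.5, -1, 1)
        cmp = compare_collinearity_structure(rep_a, rep_b, alpha=0.001)
        assert cmp.different

    def test_exact_sign_flip_enumeration_for_six_pairs(self):
        """For n=6 all-positive differences, p equals the exhaustive sign-flip value."""
        a = np.array([0.11, 0.22, 0.31, 0.44, 0.52, 0.63])
        b = a - np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        diffs = a - b
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        observed = ranks.sum()  # W+ with all positive signs
        null = []
        for signs in itertools.product([0, 1], repeat=6):
            null.append(sum(r for r, s in zip(ranks, signs) if s))
        null = np.array(null)
        p_exact = 2 * min(
            np.mean(null >= observed), np.mean(null <= observed)
        )

        ids = ["bio1", "bio2", "bio3", "bio4"]  # 6 off-diagonal pairs
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 4))
        rep_a = collinearity_report(self._stack_from_matrix(X, ids))
        rep_b = collinearity_report(self._stack_from_matrix(X, ids))
        tri = rep_a.upper_triangle()
        shifted = tri - np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        m = rep_b.r.to_numpy()
        iu = np.triu_indices(4, k=1)
        m[iu] = shifted
        m[(iu[1], iu[0])] = shifted
        cmp = compare_collinearity_structure(rep_a, rep_b)
        assert cmp.pvalue == pytest.approx(p_exact)

    def test_mismatched_predictor_sets_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(64, 2))
        rep_a = collinearity_report(self._stack_from_matrix(X, ["bio1", "bio2"]))
        rep_b = collinearity_report(self._stack_from_matrix(X, ["bio1", "bio3"]))
        with pytest.raises(ValueError):
            compare_collinearity_structure(rep_a, rep_b)
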