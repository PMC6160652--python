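"""Sparsity sweep, AUC integration, significance ranges, hub identification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nirsnet as nn
from nirsnet.nulls import ZScoreResult

import oracles


@pytest.fixture(scope="module")
def demo_corr():
    rng = np.random.default_rng(11)
    data = rng.standard_normal((8, 200))
    # plant some structure
    data[1] = 0.7 * data[0] + 0.3 * data[1]
    data[2] = 0.6 * data[0] + 0.4 * data[2]
    return nn.correlation_matrix(nn.Recording(data=data, sampling_rate_hz=10.0))


class TestMetricCurves:
    def test_default_grid_has_101_points(self):
        assert len(nn.SparsityGrid()) == 101
        assert nn.SparsityGrid().values[0] == 0.0
        assert nn.SparsityGrid().values[-1] == 1.0

    def test_edgeless_point_masks_lp(self, demo_corr):
        sw = nn.metric_curves(demo_corr, grid=nn.SparsityGrid(step=0.25), n_nulls=0)
        lp = sw.curves["l_p"]
        assert lp.mask[0]  # S = 0: edgeless
        assert sw.curves["c_p"].values[0] == 0.0

    def test_complete_point_is_its_own_null(self, demo_corr):
        sw = nn.metric_curves(demo_corr, grid=nn.SparsityGrid(start=0.5, step=0.5),
                              n_nulls=10, seed=0)
        nm = sw.normalized[-1]  # S = 1: complete graph
        assert nm.gamma == 1.0 and nm.lambda_ == 1.0

    def test_sweep_deterministic_under_seed(self, demo_corr):
        a = nn.metric_curves(demo_corr, grid=nn.SparsityGrid(step=0.1), n_nulls=10, seed=4)
        b = nn.metric_curves(demo_corr, grid=nn.SparsityGrid(step=0.1), n_nulls=10, seed=4)
        np.testing.assert_array_equal(a.curves["c_p"].values, b.curves["c_p"].values)
        np.testing.assert_array_equal(a.z_array("c_p"), b.z_array("c_p"))

    def test_curve_values_match_direct_binarization(self, demo_corr):
        sw = nn.metric_curves(demo_corr, grid=nn.SparsityGrid(step=0.2), n_nulls=0)
        for s, v in zip(sw.curves["c_p"].grid, sw.curves["c_p"].values):
            g = nn.binarize_at_sparsity(demo_corr, float(s))
            assert v == pytest.approx(nn.all_metrics(g).c_p, abs=1e-12)


class TestAUC:
    def _curve(self, grid, values):
        return nn.MetricCurve(metric="y", grid=np.asarray(grid), values=np.asarray(values))

    def test_unit_constant_integrates_to_one(self):
        grid = np.round(np.arange(0, 1.01, 0.01), 10)
        out = nn.auc(self._curve(grid, np.ones_like(grid)))
        assert out.value == pytest.approx(1.0, abs=1e-12)

    def test_identity_curve_integrates_to_half(self):
        grid = np.round(np.arange(0, 1.01, 0.01), 10)
        out = nn.auc(self._curve(grid, grid))
        assert out.value == pytest.approx(0.5, abs=1e-12)

    def test_single_trapezoid(self):
        out = nn.auc(self._curve([0.1, 0.2], [2.0, 4.0]))
        assert out.value == pytest.approx(0.3, abs=1e-12)

    def test_matches_trapezoid_oracle(self, rng):
        grid = np.round(np.arange(0.1, 0.75, 0.05), 10)
        ys = rng.standard_normal(len(grid))
        out = nn.auc(self._curve(grid, ys), window=(0.2, 0.6))
        i, j = 2, 10
        assert out.value == pytest.approx(oracles.trapezoid(ys[i : j + 1], grid[i : j + 1]), abs=1e-12)

    def test_masked_point_inside_window_flags_undefined(self):
        values = np.array([1.0, np.nan, 2.0, 3.0])
        out = nn.auc(self._curve([0.0, 0.1, 0.2, 0.3], values))
        assert not out.defined and np.isnan(out.value)
        assert "0.1" in out.reason

    def test_off_grid_window_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            nn.auc(self._curve([0.0, 0.1, 0.2], [1, 2, 3]), window=(0.05, 0.2))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 9999), a=st.floats(-3, 3), b=st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        grid = np.round(np.arange(0, 1.05, 0.05), 10)
        y1, y2 = rng.standard_normal((2, len(grid)))
        c1 = self._curve(grid, y1)
        c2 = self._curve(grid, y2)
        combo = self._curve(grid, a * y1 + b * y2)
        lhs = nn.auc(combo).value
        rhs = a * nn.auc(c1).value + b * nn.auc(c2).value
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_constant_window_area(self):
        grid = np.round(np.arange(0, 1.01, 0.01), 10)
        out = nn.auc(self._curve(grid, np.full(len(grid), 3.0)), window=(0.25, 0.75))
        assert out.value == pytest.approx(3.0 * 0.5, abs=1e-12)


class TestSignificantRange:
    def _z(self, values):
        return np.asarray(values, dtype=float)

    def test_no_significance_empty(self):
        grid = np.round(np.arange(0, 1.01, 0.01), 10)
        assert nn.significant_range(self._z(np.zeros(len(grid))), grid) == []

    def test_constructed_run_recovered(self):
        grid = np.round(np.arange(0, 1.01, 0.01), 10)
        z = np.zeros(len(grid))
        lo, hi = 10, 66  # S in [0.10, 0.66]
        z[lo : hi + 1] = 3.0
        runs = nn.significant_range(z, grid)
        assert len(runs) == 1
        run = runs[0]
        assert run["s_start"] == pytest.approx(0.10)
        assert run["s_end"] == pytest.approx(0.66)
        assert run["mean_z"] == pytest.approx(3.0)
        assert run["sd_z"] == pytest.approx(0.0)

    def test_negative_runs_detected(self):
        grid = np.round(np.arange(0, 0.51, 0.01), 10)
        z = np.zeros(len(grid))
        z[5:10] = -2.5
        runs = nn.significant_range(z, grid)
        assert len(runs) == 1 and runs[0]["mean_z"] == pytest.approx(-2.5)

    def test_accepts_zscore_results(self):
        grid = np.array([0.0, 0.1, 0.2])
        zres = [
            ZScoreResult("c_p", 1, 0, 1, z, abs(z) > 1.96)
            for z in (0.0, 2.5, 2.6)
        ]
        runs = nn.significant_range(zres, grid)
        assert runs[0]["s_start"] == pytest.approx(0.1)


class TestHubs:
    def test_identical_aucs_yield_no_hubs(self):
        report = nn.identify_hubs({"k_nodal": np.full(5, 0.5)})
        assert not report.union.any()

    def test_single_outlier_is_the_hub(self):
        aucs = np.array([0.5, 0.5, 0.5, 0.5, 0.9])
        report = nn.identify_hubs({"k_nodal": aucs})
        assert report.hub_nodes() == [4]
        assert report.means["k_nodal"] == pytest.approx(0.58)
        assert report.sds["k_nodal"] == pytest.approx(0.17888543819998318)

    def test_union_over_criteria(self):
        report = nn.identify_hubs(
            {
                "k_nodal": np.array([0.5, 0.5, 0.5, 0.5, 0.9]),
                "n_bc": np.array([0.9, 0.5, 0.5, 0.5, 0.5]),
            }
        )
        assert report.hub_nodes() == [0, 4]

    def test_rescaling_invariance(self, rng):
        aucs = rng.uniform(0.2, 1.0, size=12)
        a = nn.identify_hubs({"k_nodal": aucs}).union
        b = nn.identify_hubs({"k_nodal": aucs * 37.5}).union
        np.testing.assert_array_equal(a, b)

    def test_too_few_nodes_refused(self):
        with pytest.raises(ValueError, match="3 nodes"):
            nn.identify_hubs({"k_nodal": np.array([1.0, 2.0])})

    def test_planted_star_hub_recovered_end_to_end(self):
        """A channel correlated with every other is flagged on degree."""
        rng = np.random.default_rng(5)
        base = rng.standard_normal(400)
        data = 0.55 * base + rng.standard_normal((8, 400))
        data[0] = base + 0.25 * rng.standard_normal(400)  # the hub channel
        corr = nn.correlation_matrix(nn.Recording(data=data, sampling_rate_hz=10.0))
        sw = nn.metric_curves(corr, grid=nn.SparsityGrid(step=0.05), n_nulls=0)
        prof = nn.subject_profile("sub-01", sw)
        report = nn.identify_hubs(prof.nodal_aucs)
        assert report.flags["k_nodal"][0]


class TestProfilesAndWindow:
    def test_common_defined_window_excludes_edgeless_point(self, demo_corr):
        sw = nn.metric_curves(demo_corr, grid=nn.SparsityGrid(step=0.1), n_nulls=0)
        window = nn.common_defined_window([sw.curves], sw.grid)
        assert window[0] > 0.0 and window[1] == pytest.approx(1.0)

    def test_subject_profile_contains_all_aucs(self, demo_corr):
        sw = nn.metric_curves(demo_corr, grid=nn.SparsityGrid(step=0.1), n_nulls=0)
        prof = nn.subject_profile("s", sw, window=(0.1, 1.0))
        assert set(prof.global_aucs) == {"c_p", "l_p", "e_glob", "e_loc"}
        assert set(prof.nodal_aucs) == {"k_nodal", "e_nodal", "n_bc"}
        assert all(len(v) == 8 for v in prof.nodal_aucs.values())
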