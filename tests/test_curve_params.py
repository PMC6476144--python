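import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nodedce.clustering import assign_cluster_roles, kmeans_segment
from nodedce.curve_params import (
    FitError,
    auc,
    curve_parameters,
    extract_all,
    wash_in,
    wash_out,
    washout_window,
)


class TestAuc:
    def test_zero_curve(self):
        assert auc(np.zeros(70), 46 / 70) == 0.0

    def test_constant_curve_is_rectangle(self):
        # constant 1 from the last baseline frame over a 40-minute window:
        # 41 frames 1 minute apart -> 40 trapezoid panels of area 1
        curve = np.ones(43)
        assert auc(curve, frame_interval=1.0, n_baseline=3) == pytest.approx(40.0)

    def test_matches_oversampled_riemann_oracle(self):
        rng = np.random.default_rng(0)
        n, dt, n_baseline = 70, 46 / 70, 3
        curve = rng.normal(size=n)
        got = auc(curve, dt, n_baseline)
        # 10x oversampling of the piecewise-linear interpolant
        t = np.arange(n_baseline - 1, n) * dt
        fine_t = np.linspace(t[0], t[-1], (len(t) - 1) * 10 + 1)
        fine = np.interp(fine_t, t, curve[n_baseline - 1 :])
        mid = 0.5 * (fine[1:] + fine[:-1])
        oracle = float((mid * np.diff(fine_t)).sum())
        assert got == pytest.approx(oracle, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(
        curve=arrays(float, 50, elements=st.floats(-10, 10)),
        scale=st.floats(0.01, 100),
    )
    def test_linearity(self, curve, scale):
        assert auc(scale * curve, 0.5) == pytest.approx(
            scale * auc(curve, 0.5), rel=1e-9, abs=1e-9
        )

    @settings(max_examples=50, derandomize=True)
    @given(curve=arrays(float, 70, elements=st.floats(-5, 5)))
    def test_washout_matches_ols_oracle_on_arbitrary_curves(self, curve):
        dt = 46 / 70
        got = wash_out(curve, dt)
        t = np.arange(40) * dt
        y = curve[-40:]
        slope = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        assert got == pytest.approx(slope, abs=1e-10)


class TestWashIn:
    def test_direct_evaluation(self):
        curve = np.array([0, 0, 0, 0.5, 1.2, 1.5])
        got = wash_in(curve, n_baseline=3, frame_interval=1.0, normalizer=1.5)
        assert got == pytest.approx(0.7 / 1.5)

    def test_linear_rise_gives_constant_slope(self):
        curve = np.concatenate([np.zeros(3), 0.25 * np.arange(1, 11)])
        got = wash_in(curve, n_baseline=3, frame_interval=0.5, normalizer=2.5)
        assert got == pytest.approx(0.5 / 2.5)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        rise = np.sort(rng.uniform(0, 2, 20))
        fall = rise[-1] * np.exp(-0.1 * np.arange(1, 31))
        curve = np.concatenate([np.zeros(3), rise, fall])
        dt, norm = 46 / 70, float(curve.max())
        got = wash_in(curve, 3, dt, norm)
        peak = int(np.argmax(curve))
        oracle = max(
            (curve[i + 1] - curve[i]) / dt for i in range(2, peak)
        ) / norm
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_no_rise_returns_zero_with_warning(self):
        curve = np.concatenate([[0, 0, 1.0], -np.arange(1, 8) * 0.1])
        with pytest.warns(UserWarning, match="does not rise"):
            assert wash_in(curve, 3, 1.0) == 0.0


class TestWashOut:
    def test_exactly_linear_tail(self):
        """A linear tail of slope -0.02 per frame at 46/70 min per frame,
        normalized by 2.0, gives (-0.02*70/46)/2.0."""
        dt = 46 / 70
        curve = np.concatenate([np.zeros(3), 2.0 - 0.02 * np.arange(67)])
        got = wash_out(curve, dt, normalizer=2.0)
        assert got == pytest.approx((-0.02 / dt) / 2.0, rel=1e-9)
        assert got == pytest.approx(-0.0152173913, rel=1e-6)

    def test_constant_tail_is_zero(self):
        curve = np.concatenate([np.zeros(3), np.ones(67)])
        assert wash_out(curve, 46 / 70) == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        curve = rng.normal(size=70)
        dt = 46 / 70
        got = wash_out(curve, dt, normalizer=1.7)
        t = np.arange(40) * dt
        y = curve[-40:]
        slope = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        assert got == pytest.approx(slope / 1.7, abs=1e-10)

    def test_window_generalization(self):
        assert washout_window(70) == 40
        assert washout_window(100) == 70
        assert washout_window(50, washout_frames=20) == 20
        with pytest.raises(FitError):
            washout_window(30, washout_frames=35)
        with pytest.raises(FitError):
            washout_window(70, washout_frames=1)

    def test_decaying_tail_negative(self):
        curve = np.concatenate([np.zeros(3), np.exp(-0.05 * np.arange(67))])
        assert wash_out(curve, 46 / 70) < 0


class TestExtractAll:
    def test_phantom_parameters_match_true_curve_formulas(self, clean_phantom, clean_nde):
        """On the noiseless phantom, cluster parameters equal direct
        evaluation of the same formulas on the true compartment curves."""
        series, truth, spec = clean_phantom
        result = assign_cluster_roles(
            kmeans_segment(clean_nde, seed=0), series.frame_interval, series.n_baseline
        )
        table = extract_all(
            result, clean_nde.mean_curve(), series.frame_interval, series.n_baseline
        ).set_index("cluster")

        scale = spec.baseline_signal / clean_nde.de_max_muscle
        n_in = truth.inner_mask.sum()
        n_node = truth.node_mask.sum()
        mean_true = (
            n_in * truth.true_curves["inner"] + (n_node - n_in) * truth.true_curves["outer"]
        ) / n_node
        normalizer = scale * mean_true.max()
        for role in ("inner", "outer"):
            true_nde = scale * truth.true_curves[role]
            p = curve_parameters(
                true_nde, series.n_baseline, series.frame_interval, normalizer
            )
            assert table.loc[role, "auc"] == pytest.approx(p.auc, abs=1e-6)
            assert table.loc[role, "wash_in"] == pytest.approx(p.wash_in, abs=1e-6)
            assert table.loc[role, "wash_out"] == pytest.approx(p.wash_out, abs=1e-6)

    def test_washout_of_inner_cluster_matches_true_curve_ols(self, clean_phantom, clean_nde):
        series, truth, spec = clean_phantom
        result = assign_cluster_roles(
            kmeans_segment(clean_nde, seed=0), series.frame_interval, series.n_baseline
        )
        got = wash_out(result.cluster_curves["inner"], series.frame_interval)
        scale = spec.baseline_signal / clean_nde.de_max_muscle
        expected = wash_out(scale * truth.true_curves["inner"], series.frame_interval)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_volume_fractions_count_pixels(self, clean_phantom, clean_nde):
        series, truth, _ = clean_phantom
        result = assign_cluster_roles(
            kmeans_segment(clean_nde, seed=0), series.frame_interval, series.n_baseline
        )
        expected = 100.0 * truth.inner_mask.sum() / truth.node_mask.sum()
        assert result.volume_pct["inner"] == pytest.approx(expected)

    def test_normalizer_shared_between_clusters(self, clean_phantom, clean_nde):
        series, _, _ = clean_phantom
        result = assign_cluster_roles(
            kmeans_segment(clean_nde, seed=0), series.frame_interval, series.n_baseline
        )
        node_mean = clean_nde.mean_curve()
        table = extract_all(result, node_mean, series.frame_interval, series.n_baseline)
        norm = float(node_mean.max())
        for _, row in table.iterrows():
            raw = wash_out(result.cluster_curves[row["cluster"]], series.frame_interval)
            assert row["wash_out"] == pytest.approx(raw / norm, rel=1e-12)

    def test_schema_matches_packaged_table(self, clean_phantom, clean_nde):
        from nodedce.image_io import PARAM_COLUMNS

        series, _, _ = clean_phantom
        result = assign_cluster_roles(
            kmeans_segment(clean_nde, seed=0), series.frame_interval, series.n_baseline
        )
        table = extract_all(result, clean_nde.mean_curve(), series.frame_interval, 3)
        assert list(table.columns) == PARAM_COLUMNS
        assert table["volume_pct"].sum() == pytest.approx(100.0)
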