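import networkx as nx
import numpy as np
import pytest

from diffdim import (
    DiffusionParams,
    Graph,
    fractal_dimension_baseline,
    global_dimension,
    line_graph,
    local_dimension,
    relative_dimension_from_peak,
    relative_dimension_matrix,
    torus_graph,
)
from diffdim.dimension import FOUR_E_PI, RelativeDimensionMatrix, relative_dimension_row

from conftest import random_connected_graph


class TestPeakInversion:
    @pytest.mark.parametrize("d", [1.0, 2.0, 3.0])
    @pytest.mark.parametrize("t_hat", [0.01, 0.1, 1.0])
    def test_gaussian_forward_construction_inverts_exactly(self, d, t_hat):
        """Amplitudes built from the d-dimensional Gaussian peak law recover d."""
        p_hat = (FOUR_E_PI * t_hat) ** (-d / 2)
        assert relative_dimension_from_peak(t_hat, p_hat) == pytest.approx(d, abs=1e-12)

    def test_sigma_rescaling(self):
        p_hat = (FOUR_E_PI * 2.0 * 0.7) ** (-1.0)
        assert relative_dimension_from_peak(0.7, p_hat, sigma=2.0) == pytest.approx(2.0)

    def test_zero_log_denominator_is_undefined(self):
        t = 1.0 / FOUR_E_PI
        assert np.isnan(relative_dimension_from_peak(t, 0.5))

    def test_invalid_inputs_flagged_not_raised(self):
        assert np.isnan(relative_dimension_from_peak(-1.0, 0.5))
        assert np.isnan(relative_dimension_from_peak(0.5, 0.0))


class TestRelativeDimensionMatrix:
    def test_symmetry_on_random_graphs(self):
        """d_ij = d_ji wherever both defined, with degree-inverse masses."""
        rng = np.random.default_rng(21)
        for _ in range(50):
            g = random_connected_graph(rng, n_max=30)
            rdm = relative_dimension_matrix(g, DiffusionParams(n_times=120))
            both = rdm.defined & rdm.defined.T
            if both.any():
                assert np.nanmax(np.abs(rdm.dimensions - rdm.dimensions.T)[both]) < 1e-3

    def test_matches_per_source_pipeline(self):
        """The streamed all-pairs path equals explicit single-source runs."""
        rng = np.random.default_rng(33)
        for _ in range(5):
            g = random_connected_graph(rng, n_max=15)
            rdm = relative_dimension_matrix(g)
            for i, node in enumerate(g.node_ids[:3]):
                row, peaks, _ = relative_dimension_row(g, node)
                np.testing.assert_array_equal(np.isnan(row), ~rdm.defined[i])
                both = rdm.defined[i]
                if both.any():
                    np.testing.assert_allclose(row[both], rdm.dimensions[i, both],
                                               rtol=1e-8)

    def test_two_node_graph_all_undefined(self, two_node_graph):
        rdm = relative_dimension_matrix(two_node_graph)
        assert not rdm.defined.any()  # monotone trajectories, no interior peak

    def test_diagonal_undefined(self, path3):
        rdm = relative_dimension_matrix(path3)
        assert not rdm.defined.diagonal().any()

    def test_line_graph_plateau_near_one(self):
        g = line_graph(500)
        rdm = relative_dimension_matrix(g)
        near = rdm.dimensions[165, 115:216]
        defined = near[~np.isnan(near)]
        assert len(defined) > 50
        assert abs(np.median(defined) - 1.0) < 0.15

    def test_long_form_export(self, tmp_path, path3):
        rdm = relative_dimension_matrix(line_graph(30))
        df = rdm.to_long_dataframe()
        assert set(df.columns) == {"source", "target", "dimension", "t_hat"}
        assert (df["dimension"] > 0).all()
        rdm.to_csv(tmp_path / "rdm.csv")
        assert (tmp_path / "rdm.csv").exists()


def _toy_rdm(dims, times, taus=None):
    dims = np.asarray(dims, dtype=float)
    times = np.asarray(times, dtype=float)
    return RelativeDimensionMatrix(
        dimensions=dims, peak_times=times, peak_amplitudes=np.full_like(dims, 0.1),
        taus=taus if taus is not None else np.logspace(-2, 1, 60),
        spectral_gap=1.0, mean_degree=2.0)


class TestLocalDimension:
    def test_contributing_counts_monotone_and_values_bracketed(self):
        g = line_graph(200)
        rdm = relative_dimension_matrix(g)
        ldf = local_dimension(rdm)
        assert np.all(np.diff(ldf.counts, axis=1) >= 0)
        lo = np.nanmin(rdm.dimensions, axis=1)
        hi = np.nanmax(rdm.dimensions, axis=1)
        defined = ldf.defined
        for i in range(0, 200, 40):
            vals = ldf.values[i, defined[i]]
            if len(vals):
                assert np.all(vals >= lo[i] - 1e-12)
                assert np.all(vals <= hi[i] + 1e-12)

    def test_undefined_before_first_peak(self):
        nan = np.nan
        dims = [[nan, 1.5, 2.0], [1.5, nan, nan], [2.0, nan, nan]]
        times = [[nan, 0.5, 2.0], [0.5, nan, nan], [2.0, nan, nan]]
        ldf = local_dimension(_toy_rdm(dims, times), taus=np.array([0.1, 1.0, 3.0]))
        assert np.isnan(ldf.values[0, 0])  # no target peaked yet
        assert ldf.values[0, 1] == pytest.approx(1.5)  # only the early peak
        assert ldf.values[0, 2] == pytest.approx(1.75)  # both targets
        assert np.all(np.isnan(ldf.values[1, :1]))

    def test_strict_inequality_at_peak_time(self):
        dims = [[np.nan, 2.0], [2.0, np.nan]]
        times = [[np.nan, 1.0], [1.0, np.nan]]
        ldf = local_dimension(_toy_rdm(dims, times), taus=np.array([1.0, 1.0001]))
        assert np.isnan(ldf.values[0, 0])  # 1[t̂ < τ] is strict
        assert ldf.values[0, 1] == pytest.approx(2.0)


class TestGlobalDimension:
    def test_constant_relative_dimension_gives_constant_curve(self):
        n = 5
        dims = np.full((n, n), 1.7)
        np.fill_diagonal(dims, np.nan)
        times = np.full((n, n), 0.3)
        np.fill_diagonal(times, np.nan)
        curve = global_dimension(local_dimension(_toy_rdm(dims, times)))
        defined = ~np.isnan(curve.values)
        assert defined.any()
        np.testing.assert_allclose(curve.values[defined], 1.7)
        assert curve.max_value == pytest.approx(1.7)

    def test_line_peak_exceeds_ring_behavior(self):
        """The bounded line shows an interior maximum below the ring's plateau."""
        from diffdim import ring_graph

        line_curve = _global_curve(line_graph(100))
        ring_curve = _global_curve(ring_graph(100))
        assert ring_curve.max_value > line_curve.max_value
        # the line's maximum is attained strictly inside the scale range
        taus = line_curve.taus
        assert taus[0] < line_curve.argmax_tau < taus[-1]

    def test_empty_scale_is_nan(self):
        dims = np.array([[np.nan, 1.0], [1.0, np.nan]])
        times = np.array([[np.nan, 5.0], [5.0, np.nan]])
        curve = global_dimension(
            local_dimension(_toy_rdm(dims, times), taus=np.array([0.1, 10.0])))
        assert np.isnan(curve.values[0])
        assert curve.values[1] == pytest.approx(1.0)


def _global_curve(g):
    rdm = relative_dimension_matrix(g)
    return global_dimension(local_dimension(rdm))


class TestFractalBaseline:
    def test_long_path_central_slope_near_one(self):
        g = line_graph(501)
        # M(r) = 2r + 1 from the centre; slope of log M vs log r tends to 1
        est = fractal_dimension_baseline(g, 250, r_max=20)
        assert est == pytest.approx(1.0, abs=0.15)

    def test_torus_interior_two_dimensional_scaling(self):
        g = torus_graph(30, 30)
        node = g.node_ids[0]
        est = fractal_dimension_baseline(g, node, r_max=14)
        # independent oracle: on the 4-neighbour torus M(r) = 1 + 2r(r+1)
        # for r below half the side; the log-log least-squares slope of that
        # count is 1.7205 at r_max = 14 (it approaches 2 only asymptotically,
        # the small-r volume biasing the fit downward)
        r = np.arange(1, 15)
        expected = np.polyfit(np.log(r), np.log(1 + 2 * r * (r + 1)), 1)[0]
        assert est == pytest.approx(expected, abs=1e-9)
        assert est == pytest.approx(1.7205, abs=1e-3)
        # still clearly separates the 2-D torus from a 1-D line
        line_est = fractal_dimension_baseline(line_graph(501), 250, r_max=14)
        assert est > line_est + 0.5

    def test_complete_graph_degenerate(self):
        g = Graph.from_networkx(nx.complete_graph(8))
        with pytest.warns(UserWarning, match="truncating"):
            with pytest.raises(ValueError, match="degenerate"):
                fractal_dimension_baseline(g, 0, r_max=5)

    def test_r_max_truncated_with_warning(self):
        g = line_graph(10)
        with pytest.warns(UserWarning, match="truncating"):
            fractal_dimension_baseline(g, 0, r_max=50)

    def test_r_max_validation(self, path3):
        with pytest.raises(ValueError):
            fractal_dimension_baseline(path3, 0, r_max=1)
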