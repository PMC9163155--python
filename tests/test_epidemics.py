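import random

import networkx as nx
import numpy as np
import pytest

from diffdim import (
    Graph,
    SIRConfig,
    default_beta_grid,
    dimension_infectiousness_correlation,
    linear_beta_grid,
    node_infectiousness,
    simulate_sir,
)
from diffdim.dimension import LocalDimensionField
from diffdim.epidemics import InfectiousnessTable


@pytest.fixture
def small_world() -> Graph:
    return Graph.from_networkx(nx.connected_watts_strogatz_graph(50, 6, 0.1, seed=3))


class TestSimulateSir:
    def test_zero_transmission_infects_seed_only(self, small_world):
        rng = random.Random(0)
        assert simulate_sir(small_world, 0.0, 1.0, 0, rng) == 1

    def test_huge_transmission_sweeps_graph(self, small_world):
        rng = random.Random(1)
        n = small_world.n_nodes
        sizes = [simulate_sir(small_world, 1000.0, 1.0, 0, rng) for _ in range(100)]
        assert np.mean(sizes) >= 0.99 * n

    def test_star_hub_expected_final_size(self):
        """Branching oracle: from the hub each leaf is reached independently
        with probability β/(β+γ), so E[removed] = 1 + (N-1)/2 at β = γ."""
        g = Graph.from_networkx(nx.star_graph(20))
        rng = random.Random(7)
        n_runs = 4000
        sizes = [simulate_sir(g, 1.0, 1.0, 0, rng) for _ in range(n_runs)]
        expected = 1 + 20 / 2
        se = np.std(sizes) / np.sqrt(n_runs)
        assert abs(np.mean(sizes) - expected) < 4 * se + 0.05

    def test_seeded_bit_reproducibility(self, small_world):
        a = [simulate_sir(small_world, 0.3, 1.0, 5, random.Random(42)) for _ in range(3)]
        b = [simulate_sir(small_world, 0.3, 1.0, 5, random.Random(42)) for _ in range(3)]
        assert a == b

    def test_invalid_rates(self, small_world):
        with pytest.raises(ValueError):
            simulate_sir(small_world, -0.1, 1.0, 0, random.Random(0))


class TestNodeInfectiousness:
    def test_zero_beta_grid(self, small_world):
        cfg = SIRConfig(beta_grid=np.array([0.0]), n_realizations=5, seed=0)
        table = node_infectiousness(small_world, cfg)
        np.testing.assert_array_equal(table.mean_removed, 1.0)
        assert table.beta_crit is None  # never reaches N/2: flagged undefined

    def test_beta_crit_is_upper_grid_point_of_crossing(self):
        table = InfectiousnessTable(
            betas=np.array([0.1, 0.2, 0.3]),
            mean_removed=np.tile([[2.0, 4.0, 9.0]], (10, 1)))
        # population mean crosses N/2 = 5 between 0.2 and 0.3
        assert table.beta_crit == pytest.approx(0.3)
        assert table.beta_crit_index == 2

    def test_small_world_transition(self, small_world):
        cfg = SIRConfig(beta_grid=default_beta_grid(small_world, n_points=6),
                        n_realizations=60, seed=9)
        table = node_infectiousness(small_world, cfg)
        pop = table.population_mean
        n = small_world.n_nodes
        assert pop[0] < n / 4
        assert pop[-1] > n / 2
        assert table.beta_crit is not None

    def test_population_mean_monotone_in_beta(self, small_world):
        cfg = SIRConfig(beta_grid=linear_beta_grid(0.8, 6),
                        n_realizations=400, seed=2)
        table = node_infectiousness(small_world, cfg)
        diffs = np.diff(table.population_mean)
        assert np.all(diffs > -0.5)  # non-decreasing within Monte-Carlo error

    def test_reproducible(self, small_world):
        cfg = SIRConfig(beta_grid=np.array([0.2]), n_realizations=30, seed=5)
        t1 = node_infectiousness(small_world, cfg)
        t2 = node_infectiousness(small_world, cfg)
        np.testing.assert_array_equal(t1.mean_removed, t2.mean_removed)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SIRConfig(beta_grid=np.array([-0.1]))
        with pytest.raises(ValueError):
            SIRConfig(beta_grid=np.array([0.1]), gamma=0.0)
        with pytest.raises(ValueError):
            SIRConfig(beta_grid=np.array([0.1]), n_realizations=0)


def _field(values, taus):
    values = np.asarray(values, dtype=float)
    return LocalDimensionField(taus=np.asarray(taus, dtype=float), values=values,
                               counts=np.ones_like(values, dtype=int))


class TestCorrelationSurface:
    def test_perfect_correlation_when_infectiousness_equals_dimension(self):
        rng = np.random.default_rng(0)
        d0 = rng.uniform(1, 3, size=20)
        ldf = _field(np.column_stack([d0, d0 + rng.normal(0, 1, 20)]), [0.1, 1.0])
        table = InfectiousnessTable(betas=np.array([0.2, 0.4]),
                                    mean_removed=np.column_stack([d0, d0]))
        surf = dimension_infectiousness_correlation(ldf, table)
        np.testing.assert_allclose(surf.correlations[0], 1.0)
        assert np.all(surf.r_star >= surf.correlations[1])
        assert surf.tau_star[0] == pytest.approx(0.1)

    def test_constant_infectiousness_flagged_nan(self):
        ldf = _field(np.linspace(1, 2, 10)[:, None], [0.5])
        table = InfectiousnessTable(betas=np.array([0.1]),
                                    mean_removed=np.full((10, 1), 3.0))
        surf = dimension_infectiousness_correlation(ldf, table)
        assert np.isnan(surf.correlations).all()

    def test_under_three_defined_nodes_flagged_nan(self):
        vals = np.full((10, 1), np.nan)
        vals[:2, 0] = [1.0, 2.0]
        ldf = _field(vals, [0.5])
        table = InfectiousnessTable(betas=np.array([0.1]),
                                    mean_removed=np.random.default_rng(1).uniform(1, 5, (10, 1)))
        surf = dimension_infectiousness_correlation(ldf, table)
        assert np.isnan(surf.correlations).all()

    def test_node_set_mismatch(self):
        ldf = _field(np.ones((5, 1)), [0.5])
        table = InfectiousnessTable(betas=np.array([0.1]),
                                    mean_removed=np.ones((6, 1)))
        with pytest.raises(ValueError, match="node set"):
            dimension_infectiousness_correlation(ldf, table)

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(1, 4, size=(30, 3))
        inf = rng.uniform(1, 30, size=(30, 2))
        surf = dimension_infectiousness_correlation(
            _field(vals, [0.1, 0.5, 1.0]),
            InfectiousnessTable(betas=np.array([0.2, 0.5]), mean_removed=inf))
        for s in range(3):
            for b in range(2):
                expected = np.corrcoef(vals[:, s], inf[:, b])[0, 1]
                assert surf.correlations[s, b] == pytest.approx(expected)
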