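import itertools
import math

import numpy as np
import pytest

import networkx as nx

from edgefront.expansion_geo import (
    DistanceTable,
    UnreachableError,
    diversity_distance_regression,
    haversine_km,
    least_cost_distance,
    distance_table,
    psi_from_frequencies,
    psi_matrix_and_ranking,
    psi_pair,
)
from edgefront.simdata import ExpansionConfig, make_toy_ocean_grid, simulate_expansion

from conftest import make_gm, make_pm


class TestLeastCost:
    def test_corner_to_corner_all_water(self):
        grid = make_toy_ocean_grid(3, 3)
        d = least_cost_distance(grid, (0, 0), (2, 2))
        assert d == pytest.approx(2 * math.sqrt(2))

    def test_center_land_detour(self):
        grid = make_toy_ocean_grid(3, 3, land_cells=[(1, 1)])
        d = least_cost_distance(grid, (0, 0), (2, 2))
        assert d == pytest.approx(2 + math.sqrt(2))

    def test_waypoint_never_shortens(self):
        grid = make_toy_ocean_grid(4, 4, land_cells=[(1, 1), (2, 2)])
        free = least_cost_distance(grid, (0, 0), (3, 3))
        forced = least_cost_distance(grid, (0, 0), (3, 3), waypoints=[(0, 3)])
        assert forced >= free - 1e-12

    def test_unreachable(self):
        grid = make_toy_ocean_grid(3, 3, land_cells=[(1, 0), (1, 1), (1, 2)])
        with pytest.raises(UnreachableError):
            least_cost_distance(grid, (0, 0), (2, 2))

    def test_matches_brute_force_enumeration(self):
        # exhaustive simple-path enumeration oracle on grids <= 4x4
        rng = np.random.default_rng(9)
        for trial in range(5):
            land = [
                (int(r), int(c))
                for r, c in rng.integers(0, 4, size=(3, 2))
                if (r, c) not in ((0, 0), (3, 3))
            ]
            grid = make_toy_ocean_grid(4, 4, land_cells=land)
            g = grid.graph()
            src, dst = (0, 0), (3, 3)
            if not (g.has_node(src) and g.has_node(dst)):
                continue
            best = math.inf
            for path in nx.all_simple_paths(g, src, dst):
                w = sum(
                    g.edges[a, b]["weight"] for a, b in zip(path[:-1], path[1:])
                )
                best = min(best, w)
            if math.isinf(best):
                with pytest.raises(UnreachableError):
                    least_cost_distance(grid, src, dst)
            else:
                assert least_cost_distance(grid, src, dst) == pytest.approx(best)

    def test_triangle_inequality(self):
        grid = make_toy_ocean_grid(5, 5, land_cells=[(2, 1), (2, 2), (1, 3)])
        pts = [(0, 0), (4, 4), (0, 4), (4, 0)]
        for a, b, c in itertools.permutations(pts, 3):
            dab = least_cost_distance(grid, a, b)
            dac = least_cost_distance(grid, a, c)
            dcb = least_cost_distance(grid, c, b)
            assert dab <= dac + dcb + 1e-9

    def test_snap_tie_breaks_row_major(self):
        grid = make_toy_ocean_grid(3, 3, land_cells=[(1, 1)])
        # equidistant from (0,0), (0,1) and (1,0): first in row-major order wins
        assert grid.snap(0.5, 0.5) == (0, 0)

    def test_haversine_sanity(self):
        # one degree of latitude ~ 111.2 km
        assert haversine_km(0, 0, 1, 0) == pytest.approx(111.2, abs=0.3)

    def test_distance_table_origin_zero(self):
        grid = make_toy_ocean_grid(3, 3)
        sites = {"O": (0.0, 0.0), "X": (2.0, 2.0)}
        tab = distance_table(grid, sites, "O")
        assert tab.distances["O"] == 0.0
        assert tab.distances["X"] == pytest.approx(2 * math.sqrt(2))


class TestRegression:
    def _dist(self, xs):
        return DistanceTable(origin="a0", distances={f"a{i}": float(x) for i, x in enumerate(xs)})

    def test_exact_line(self):
        res = diversity_distance_regression(
            {"a0": 1.0, "a1": 3.0, "a2": 5.0}, self._dist([0, 1, 2])
        )
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_worked_toy(self):
        res = diversity_distance_regression(
            {"a0": 0.0, "a1": 1.0, "a2": 1.0}, self._dist([0, 1, 2])
        )
        assert res.slope == pytest.approx(0.5)
        assert res.r_squared == pytest.approx(0.75)
        assert res.p_value == pytest.approx(1.0 / 3.0)

    def test_constant_y(self):
        res = diversity_distance_regression(
            {"a0": 2.0, "a1": 2.0, "a2": 2.0}, self._dist([0, 1, 2])
        )
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_zero_x_variance(self):
        with pytest.raises(ValueError, match="variance"):
            diversity_distance_regression(
                {"a0": 1.0, "a1": 2.0, "a2": 3.0},
                DistanceTable(origin="a0", distances={"a0": 0.0, "a1": 0.0, "a2": 0.0}),
            )

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 100, size=8)
        y = rng.normal(size=8)
        res = diversity_distance_regression(
            {f"a{i}": y[i] for i in range(8)},
            DistanceTable(origin="a0", distances={"a0": 0.0, **{f"a{i}": x[i] for i in range(1, 8)}}),
        )
        x[0] = 0.0
        beta = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert res.slope == pytest.approx(beta)
        assert res.intercept == pytest.approx(y.mean() - beta * x.mean())


class TestPsi:
    def test_worked_pair(self):
        assert psi_from_frequencies([0.1, 0.2], [0.3, 0.6]) == pytest.approx(-0.3)

    def test_identical_pops_zero(self):
        rng = np.random.default_rng(1)
        block = rng.binomial(2, 0.3, size=(10, 200))
        gm = make_gm(np.vstack([block, block]).tolist())
        pm = make_pm({f"s{i}": ("A" if i < 10 else "B") for i in range(20)})
        psi, used = psi_pair(gm, pm, "A", "B", subsample_n=10, seed=0)
        assert used > 0
        assert abs(psi) < 0.05

    def test_antisymmetry_exact(self):
        gm, pm, _ = simulate_expansion(ExpansionConfig(n_loci=500, seed=2))
        pij, _ = psi_pair(gm, pm, "D00", "D05", subsample_n=10, seed=7)
        pji, _ = psi_pair(gm, pm, "D05", "D00", subsample_n=10, seed=7)
        assert pij == pytest.approx(-pji, abs=0.0)

    def test_matrix_antisymmetry_entrywise(self):
        gm, pm, _ = simulate_expansion(
            ExpansionConfig(n_demes=4, samples_per_deme=8, n_loci=400, seed=3)
        )
        mat = psi_matrix_and_ranking(gm, pm, subsample_n=8, seed=1)
        assert np.allclose(mat.values, -mat.values.T)
        assert np.allclose(np.diag(mat.values), 0.0)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        calls = rng.binomial(2, rng.uniform(0.05, 0.5, 300), size=(16, 300))
        gm = make_gm(calls.tolist())
        pm1 = make_pm({f"s{i}": ("A" if i < 8 else "B") for i in range(16)})
        psi1, _ = psi_pair(gm, pm1, "A", "B", subsample_n=10, seed=5)
        # shuffle sample order within each population
        order = list(np.r_[np.random.default_rng(0).permutation(8),
                           8 + np.random.default_rng(1).permutation(8)])
        gm2 = gm.subset_samples([gm.samples[i] for i in order])
        psi2, _ = psi_pair(gm2, pm1, "A", "B", subsample_n=10, seed=5)
        assert psi1 == pytest.approx(psi2)

    def test_identical_pops_ranking_stable(self):
        rng = np.random.default_rng(8)
        block = rng.binomial(2, rng.uniform(0.1, 0.5, 200), size=(8, 200))
        gm = make_gm(np.vstack([block, block, block]).tolist())
        pm = make_pm({f"s{i}": f"P{i // 8}" for i in range(24)})
        m1 = psi_matrix_and_ranking(gm, pm, subsample_n=8, seed=0)
        m2 = psi_matrix_and_ranking(gm, pm, subsample_n=8, seed=0)
        assert np.allclose(m1.values, 0.0)
        assert m1.ranking == m2.ranking  # tie-break by label is stable

    def test_no_usable_loci_warns(self):
        gm = make_gm([[0], [0], [0], [0]])
        pm = make_pm({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        with pytest.warns(UserWarning):
            psi, used = psi_pair(gm, pm, "A", "B", subsample_n=4, seed=0)
        assert used == 0 and math.isnan(psi)

    def test_psi_ranking_recovers_origin(self):
        # stochastic recovery at reduced scale (acceptance runs the full 20x)
        wins = 0
        for seed in range(8):
            gm, pm, truth = simulate_expansion(ExpansionConfig(n_loci=3000, seed=seed))
            mat = psi_matrix_and_ranking(gm, pm, subsample_n=10, seed=seed + 100)
            wins += mat.ranking[0] == truth.origin_deme
        assert wins >= 6
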