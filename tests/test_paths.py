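"""Shortest paths, average-path profiles, normalization, peak/mean ratio."""

import numpy as np
import pytest

from reinet import (
    Network,
    ResidueProfile,
    ValidationError,
    all_pairs_shortest_paths,
    average_shortest_path_profile,
    build_energy_network,
    make_random_graph,
    normalize_profile,
    pair_energy_matrix,
    peak_to_average_ratio,
)
from _oracles import floyd_warshall


def path_graph(costs=(1.0, 1.0)):
    n = len(costs) + 1
    m = np.full((n, n), np.inf)
    for i, c in enumerate(costs):
        m[i, i + 1] = m[i + 1, i] = c
    return Network(costs=m, labels=[chr(97 + i) for i in range(n)],
                   directed=False, semantics="binary")


def make_profile(values, normalized=None, semantics="inv_energy"):
    values = np.asarray(values, float)
    return ResidueProfile(
        values=values,
        labels=[str(i) for i in range(len(values))],
        semantics=semantics,
        unreachable_count=np.zeros(len(values), int),
        normalized=normalized,
    )


class TestAllPairsShortestPaths:
    def test_path_graph(self):
        d = all_pairs_shortest_paths(path_graph()).values
        assert d[0, 2] == 2.0 and d[0, 1] == 1.0
        assert np.all(np.diag(d) == 0)

    def test_disconnected_components_are_infinite(self):
        net = make_random_graph(6, edge_prob=0.0, seed=1)
        d = all_pairs_shortest_paths(net).values
        off = ~np.eye(6, dtype=bool)
        assert np.all(np.isinf(d[off]))

    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_floyd_warshall(self, directed):
        for seed in range(10):
            net = make_random_graph(20, edge_prob=0.25, seed=seed, directed=directed)
            d = all_pairs_shortest_paths(net).values
            np.testing.assert_allclose(d, floyd_warshall(net.costs, directed), atol=1e-12)

    def test_triangle_inequality(self):
        net = make_random_graph(15, edge_prob=0.4, seed=3)
        d = all_pairs_shortest_paths(net).values
        finite = np.isfinite(d)
        for k in range(15):
            via = d[:, [k]] + d[[k], :]
            mask = finite & np.isfinite(via)
            assert np.all(d[mask] <= via[mask] + 1e-9)

    def test_rejects_nonpositive_costs(self):
        net = path_graph()
        net.costs[0, 1] = net.costs[1, 0] = 0.0  # corrupt after validation
        with pytest.raises(ValidationError):
            all_pairs_shortest_paths(net)


class TestProfile:
    def test_path_graph_hand_values(self):
        prof = average_shortest_path_profile(all_pairs_shortest_paths(path_graph()))
        np.testing.assert_allclose(prof.values, [1.5, 1.0, 1.5])

    def test_complete_graph_all_ones(self):
        n = 6
        costs = np.where(np.eye(n, dtype=bool), np.inf, 1.0)
        net = Network(costs=costs, labels=list("abcdef"), directed=False, semantics="binary")
        prof = average_shortest_path_profile(all_pairs_shortest_paths(net))
        np.testing.assert_allclose(prof.values, 1.0)

    def test_column_equals_row_average_when_symmetric(self):
        net = make_random_graph(25, edge_prob=0.3, seed=7)
        paths = all_pairs_shortest_paths(net)
        col = average_shortest_path_profile(paths, direction="incoming")
        row = average_shortest_path_profile(paths, direction="outgoing")
        np.testing.assert_allclose(col.values, row.values, atol=1e-12)

    def test_isolated_residue_gets_inf_with_warning(self):
        n = 25  # isolated node keeps unreachable fraction under the 10% limit
        costs = np.where(np.eye(n, dtype=bool), np.inf, 1.0)
        costs[n - 1, :] = costs[:, n - 1] = np.inf
        net = Network(costs=costs, labels=[str(i) for i in range(n)],
                      directed=False, semantics="binary")
        with pytest.warns(UserWarning, match="unreachable"):
            prof = average_shortest_path_profile(all_pairs_shortest_paths(net))
        assert np.isinf(prof.values[-1])
        assert prof.unreachable_count[-1] == n - 1

    def test_fragmented_network_rejected(self):
        net = make_random_graph(10, edge_prob=0.0, seed=1)
        with pytest.raises(ValidationError, match="unreachable"):
            average_shortest_path_profile(all_pairs_shortest_paths(net))


class TestNormalization:
    def test_mean_method(self):
        prof = normalize_profile(make_profile([2, 4, 6]), "mean")
        np.testing.assert_allclose(prof.values, [0.5, 1.0, 1.5])
        assert prof.normalized == "mean"

    def test_uniform_profile_all_ones(self):
        np.testing.assert_allclose(normalize_profile(make_profile([3, 3, 3])).values, 1.0)

    def test_minmax(self):
        np.testing.assert_allclose(
            normalize_profile(make_profile([2, 4, 6]), "minmax").values, [0, 0.5, 1]
        )

    def test_minmax_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            normalize_profile(make_profile([5, 5, 5]), "minmax")


class TestPeakToAverageRatio:
    def test_uniform_profile_gives_one(self):
        assert peak_to_average_ratio(make_profile([2, 2, 2]), "1") == pytest.approx(1.0)

    def test_hand_value(self):
        assert peak_to_average_ratio(make_profile([3, 1, 1, 1]), "0") == pytest.approx(2.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            peak_to_average_ratio(make_profile([1, 2]), "nope")

    def test_invariant_under_mean_normalization(self):
        prof = make_profile([2, 5, 3, 9])
        assert peak_to_average_ratio(prof, "3") == pytest.approx(
            peak_to_average_ratio(normalize_profile(prof), "3"), abs=1e-12
        )


class TestScaleInvariance:
    def test_uniform_cost_scaling(self):
        lam = 7.0
        net = make_random_graph(20, edge_prob=0.35, seed=11)
        scaled = Network(costs=net.costs * lam, labels=net.labels,
                         directed=False, semantics=net.semantics)
        p1 = all_pairs_shortest_paths(net)
        p2 = all_pairs_shortest_paths(scaled)
        finite = np.isfinite(p1.values)
        np.testing.assert_allclose(p2.values[finite], lam * p1.values[finite], rtol=1e-12)
        prof1 = normalize_profile(average_shortest_path_profile(p1))
        prof2 = normalize_profile(average_shortest_path_profile(p2))
        np.testing.assert_allclose(prof1.values, prof2.values, atol=1e-12)
        for lab in net.labels:
            r1 = peak_to_average_ratio(average_shortest_path_profile(p1), lab)
            r2 = peak_to_average_ratio(average_shortest_path_profile(p2), lab)
            assert r1 == pytest.approx(r2, abs=1e-12)


class TestEnergyNetworkMonotonicity:
    def test_strengthening_one_pair_never_lengthens_paths(self):
        from reinet import PairEnergyMatrix

        rng = np.random.default_rng(5)
        n = 12
        vals = rng.uniform(0.1, 2.0, (n, n))
        vals = np.triu(vals, 1)
        vals = vals + vals.T
        labels = [str(i) for i in range(n)]
        base = PairEnergyMatrix(values=vals, labels=labels, n_frames=1)
        d0 = all_pairs_shortest_paths(build_energy_network(base)).values
        stronger = vals.copy()
        stronger[2, 7] = stronger[7, 2] = vals[2, 7] * 10
        d1 = all_pairs_shortest_paths(
            build_energy_network(PairEnergyMatrix(values=stronger, labels=labels, n_frames=1))
        ).values
        assert np.all(d1 <= d0 + 1e-12)


class TestHubRecovery:
    def test_engineered_hub_attains_minimum(self):
        from reinet import make_hub_system

        topo, traj, hubs = make_hub_system(
            n_residues=20, hub_strength_factor=10.0, seed=20
        )
        m = pair_energy_matrix(topo, traj)
        prof = average_shortest_path_profile(
            all_pairs_shortest_paths(build_energy_network(m))
        )
        assert int(np.argmin(prof.values)) in hubs
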