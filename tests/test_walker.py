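"""Walk kernel invariants, z-score extraction, and the closed-form oracle."""

import numpy as np
import pytest

from plcdm import (
    MultilayerNetwork,
    WalkParams,
    build_transition_model,
    default_iteration_count,
    expected_visit_distribution,
    extract_community,
    run_plcdm,
    write_walk_result,
    zscore_transform,
)

from conftest import random_multilayer


def two_cliques_net():
    """Two 4-cliques {a..d} and {w..z} joined by one bridge edge d-w."""
    net = MultilayerNetwork()
    for group in (("a", "b", "c", "d"), ("w", "x", "y", "z")):
        for ix in range(4):
            for jx in range(ix + 1, 4):
                net.add_edge("L1", group[ix], group[jx])
    net.add_edge("L1", "d", "w")
    return net


class TestWalkParams:
    def test_defaults(self):
        p = WalkParams()
        assert p.jump_prob == 0.5
        assert p.layer_change_prob == 0.5
        assert p.iteration_count is None
        assert p.resolve_iterations(50) == default_iteration_count(50) == 100_000
        assert p.resolve_iterations(500) == 500_000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"iteration_count": 0},
            {"jump_prob": -0.1},
            {"jump_prob": 1.5},
            {"layer_change_prob": 2.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WalkParams(**kwargs)


class TestWalkInvariants:
    def test_count_identity(self, toy_net):
        model = build_transition_model(toy_net)
        params = WalkParams(iteration_count=10_000, rng_seed=5)
        res = run_plcdm(toy_net, model, "1", params)
        assert res.total_count == 1 + res.iterations + res.n_jumps

    def test_count_identity_multilayer(self, two_layer_net):
        model = build_transition_model(two_layer_net)
        params = WalkParams(iteration_count=5_000, rng_seed=11)
        res = run_plcdm(two_layer_net, model, "b", params)
        assert res.total_count == 1 + res.iterations + res.n_jumps

    def test_determinism(self, two_layer_net):
        model = build_transition_model(two_layer_net)
        params = WalkParams(iteration_count=2_000, rng_seed=123)
        r1 = run_plcdm(two_layer_net, model, "a", params)
        r2 = run_plcdm(two_layer_net, model, "a", params)
        assert r1.raw_counts == r2.raw_counts
        assert r1.n_jumps == r2.n_jumps
        assert r1.community == r2.community

    def test_different_rng_seeds_differ(self, toy_net):
        model = build_transition_model(toy_net)
        a = run_plcdm(toy_net, model, "1", WalkParams(iteration_count=2_000, rng_seed=1))
        b = run_plcdm(toy_net, model, "1", WalkParams(iteration_count=2_000, rng_seed=2))
        assert a.raw_counts != b.raw_counts

    def test_unknown_seed_raises(self, toy_net):
        model = build_transition_model(toy_net)
        with pytest.raises(KeyError):
            run_plcdm(toy_net, model, "nope")

    def test_unreachable_component_never_visited(self):
        # seed's component {a,b}; {c,d} unreachable without edges between them
        net = MultilayerNetwork()
        net.add_edge("L1", "a", "b")
        net.add_edge("L1", "c", "d")
        model = build_transition_model(net)
        res = run_plcdm(net, model, "a", WalkParams(iteration_count=5_000, rng_seed=0))
        assert res.raw_counts["c"] == 0
        assert res.raw_counts["d"] == 0
        assert res.community == {"a", "b"}

    def test_two_cliques_seed_community(self):
        net = two_cliques_net()
        model = build_transition_model(net)
        res = run_plcdm(net, model, "a", WalkParams(iteration_count=200_000, rng_seed=3))
        assert res.community == {"a", "b", "c", "d"}

    def test_isolated_seed_warns_and_returns_singleton(self):
        net = MultilayerNetwork()
        net.add_edge("L1", "a", "b")
        net.add_node("iso", "L1")
        model = build_transition_model(net)
        with pytest.warns(UserWarning, match="isolated"):
            res = run_plcdm(net, model, "iso", WalkParams(iteration_count=500))
        assert res.community == {"iso"}
        assert res.raw_counts["iso"] == res.total_count

    def test_jump_prob_one_pins_walker_to_seed_orbit(self, toy_net):
        model = build_transition_model(toy_net)
        res = run_plcdm(
            toy_net, model, "1", WalkParams(iteration_count=5_000, jump_prob=1.0)
        )
        # every iteration ends with a jump: the seed collects one score per
        # iteration plus the initial one
        assert res.n_jumps == res.iterations
        assert res.raw_counts["1"] >= res.iterations + 1
        assert max(res.raw_counts, key=res.raw_counts.get) == "1"


class TestZScores:
    def test_hand_example(self):
        counts = {"a": 4, "b": 2, "c": 0, "d": 0}
        z = zscore_transform(counts, {"a", "b", "c", "d"})
        # mean 1.5, population sd = sqrt(2.75)
        sd = np.sqrt(2.75)
        assert z["a"] == pytest.approx(2.5 / sd)
        assert z["b"] == pytest.approx(0.5 / sd)
        assert z["c"] == pytest.approx(-1.5 / sd)
        assert z["d"] == pytest.approx(-1.5 / sd)
        assert z["a"] == pytest.approx(1.50755672, abs=1e-6)

    def test_population_includes_unvisited_nodes(self):
        z = zscore_transform({"a": 10}, {"a", "b", "c"})
        assert set(z) == {"a", "b", "c"}
        assert z["b"] == z["c"] < 0 < z["a"]

    def test_constant_counts_give_all_zero(self):
        z = zscore_transform({"a": 3, "b": 3}, {"a", "b"})
        assert z == {"a": 0.0, "b": 0.0}

    def test_mean_zero_unit_variance(self):
        rng = np.random.default_rng(0)
        counts = {f"v{i}": int(c) for i, c in enumerate(rng.integers(0, 50, 20))}
        z = zscore_transform(counts, set(counts))
        vals = np.array(list(z.values()))
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std() == pytest.approx(1.0, abs=1e-12)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            zscore_transform({}, set())


class TestExtractCommunity:
    def test_strictly_positive_rule(self):
        z = {"a": 1.2, "b": 0.0, "c": -0.5}
        assert extract_community(z, "a") == {"a"}
        z["b"] = 0.1
        assert extract_community(z, "a") == {"a", "b"}

    def test_all_zero_falls_back_to_seed(self):
        assert extract_community({"a": 0.0, "b": 0.0}, "b") == {"b"}


class TestOracle:
    def test_two_node_path_splits_evenly_without_jumps(self):
        # deterministic alternation a <-> b: Cesàro limit scores each 1/2
        net = MultilayerNetwork()
        net.add_edge("L1", "a", "b")
        model = build_transition_model(net)
        dist = expected_visit_distribution(net, model, "a", 0.0, 0.0)
        assert dist["a"] == pytest.approx(0.5, abs=1e-9)
        assert dist["b"] == pytest.approx(0.5, abs=1e-9)

    def test_distribution_sums_to_one(self, two_layer_net):
        model = build_transition_model(two_layer_net)
        dist = expected_visit_distribution(two_layer_net, model, "a", 0.5, 0.5)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(p >= 0 for p in dist.values())

    def test_jump_prob_one_makes_seed_dominant(self, toy_net):
        model = build_transition_model(toy_net)
        dist = expected_visit_distribution(toy_net, model, "1", 1.0, 0.0)
        assert dist["1"] == max(dist.values())
        assert dist["1"] >= 0.5  # at least the jump increment every step

    def test_empirical_frequencies_converge_to_oracle(self, two_layer_net):
        model = build_transition_model(two_layer_net)
        params = WalkParams(iteration_count=1_000_000, rng_seed=7)
        res = run_plcdm(two_layer_net, model, "b", params)
        emp = {v: c / res.total_count for v, c in res.raw_counts.items()}
        exact = expected_visit_distribution(two_layer_net, model, "b", 0.5, 0.5)
        tv = 0.5 * sum(abs(emp[v] - exact[v]) for v in emp)
        assert tv < 0.02

    def test_empirical_convergence_two_cliques(self):
        net = two_cliques_net()
        model = build_transition_model(net)
        params = WalkParams(iteration_count=1_000_000, rng_seed=19)
        res = run_plcdm(net, model, "a", params)
        emp = {v: c / res.total_count for v, c in res.raw_counts.items()}
        exact = expected_visit_distribution(net, model, "a", 0.5, 0.5)
        tv = 0.5 * sum(abs(emp[v] - exact[v]) for v in emp)
        assert tv < 0.02
        # the oracle agrees with the sampled community structure: seed-side
        # clique mass strictly exceeds far-side mass
        assert min(exact[v] for v in "abcd") > max(exact[v] for v in "wxyz")

    def test_state_space_guard(self):
        net = random_multilayer(n_nodes=30, n_layers=3, edge_prob=0.2, seed=0)
        model = build_transition_model(net)
        with pytest.raises(ValueError, match="state space"):
            expected_visit_distribution(net, model, "v0", 0.5, 0.5, max_states=50)


class TestWalkResultIO:
    def test_write_walk_result_round_trip_fields(self, toy_net, tmp_path):
        model = build_transition_model(toy_net)
        res = run_plcdm(toy_net, model, "1", WalkParams(iteration_count=1_000))
        p = tmp_path / "res.tsv"
        write_walk_result(res, str(p), network_hash="abc123")
        text = p.read_text()
        assert "# seed\t1" in text
        assert "# network_hash\tabc123" in text
        rows = [l for l in text.splitlines() if not l.startswith(("#", "node"))]
        assert len(rows) == toy_net.n_nodes
        counts = {r.split("\t")[0]: int(r.split("\t")[1]) for r in rows}
        assert counts == res.raw_counts
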