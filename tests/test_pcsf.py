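"""Edge weighting, cumulative prizes, and the two PCSF solvers."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from omnitide import pcsf
from .conftest import random_digraph


def line_graph(costs: dict[tuple[str, str], float]) -> nx.DiGraph:
    g = nx.DiGraph()
    for (u, v), c in costs.items():
        g.add_edge(u, v, cost=c, weight=1 - c, types=("signaling",))
    return g


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


def test_edge_weight_is_outdegree_reciprocal():
    df = pd.DataFrame(
        {
            "source": ["a", "a", "a", "a", "b"],
            "target": ["b", "c", "d", "e", "c"],
            "type": ["signaling"] * 5,
        }
    )
    g = pcsf.assign_edge_weights(df)
    assert g["a"]["b"]["weight"] == pytest.approx(0.25)
    assert g["a"]["b"]["cost"] == pytest.approx(0.75)
    assert g["b"]["c"]["weight"] == pytest.approx(1.0)
    assert g["b"]["c"]["cost"] == pytest.approx(0.0)


def test_outgoing_weights_sum_to_one_for_every_source():
    rng = np.random.default_rng(0)
    g = random_digraph(rng, 10, 20)
    df = pd.DataFrame(
        {"source": [u for u, _ in g.edges], "target": [v for _, v in g.edges]}
    )
    h = pcsf.assign_edge_weights(df)
    for u in h.nodes:
        if h.out_degree(u):
            assert sum(h[u][v]["weight"] for _, v in h.out_edges(u)) == pytest.approx(1.0)


def test_self_loops_dropped_and_parallel_types_merged():
    df = pd.DataFrame(
        {
            "source": ["a", "a", "a"],
            "target": ["a", "b", "b"],
            "type": ["signaling", "kinase->target", "TF->target"],
        }
    )
    g = pcsf.assign_edge_weights(df)
    assert not g.has_edge("a", "a")
    assert g["a"]["b"]["types"] == ("TF->target", "kinase->target")
    assert g["a"]["b"]["weight"] == pytest.approx(1.0)


def test_merge_causal_edges_recomputes_weights():
    base = pd.DataFrame({"source": ["x"], "target": ["y"], "type": ["signaling"]})
    assert pcsf.merge_causal_edges(base, None).equals(base)
    extra = pd.DataFrame({"source": ["x"], "target": ["z"], "sign": ["+"]})
    merged = pcsf.merge_causal_edges(base, extra)
    g = pcsf.assign_edge_weights(merged)
    assert g["x"]["y"]["weight"] == pytest.approx(0.5)  # kout(x) rose to 2
    assert g["x"]["z"]["sign"] == "+"


# ---------------------------------------------------------------------------
# prizes
# ---------------------------------------------------------------------------


def test_cumulative_prize_activation_and_max_over_measurements():
    cols = [f"t{i}" for i in range(1, 10)]
    lfc = pd.DataFrame(0.0, index=["A", "B_S1", "B_S2", "C"], columns=cols)
    lfc.loc["A", "t3"] = 1.2
    lfc.loc["B_S1", "t2"] = 0.8
    lfc.loc["B_S2", "t2"] = -1.5
    lfc.loc["C", "t5"] = 1.0  # exactly at threshold: NOT prized (strict >)
    sched = pcsf.cumulative_prizes({"PHOS": lfc})
    assert list(sched.loc["A"]) == [0, 0, 1, 1, 1, 1, 1, 1, 1]
    assert list(sched.loc["B"]) == [0, 1, 1, 1, 1, 1, 1, 1, 1]
    assert list(sched.loc["C"]) == [0] * 9
    # monotone by construction
    assert (np.diff(sched.to_numpy(), axis=1) >= 0).all()


def test_attach_dummy_adds_one_edge_per_root():
    g = line_graph({("A", "b"): 0.5, ("B", "c"): 0.5})
    params = pcsf.PCSFParams(roots=("A", "B"))
    aug = pcsf.attach_dummy(g, params)
    assert aug.out_degree(pcsf.DUMMY) == 2
    assert aug[pcsf.DUMMY]["A"]["cost"] == params.omega
    with pytest.raises(ValueError, match="missing root"):
        pcsf.attach_dummy(g, pcsf.PCSFParams(roots=("A", "ZZZ")))
    with pytest.raises(ValueError):
        pcsf.attach_dummy(g, pcsf.PCSFParams(roots=()))


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


def test_three_node_path_connect_or_forfeit_by_beta():
    g = line_graph({("R", "a"): 0.5, ("a", "b"): 0.5})
    p10 = pcsf.PCSFParams(beta=10, omega=5, depth=5, mu=0, roots=("R",))
    for mode in ("exact", "heuristic"):
        f = pcsf.solve_pcsf(g, {"b": 1.0}, p10, mode=mode)
        assert set(f.nodes) == {"R", "a", "b"}
        assert f.objective == pytest.approx(6.0)
    p5 = pcsf.PCSFParams(beta=5, omega=5, depth=5, mu=0, roots=("R",))
    for mode in ("exact", "heuristic"):
        f = pcsf.solve_pcsf(g, {"b": 1.0}, p5, mode=mode)
        assert f.nodes == {} and f.objective == pytest.approx(5.0)


def test_no_prizes_gives_empty_forest():
    g = line_graph({("R", "a"): 0.1})
    f = pcsf.solve_pcsf(g, {}, pcsf.PCSFParams(roots=("R",)), mode="exact")
    assert f.nodes == {} and f.objective == 0.0


def test_unreachable_prize_is_forfeited_not_an_error():
    g = line_graph({("R", "a"): 0.1, ("x", "y"): 0.1})
    params = pcsf.PCSFParams(beta=10, omega=5, roots=("R",))
    f = pcsf.solve_pcsf(g, {"y": 1.0}, params, mode="exact")
    assert "y" not in f.nodes
    assert f.objective == pytest.approx(10.0)


def test_depth_constraint_is_enforced():
    chain = {(f"v{i}", f"v{i+1}"): 0.0 for i in range(8)}
    chain[("R", "v0")] = 0.0
    g = line_graph(chain)
    params = pcsf.PCSFParams(beta=100, omega=1, depth=3, roots=("R",))
    for mode in ("exact", "heuristic"):
        f = pcsf.solve_pcsf(g, {"v7": 1.0}, params, mode=mode)
        assert all(d <= 3 for d in f.nodes.values())
        assert "v7" not in f.nodes


def test_forest_objective_rejects_invalid_certificates():
    g = line_graph({("R", "a"): 0.5, ("a", "b"): 0.5})
    params = pcsf.PCSFParams(roots=("R",))
    bad = pcsf.Forest({"R": 0, "b": 1}, [("R", "b")], ["R"], 0.0)
    with pytest.raises(ValueError, match="not in the scaffold"):
        pcsf.forest_objective(bad, {}, params, g)
    deep = pcsf.Forest(
        {"R": 0, "a": 1, "b": 2}, [("R", "a"), ("a", "b")], ["R"], 0.0
    )
    shallow_params = pcsf.PCSFParams(roots=("R",), depth=1)
    with pytest.raises(ValueError, match="depth"):
        pcsf.forest_objective(deep, {}, shallow_params, g)
    with pytest.raises(ValueError):
        pcsf.Forest({"R": 0, "a": 1}, [], ["R"], 0.0)  # |E| != |V| - kappa


def test_exact_mode_refuses_oversized_instances():
    rng = np.random.default_rng(1)
    g = random_digraph(rng, 15, 40)
    with pytest.raises(ValueError, match="exact mode"):
        pcsf.solve_pcsf(g, {}, pcsf.PCSFParams(roots=("n0",)), mode="exact")


def test_degree_penalty_mu_excludes_hubs():
    # hub h with degree 5; mu large enough that including it is penalized
    costs = {("R", "h"): 0.1}
    for i in range(4):
        costs[("h", f"x{i}")] = 0.1
    g = line_graph(costs)
    base = pcsf.PCSFParams(beta=1, omega=0.5, depth=5, mu=0, roots=("R",))
    f0 = pcsf.solve_pcsf(g, {"h": 1.0}, base, mode="exact")
    assert "h" in f0.nodes
    punitive = pcsf.PCSFParams(beta=1, omega=0.5, depth=5, mu=1.0, roots=("R",))
    f1 = pcsf.solve_pcsf(g, {"h": 1.0}, punitive, mode="exact")
    assert "h" not in f1.nodes


def test_heuristic_matches_exact_on_seeded_suite():
    rng = np.random.default_rng(42)
    n_match = 0
    N = 30
    for _ in range(N):
        n = int(rng.integers(5, 13))
        g = random_digraph(rng, n, int(rng.integers(n - 1, 21)))
        prizes = {v: float(rng.integers(0, 2)) for v in g.nodes}
        roots = tuple(sorted(str(x) for x in rng.choice(sorted(g.nodes), 2, replace=False)))
        params = pcsf.PCSFParams(beta=10, omega=5, depth=5, mu=0, roots=roots)
        fe = pcsf.solve_pcsf(g, prizes, params, mode="exact")
        fh = pcsf.solve_pcsf(g, prizes, params, mode="heuristic")
        assert fh.objective >= fe.objective - 1e-9
        n_match += abs(fh.objective - fe.objective) <= 1e-9
    assert n_match >= int(0.9 * N)


def test_connected_prize_set_monotone_in_beta():
    rng = np.random.default_rng(43)
    for _ in range(20):
        g = random_digraph(rng, 8, 14)
        prizes = {v: float(rng.integers(0, 2)) for v in g.nodes}
        roots = tuple(sorted(str(x) for x in rng.choice(sorted(g.nodes), 2, replace=False)))
        prev: set = set()
        for beta in (1, 5, 10, 50):
            params = pcsf.PCSFParams(beta=beta, omega=5, depth=5, roots=roots)
            f = pcsf.solve_pcsf(g, prizes, params, mode="exact")
            connected = {v for v in f.nodes if prizes.get(v, 0) > 0}
            assert prev <= connected
            prev = connected


def test_temporal_series_empty_until_activation(small_interactome):
    import omnitide.synthetic as syn

    cfg, edges, truth = small_interactome
    g = pcsf.assign_edge_weights(edges)
    sched = syn.prize_schedule_from_truth(truth, g.nodes, cfg.n_timepoints)
    params = pcsf.PCSFParams(roots=tuple(truth.roots))
    forests, first_seen = pcsf.run_temporal_series(g, sched, params, mode="exact")
    act = truth.prize_activation[truth.cascade_nodes[-1]]
    for t, f in forests.items():
        if int(t.lstrip("t")) < act:
            assert f.nodes == {}
        else:
            assert sorted(f.edges) == sorted(truth.cascade_edges)
    for node in truth.cascade_nodes:
        assert first_seen[node] == f"t{act}"
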