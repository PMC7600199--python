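import networkx as nx
import numpy as np
import pytest

from oracles import all_shortest_paths_centralities
from sca1net.centrality_dynamics import (
    CentralityTable,
    centralities,
    classify_trajectories,
    prioritize_targets,
    scale_for_heatmap,
    stack_stages,
    top_nodes,
)
from sca1net.network_construction import StageNetwork


def _table(graph, stage="early"):
    return centralities(StageNetwork(stage=stage, graph=graph))


def test_path_graph_worked_values():
    g = nx.path_graph(["a", "b", "c", "d"])
    t = _table(g).values.set_index("node")
    assert t["DC"].to_dict() == {"a": 1, "b": 2, "c": 2, "d": 1}
    assert t.loc["b", "BC"] == 2.0  # pairs {a,c} and {a,d}
    assert t.loc["a", "farness"] == 6.0  # 1 + 2 + 3
    assert t.loc["a", "CC"] == pytest.approx(0.5)  # 3/6


def test_star_graph_worked_values():
    g = nx.star_graph(3)  # center 0, leaves 1..3
    t = _table(g).values.set_index("node")
    assert t.loc[0, "DC"] == 3
    assert t.loc[0, "BC"] == 3.0  # the three leaf pairs
    assert t.loc[0, "CC"] == 1.0
    assert all(t.loc[leaf, "BC"] == 0.0 for leaf in (1, 2, 3))


def test_single_edge():
    t = _table(nx.path_graph(2)).values.set_index("node")
    assert (t["DC"] == 1).all() and (t["BC"] == 0.0).all()
    assert (t["CC"] == 1.0).all()


def test_complete_graph_bc_zero():
    t = _table(nx.complete_graph(5)).values
    assert (t["BC"] == 0.0).all()


def test_empty_graph_rejected():
    with pytest.raises(ValueError, match="empty"):
        centralities(StageNetwork(stage="early", graph=nx.Graph()))


def test_oracle_equivalence_on_random_graphs():
    """DC/BC/farness/CC match explicit all-shortest-paths enumeration on
    100 random graphs (n <= 8, connected or not) to 1e-9."""
    rng = np.random.default_rng(2024)
    for trial in range(100):
        n = int(rng.integers(2, 9))
        p = float(rng.uniform(0.2, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        t = _table(g).values.set_index("node")
        dc, bc, farness, cc = all_shortest_paths_centralities(g)
        for v in g.nodes:
            assert t.loc[v, "DC"] == dc[v], f"trial {trial}"
            assert abs(t.loc[v, "BC"] - bc[v]) < 1e-9, f"trial {trial}"
            assert abs(t.loc[v, "farness"] - farness[v]) < 1e-9
            assert abs(t.loc[v, "CC"] - cc[v]) < 1e-9


def test_bc_total_equals_intermediate_incidence_mass():
    """Sum of BC over nodes equals the summed shortest-path-fraction mass
    of intermediate vertices over all unordered pairs (conservation)."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        g = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(2**31)))
        t = _table(g).values
        _, bc_oracle, _, _ = all_shortest_paths_centralities(g)
        assert t["BC"].sum() == pytest.approx(sum(bc_oracle.values()), abs=1e-9)


def test_scaling_basic_and_degenerate():
    g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("b", "d"), ("b", "e")])
    table = scale_for_heatmap(_table(g))
    df = table.values
    for m in ("DC", "BC", "CC"):
        col = df[f"scaled_{m}"]
        assert col.min() == 0.0 and col.max() == 1.0
    # degenerate: all-equal values map to 0.5
    t2 = scale_for_heatmap(_table(nx.path_graph(2), "late"))
    assert (t2.values["scaled_DC"] == 0.5).all()


def test_scaling_values_zero_half_one():
    # DC values 1, 2, 3 scale to 0, 0.5, 1 within the stage
    g = nx.path_graph(["a", "b", "c", "d"])
    g.add_edge("b", "d")
    t = scale_for_heatmap(_table(g)).values.set_index("node")
    assert t.loc["a", "scaled_DC"] == 0.0
    assert t.loc["c", "scaled_DC"] == 0.5
    assert t.loc["b", "scaled_DC"] == 1.0


def test_top_nodes_ranking_and_ties():
    g = nx.star_graph(3)
    g = nx.relabel_nodes(g, {0: "center", 1: "zz", 2: "aa", 3: "mm"})
    table = _table(g)
    assert top_nodes(table, "DC", "early", 1) == ["center"]
    # the three leaves tie at DC = 1: alphabetical order between them
    assert top_nodes(table, "DC", "early", 4) == ["center", "aa", "mm", "zz"]
    assert top_nodes(table, "DC", "early", 99) == ["center", "aa", "mm", "zz"]
    with pytest.raises(ValueError, match="k"):
        top_nodes(table, "DC", "early", 0)
    with pytest.raises(ValueError, match="metric"):
        top_nodes(table, "PageRank", "early", 1)


def _three_stage_table(values_by_stage):
    """Build a scaled CentralityTable directly from per-stage scaled DC/BC/CC
    triples: {stage: {node: (dc, bc, cc)}} with raw == scaled for simplicity."""
    import pandas as pd

    rows = []
    for stage, nodes in values_by_stage.items():
        for node, (dc, bc, cc) in nodes.items():
            rows.append({"node": node, "stage": stage, "DC": dc, "BC": bc,
                         "farness": 1.0, "CC": cc, "scaled_DC": dc,
                         "scaled_BC": bc, "scaled_CC": cc})
    return CentralityTable(pd.DataFrame(rows))


def test_trajectory_classification_tolerance():
    table = _three_stage_table({
        "early": {"up": (0.1, 0.1, 0.1), "down": (0.9, 0.9, 0.9),
                  "flat": (0.5, 0.5, 0.5)},
        "middle": {"up": (0.5, 0.5, 0.5), "down": (0.5, 0.5, 0.5),
                   "flat": (0.52, 0.52, 0.52)},
        "late": {"up": (0.9, 0.9, 0.9), "down": (0.1, 0.1, 0.1),
                 "flat": (0.48, 0.48, 0.48)},
    })
    calls = {(c.node, c.metric): c for c in classify_trajectories(table, 0.1)}
    assert calls[("up", "DC")].classification == "increasing"
    assert calls[("down", "BC")].classification == "decreasing"
    assert calls[("flat", "CC")].classification == "stable"
    assert calls[("up", "DC")].magnitude == pytest.approx(0.8)


def test_trajectory_absent_stage_flagged_not_imputed():
    table = _three_stage_table({
        "early": {"part": (0.1, 0.1, 0.1), "full": (0.5, 0.5, 0.5)},
        "middle": {"full": (0.5, 0.5, 0.5)},
        "late": {"part": (0.9, 0.9, 0.9), "full": (0.5, 0.5, 0.5)},
    })
    calls = {(c.node, c.metric): c for c in classify_trajectories(table, 0.05)}
    part = calls[("part", "DC")]
    assert part.classification == "absent-some-stages"
    assert part.magnitude == pytest.approx(0.8)  # partial call over its span
    assert set(part.per_stage) == {"early", "late"}


def _dynamic_stage_networks():
    """Three hand-built stage graphs with planted dynamics:
    - ANC: a constant 8-leaf anchor star (stable max DC/BC);
    - HUB: degree and brokerage grow early -> late (inhibition pattern);
    - BRK: a bridge between two triangles that decays to a pendant
      (stimulation pattern);
    - CLQ1-4: an isolated 4-clique holding top closeness at every stage.
    """
    anchor = [("ANC", f"a{i}") for i in range(1, 9)]
    clique = [(f"CLQ{i}", f"CLQ{j}") for i in range(1, 5) for j in range(i + 1, 5)]
    tri_b = [("b1", "b2"), ("b1", "b3"), ("b2", "b3")]
    tri_c = [("c1", "c2"), ("c1", "c3"), ("c2", "c3")]
    early = nx.Graph(
        anchor + clique + tri_b + tri_c
        + [("HUB", "a1")]
        + [("BRK", x) for x in ("b1", "b2", "b3", "c1", "c2", "c3")]
    )
    middle = nx.Graph(
        anchor + clique + tri_b + tri_c
        + [("HUB", f"a{i}") for i in range(1, 5)]
        + [("BRK", x) for x in ("b1", "b2", "b3", "c1")]
    )
    late = nx.Graph(
        anchor + clique + tri_b + tri_c
        + [("HUB", f"a{i}") for i in range(1, 9)] + [("HUB", "h1")]
        + [("BRK", "b1")]
    )
    return [StageNetwork(stage=s, graph=g)
            for s, g in [("early", early), ("middle", middle), ("late", late)]]


def test_prioritization_recovers_planted_dynamics():
    nets = _dynamic_stage_networks()
    table = scale_for_heatmap(stack_stages(*[centralities(n) for n in nets]))
    calls = classify_trajectories(table, tolerance=0.05)
    result = prioritize_targets(calls, table, cc_quantile=0.8)
    assert "HUB" in result["inhibition_candidates"]
    assert "BRK" in result["stimulation_candidates"]
    assert {"CLQ1", "CLQ2", "CLQ3", "CLQ4"} <= set(result["persistent_high_cc"])
    assert "BRK" not in result["persistent_high_cc"]
    assert "BRK" not in result["inhibition_candidates"]
    assert "HUB" not in result["stimulation_candidates"]
    # evidence is attached for every candidate
    assert result["evidence"]["HUB"]["DC"]["classification"] == "increasing"
    assert result["evidence"]["BRK"]["CC"]["classification"] == "decreasing"
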