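"""Degree/betweenness/closeness centralities per stage, heatmap scaling,
trajectory classification and drug-target prioritization.

Conventions: DC is the raw neighbor count.  BC is the unnormalized
pair-dependency sum over unordered node pairs, endpoints excluded (the
count, weighted by shortest-path fractions, of shortest paths a node sits
inside).  Closeness is reported both ways the literature uses it: the raw
farness sum of shortest-path distances d(i,j) to every other node in i's
connected component, and CC = (n_c - 1) / farness, the component-
normalized inverse average distance under which "highest closeness" means
"most central".  All distances are unweighted hops.

Trajectories are classified on min-max-scaled values ([0, 1] per metric
per stage across nodes): a node whose late-minus-early scaled value
exceeds a tolerance is increasing, below the negative tolerance
decreasing, else stable.  Prioritization follows the network-medicine
reading of centrality dynamics: nodes gaining DC and BC are inhibition
candidates, nodes losing BC and CC are stimulation candidates, and nodes
holding a top-quantile CC at every stage are persistent-high-CC (the
discrete-cluster pattern).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import STAGES
from .network_construction import StageNetwork

METRICS = ("DC", "BC", "CC")
DEFAULT_TOLERANCE = 0.05
DEFAULT_CC_QUANTILE = 0.8


@dataclass
class CentralityTable:
    """Long-format centrality values: one row per (node, stage).

    Columns: node, stage, DC, BC, farness, CC and, after scaling,
    scaled_DC / scaled_BC / scaled_CC.
    """

    values: pd.DataFrame

    def stages(self) -> list[str]:
        present = set(self.values["stage"])
        return [s for s in STAGES if s in present] + sorted(
            present - set(STAGES)
        )

    def nodes(self) -> list[str]:
        return sorted(self.values["node"].unique())

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index=False, float_format="%.10g")


def centralities(network: StageNetwork | nx.Graph, stage: str | None = None) -> CentralityTable:
    """DC, BC, farness and CC for every node of one stage network."""
    if isinstance(network, StageNetwork):
        graph = network.graph
        stage = stage if stage is not None else network.stage
    else:
        graph = network
        stage = stage if stage is not None else "all"
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    bc = nx.betweenness_centrality(graph, normalized=False)
    rows = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        n_c = len(comp)
        for node, dists in nx.all_pairs_shortest_path_length(sub):
            farness = sum(dists.values())
            cc = (n_c - 1) / farness if farness > 0 else 0.0
            rows.append(
                {
                    "node": node,
                    "stage": stage,
                    "DC": graph.degree(node),
                    "BC": float(bc[node]),
                    "farness": float(farness),
                    "CC": float(cc),
                }
            )
    df = pd.DataFrame(rows).sort_values("node", kind="mergesort").reset_index(drop=True)
    return CentralityTable(df)


def stack_stages(*tables: CentralityTable) -> CentralityTable:
    return CentralityTable(
        pd.concat([t.values for t in tables], ignore_index=True)
    )


def scale_for_heatmap(table: CentralityTable) -> CentralityTable:
    """Min-max scale each metric to [0, 1] per stage across nodes.

    A constant column (including a single-node stage) maps to 0.5: no
    ordering information, so every node sits mid-scale.
    """
    df = table.values.copy()
    for metric in METRICS:
        scaled = np.empty(len(df))
        for _, idx in df.groupby("stage").groups.items():
            col = df.loc[idx, metric].astype(float)
            lo, hi = col.min(), col.max()
            if hi > lo:
                scaled[df.index.get_indexer(idx)] = (col - lo) / (hi - lo)
            else:
                scaled[df.index.get_indexer(idx)] = 0.5
        df[f"scaled_{metric}"] = scaled
    return CentralityTable(df)


def top_nodes(
    table: CentralityTable, metric: str, stage: str, k: int
) -> list[str]:
    """Top-k nodes by a metric at one stage; ties broken alphabetically."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = table.values[table.values["stage"] == stage]
    ranked = sub.sort_values(
        [metric, "node"], ascending=[False, True], kind="mergesort"
    )
    return ranked["node"].head(k).tolist()


@dataclass(frozen=True)
class TrajectoryCall:
    node: str
    metric: str
    per_stage: dict[str, float]  # scaled values at the stages the node has
    classification: str  # increasing / decreasing / stable / absent-some-stages
    magnitude: float | None  # last-minus-first present scaled value


def classify_trajectories(
    table: CentralityTable, tolerance: float = DEFAULT_TOLERANCE
) -> list[TrajectoryCall]:
    """Classify each node's scaled-centrality trajectory across stages.

    Nodes present at every stage get increasing / decreasing / stable by
    comparing late vs early scaled values against the tolerance.  Nodes
    missing >= 1 stage are flagged ``absent-some-stages``; if they appear
    in >= 2 stages the magnitude over their present span is still
    reported (a partial call), otherwise the magnitude is undefined.
    Absence is never imputed as zero.
    """
    stages = table.stages()
    df = table.values
    needed = [f"scaled_{m}" for m in METRICS]
    if any(c not in df.columns for c in needed):
        raise ValueError("table must be scaled first (scale_for_heatmap)")
    calls: list[TrajectoryCall] = []
    for node, sub in df.groupby("node", sort=True):
        per_stage_rows = sub.set_index("stage")
        present = [s for s in stages if s in per_stage_rows.index]
        for metric in METRICS:
            vals = {s: float(per_stage_rows.loc[s, f"scaled_{metric}"]) for s in present}
            if len(present) < len(stages):
                mag = (
                    vals[present[-1]] - vals[present[0]]
                    if len(present) >= 2
                    else None
                )
                cls = "absent-some-stages"
            else:
                mag = vals[present[-1]] - vals[present[0]]
                if mag > tolerance:
                    cls = "increasing"
                elif mag < -tolerance:
                    cls = "decreasing"
                else:
                    cls = "stable"
            calls.append(TrajectoryCall(str(node), metric, vals, cls, mag))
    return calls


def prioritize_targets(
    calls: list[TrajectoryCall],
    table: CentralityTable,
    cc_quantile: float = DEFAULT_CC_QUANTILE,
) -> dict:
    """Rank nodes as pharmacological candidates from centrality dynamics.

    - inhibition candidates: DC and BC both increasing (gaining hub and
      broker roles as aggregation progresses);
    - stimulation candidates: BC and CC both decreasing (losing their
      place in the network, to be functionally supported);
    - persistent-high-CC: CC at or above the ``cc_quantile`` quantile of
      its stage at every stage the analysis covers.
    """
    by_node: dict[str, dict[str, str]] = {}
    for c in calls:
        by_node.setdefault(c.node, {})[c.metric] = c.classification
    inhibition = sorted(
        n for n, m in by_node.items()
        if m.get("DC") == "increasing" and m.get("BC") == "increasing"
    )
    stimulation = sorted(
        n for n, m in by_node.items()
        if m.get("BC") == "decreasing" and m.get("CC") == "decreasing"
    )

    stages = table.stages()
    df = table.values
    persistent: list[str] = []
    cutoffs = {
        s: df.loc[df["stage"] == s, "CC"].quantile(cc_quantile) for s in stages
    }
    for node, sub in df.groupby("node", sort=True):
        per_stage = sub.set_index("stage")["CC"]
        if all(
            s in per_stage.index and per_stage[s] >= cutoffs[s] for s in stages
        ):
            persistent.append(str(node))

    evidence = {
        n: {c.metric: {"classification": c.classification, "magnitude": c.magnitude}
            for c in calls if c.node == n}
        for n in set(inhibition) | set(stimulation) | set(persistent)
    }
    return {
        "inhibition_candidates": inhibition,
        "stimulation_candidates": stimulation,
        "persistent_high_cc": sorted(persistent),
        "cc_quantile": cc_quantile,
        "evidence": evidence,
    }
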