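"""Stage-specific PPI network construction and the stage-labelled union.

A stage network is the induced subgraph of the input interactome on the
member proteins of that stage's common dysregulated pathways, after three
filters applied exactly as in the motivating analysis: a tissue-expression
filter (node score >= 4.8, nervous-system expression), a high-confidence
interaction filter (edge confidence >= 0.950, both thresholds inclusive),
and deletion of unconnected (degree-0) nodes.  No neighborhood expansion
is performed: only interactions between member proteins are used.

The three stage networks merge into a union graph whose nodes carry their
exact stage-membership set and a group label: ``all`` (yellow, perturbed
at every stage), ``middle-specific`` (green), ``late-specific`` (magenta),
or the literal membership pattern (e.g. ``early+middle``) for the
remaining combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io_formats import STAGES, PPIEdgeTable

DEFAULT_EDGE_THRESHOLD = 0.950
DEFAULT_TISSUE_THRESHOLD = 4.8

GROUP_COLORS = {"all": "yellow", "middle-specific": "green", "late-specific": "magenta"}


@dataclass
class StageNetwork:
    stage: str
    graph: nx.Graph
    input_pathways: tuple[str, ...] = ()
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class UnionNetwork:
    graph: nx.Graph
    stage_sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def group_of(self, node: str) -> str:
        return self.graph.nodes[node]["group"]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for _, d in self.graph.nodes(data=True):
            sizes[d["group"]] = sizes.get(d["group"], 0) + 1
        return sizes

    def membership_table(self) -> pd.DataFrame:
        """Gantt-style table: one row per node, one boolean column per stage."""
        rows = []
        for node in sorted(self.graph.nodes):
            stages = self.graph.nodes[node]["stage_set"]
            rows.append(
                {
                    "node": node,
                    **{s: s in stages for s in STAGES},
                    "group": self.graph.nodes[node]["group"],
                }
            )
        return pd.DataFrame(rows, columns=["node", *STAGES, "group"])


def build_stage_network(
    member_proteins,
    ppi: PPIEdgeTable,
    stage: str = "early",
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
    tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD,
    input_pathways=(),
) -> StageNetwork:
    """Filtered induced PPI subgraph on one stage's pathway members."""
    members = set(member_proteins)
    if not members:
        raise ValueError("empty member-protein list")
    scores = ppi.tissue_scores
    kept = {m for m in members if scores.get(m, 0.0) >= tissue_threshold}
    g = nx.Graph()
    for _, row in ppi.edges.iterrows():
        a, b = row["node_a"], row["node_b"]
        if a in kept and b in kept and float(row["confidence"]) >= edge_threshold:
            g.add_edge(a, b, confidence=float(row["confidence"]))
    # unconnected nodes deleted: only nodes with >= 1 surviving edge remain
    return StageNetwork(
        stage=stage,
        graph=g,
        input_pathways=tuple(input_pathways),
        edge_threshold=edge_threshold,
        tissue_threshold=tissue_threshold,
    )


def group_label(stage_set: frozenset[str]) -> str:
    if stage_set == frozenset(STAGES):
        return "all"
    if stage_set == frozenset({"middle"}):
        return "middle-specific"
    if stage_set == frozenset({"late"}):
        return "late-specific"
    return "+".join(s for s in STAGES if s in stage_set)


def merge_stage_networks(*stage_networks: StageNetwork) -> UnionNetwork:
    """Union of stage graphs with per-node stage-membership labels.

    Associative and order-independent: the result depends only on the set
    of stage networks.  Edge confidences keep the maximum over the stages
    an edge appears in.
    """
    union = nx.Graph()
    stage_sets: dict[str, set[str]] = {}
    for sn in stage_networks:
        for node in sn.graph.nodes:
            stage_sets.setdefault(node, set()).add(sn.stage)
        for a, b, d in sn.graph.edges(data=True):
            if union.has_edge(a, b):
                prev = union.edges[a, b].get("confidence", 0.0)
                union.edges[a, b]["confidence"] = max(prev, d.get("confidence", 0.0))
            else:
                union.add_edge(a, b, confidence=d.get("confidence", 0.0))
    frozen = {n: frozenset(s) for n, s in stage_sets.items()}
    for node, sset in frozen.items():
        grp = group_label(sset)
        union.add_node(
            node,
            stage_set=sset,
            group=grp,
            color=GROUP_COLORS.get(grp, "grey"),
        )
    return UnionNetwork(graph=union, stage_sets=frozen)


def annotation_overrepresentation(
    network: UnionNetwork, flagged_genes, background
):
    """Hypergeometric over-representation of a flagged gene list among the
    union network's nodes (e.g. a literature-mined aggregation gene list)."""
    from .io_formats import GeneSet, GeneSetCollection
    from .pathway_enrichment import enrich

    flagged = set(flagged_genes)
    background = set(background)
    if not flagged <= background:
        raise ValueError("flagged genes must be a subset of the background")
    collection = GeneSetCollection(
        {"flagged": GeneSet("flagged", "flagged gene list", frozenset(flagged))}
    )
    results = enrich(sorted(network.graph.nodes), collection, background)
    return results[0]
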