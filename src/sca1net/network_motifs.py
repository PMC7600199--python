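"""Connected 4-node motif census and z-scores against a degree-preserving null.

The census enumerates every connected induced 4-node subgraph exactly
(ESU-style enumeration, no sampling) and classifies it into one of the six
isomorphism classes of connected simple undirected graphs on 4 vertices:
path, star, cycle, triangle-with-pendant (paw), diamond and complete.  A
class is fully determined by the induced edge count m and, for m = 3 or 4,
the maximum degree within the subgraph.

Significance is measured against an ensemble of degree-preserving
randomized networks built by attempted double-edge swaps (the field's
standard null model): per class z = (real - null mean) / null sd, and the
aggregate z is the unweighted mean over classes whose null sd is positive.
Classes with zero null sd have no defined z and are reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

MOTIF_CLASSES = ("path", "star", "cycle", "paw", "diamond", "complete")

DEFAULT_ENSEMBLE_SIZE = 1000
DEFAULT_SWAPS_PER_EDGE = 10


@dataclass
class MotifCensus:
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for c in MOTIF_CLASSES:
            self.counts.setdefault(c, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class MotifZScore:
    real_counts: dict[str, int]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    z: dict[str, float | None]
    aggregate_z: float | None
    ensemble_size: int
    swaps_per_edge: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "real_counts": self.real_counts,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "aggregate_z": self.aggregate_z,
            "ensemble_size": self.ensemble_size,
            "swaps_per_edge": self.swaps_per_edge,
            "seed": self.seed,
        }


def _classify(m: int, max_deg: int) -> str:
    # m = induced edge count among 4 nodes, max_deg = max degree inside
    if m == 3:
        return "star" if max_deg == 3 else "path"
    if m == 4:
        return "paw" if max_deg == 3 else "cycle"
    if m == 5:
        return "diamond"
    return "complete"  # m == 6


def census_4node(graph: nx.Graph) -> MotifCensus:
    """Exact census of connected induced 4-node subgraphs.

    ESU enumeration: each connected 4-subset is generated exactly once by
    growing from its lowest-index vertex through its exclusive
    neighborhood.  Adjacency is held as integer bitmasks so the induced
    edge count is a popcount.
    """
    if any(a == b for a, b in graph.edges):
        raise ValueError("graph must not contain self-loops")
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = [0] * n
    neigh: list[list[int]] = [[] for _ in range(n)]
    for a, b in graph.edges:
        ia, ib = index[a], index[b]
        adj[ia] |= 1 << ib
        adj[ib] |= 1 << ia
        neigh[ia].append(ib)
        neigh[ib].append(ia)

    counts = {c: 0 for c in MOTIF_CLASSES}

    def classify_subset(vs: tuple[int, int, int, int]) -> None:
        mask = 0
        for v in vs:
            mask |= 1 << v
        degs = [(adj[v] & mask).bit_count() for v in vs]
        m = sum(degs) // 2
        counts[_classify(m, max(degs))] += 1

    def extend(sub: list[int], ext: set[int], root: int) -> None:
        if len(sub) == 4:
            classify_subset(tuple(sub))  # connected by construction
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            # exclusive neighborhood: neighbors of w beyond root not already
            # adjacent to the current subgraph
            new_ext = set(ext)
            sub_neigh = set()
            for v in sub:
                sub_neigh.update(neigh[v])
            for u in neigh[w]:
                if u > root and u not in sub and u not in sub_neigh:
                    new_ext.add(u)
            extend(sub + [w], new_ext, root)

    for v in range(n):
        ext = {u for u in neigh[v] if u > v}
        extend([v], ext, v)
    return MotifCensus(counts)


def randomize_preserving_degrees(
    graph: nx.Graph, n_swaps: int | None = None, seed: int = 0
) -> nx.Graph:
    """Degree-preserving randomization by attempted double-edge swaps.

    Each attempt picks two distinct edges (a,b), (c,d) and rewires to
    (a,d), (c,b) unless that would create a self-loop or a multi-edge.
    The degree sequence is invariant by construction.  Graphs admitting no
    legal swap (e.g. stars) come back unchanged, with a log record.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    n_edges = g.number_of_edges()
    if n_edges < 2:
        logger.info("fewer than 2 edges: returning an identical copy")
        return g
    if n_swaps is None:
        n_swaps = DEFAULT_SWAPS_PER_EDGE * n_edges
    rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in g.edges]
    n_success = 0
    for _ in range(n_swaps):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # random orientation of the second edge
        if rng.integers(2):
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue  # shared endpoint: swap would self-loop or duplicate
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        n_success += 1
    if n_success == 0:
        logger.info("no legal double-edge swap found: graph returned unchanged")
    return g


def motif_zscores(
    graph: nx.Graph,
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> MotifZScore:
    """Per-class and aggregate motif z-scores over a randomized ensemble."""
    if ensemble_size < 2:
        raise ValueError("ensemble_size must be >= 2")
    real = census_4node(graph).counts
    n_swaps = swaps_per_edge * max(graph.number_of_edges(), 1)
    ss = np.random.SeedSequence([seed, graph.number_of_edges()])
    child_seeds = ss.generate_state(ensemble_size)
    null_counts = {c: np.empty(ensemble_size) for c in MOTIF_CLASSES}
    for i in range(ensemble_size):
        rnd = randomize_preserving_degrees(graph, n_swaps, seed=int(child_seeds[i]))
        cc = census_4node(rnd).counts
        for c in MOTIF_CLASSES:
            null_counts[c][i] = cc[c]
    null_mean = {c: float(null_counts[c].mean()) for c in MOTIF_CLASSES}
    null_sd = {c: float(null_counts[c].std(ddof=0)) for c in MOTIF_CLASSES}
    z: dict[str, float | None] = {}
    defined = []
    for c in MOTIF_CLASSES:
        if null_sd[c] > 0:
            z[c] = (real[c] - null_mean[c]) / null_sd[c]
            defined.append(z[c])
        else:
            z[c] = None
    aggregate = float(np.mean(defined)) if defined else None
    if aggregate is not None and not math.isfinite(aggregate):
        aggregate = None
    return MotifZScore(
        real_counts=dict(real),
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        aggregate_z=aggregate,
        ensemble_size=ensemble_size,
        swaps_per_edge=swaps_per_edge,
        seed=seed,
    )
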