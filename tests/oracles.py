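"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: explicit shortest-path enumeration for
centralities, exhaustive 4-subset inspection for the motif census, and
exact rational enumeration for the hypergeometric tail.  They share no
code with the package paths they check.
"""

from fractions import Fraction
from itertools import combinations

import networkx as nx


def all_shortest_paths_centralities(graph: nx.Graph):
    """(DC, BC, farness, CC) per node by explicit path enumeration."""
    nodes = sorted(graph.nodes)
    dc = {v: graph.degree(v) for v in nodes}
    bc = {v: 0.0 for v in nodes}
    farness = {v: 0 for v in nodes}
    for s, t in combinations(nodes, 2):
        if not nx.has_path(graph, s, t):
            continue
        paths = list(nx.all_shortest_paths(graph, s, t))
        d = len(paths[0]) - 1
        farness[s] += d
        farness[t] += d
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    cc = {}
    for v in nodes:
        comp = nx.node_connected_component(graph, v)
        cc[v] = (len(comp) - 1) / farness[v] if farness[v] > 0 else 0.0
    return dc, bc, farness, cc


def _classify_degseq(degs):
    key = tuple(sorted(degs))
    return {
        (1, 1, 2, 2): "path",
        (1, 1, 1, 3): "star",
        (2, 2, 2, 2): "cycle",
        (1, 2, 2, 3): "paw",
        (2, 2, 3, 3): "diamond",
        (3, 3, 3, 3): "complete",
    }[key]


def naive_motif_census(graph: nx.Graph):
    """Counts of connected induced 4-node subgraphs via all C(n,4) subsets."""
    counts = {c: 0 for c in ("path", "star", "cycle", "paw", "diamond", "complete")}
    for subset in combinations(sorted(graph.nodes), 4):
        sub = graph.subgraph(subset)
        if nx.is_connected(sub):
            counts[_classify_degseq([d for _, d in sub.degree()])] += 1
    return counts


def exact_hypergeom_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(|draw of size n intersects K-set| >= k) by enumerating all draws."""
    background = range(N)
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(background, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)
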