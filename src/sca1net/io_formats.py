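"""Readers and writers for every table and graph format the pipeline touches.

All tabular formats are tab-separated with a header row, matching the
export conventions of the tool ecosystem this pipeline replaces (Cytoscape,
Enrichr, STRING downloads).  Gene identifiers are opaque, case-sensitive
strings; no symbol-casing conversion is ever applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ["sample_id", "group", "time_point", "replicate", "role"]
STAGES = ("early", "middle", "late")
CONTROL_LABEL = "control"


class ValidationError(ValueError):
    """An input table violated a structural invariant."""


@dataclass
class ExpressionStudy:
    """An FPKM expression matrix plus its sample design for one model.

    ``fpkm`` is genes x samples (fragments per kilobase of exon model per
    million mapped reads, non-negative).  ``design`` has one row per sample
    with columns ``sample_id, group, time_point, replicate, role`` where
    ``role`` is ``case`` or ``control``.  A single-baseline design (the cell
    model) carries one control group at time-point ``control``; a paired
    design (the mouse model) carries one control group per time-point.
    """

    model_id: str
    fpkm: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fpkm.index.duplicated().any():
            dupes = self.fpkm.index[self.fpkm.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        missing = set(self.fpkm.columns) - set(self.design["sample_id"])
        if missing:
            raise ValidationError(
                f"samples in matrix absent from design: {sorted(missing)[:5]}"
            )
        extra = set(self.design["sample_id"]) - set(self.fpkm.columns)
        if extra:
            raise ValidationError(
                f"samples in design absent from matrix: {sorted(extra)[:5]}"
            )
        neg = np.asarray(self.fpkm.values < 0).nonzero()
        if neg[0].size:
            g = self.fpkm.index[neg[0][0]]
            s = self.fpkm.columns[neg[1][0]]
            raise ValidationError(f"negative FPKM for gene {g!r} in sample {s!r}")
        counts = self.design.groupby("group").size()
        thin = counts[counts < 2]
        if len(thin):
            raise ValidationError(
                f"groups with fewer than 2 replicates: {thin.index.tolist()}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    def group_matrix(self, group: str) -> pd.DataFrame:
        """FPKM columns belonging to one design group."""
        samples = self.design.loc[self.design["group"] == group, "sample_id"]
        if samples.empty:
            raise KeyError(f"group {group!r} absent from design of {self.model_id!r}")
        return self.fpkm[list(samples)]

    def comparisons(self) -> list[tuple[str, str, str]]:
        """(time_point, case_group, control_group) triples for DEG calling.

        Each non-control time-point's case group is compared to the control
        group at the same time-point if one exists (paired design), else to
        the single baseline control.
        """
        des = self.design
        out: list[tuple[str, str, str]] = []
        baseline = des.loc[
            (des["time_point"] == CONTROL_LABEL) & (des["role"] == "control"), "group"
        ].unique()
        for tp in des.loc[des["time_point"] != CONTROL_LABEL, "time_point"].unique():
            cases = des.loc[
                (des["time_point"] == tp) & (des["role"] == "case"), "group"
            ].unique()
            paired = des.loc[
                (des["time_point"] == tp) & (des["role"] == "control"), "group"
            ].unique()
            if not len(cases):
                continue
            if len(paired):
                out.append((tp, cases[0], paired[0]))
            elif len(baseline):
                out.append((tp, cases[0], baseline[0]))
            else:
                raise ValidationError(
                    f"time-point {tp!r} has no control group and no baseline"
                )
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionStudy):
            return NotImplemented
        return (
            self.model_id == other.model_id
            and self.fpkm.equals(other.fpkm)
            and self.design.reset_index(drop=True).equals(
                other.design.reset_index(drop=True)
            )
        )


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (the KEGG-pathway stand-in)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if not gs.members:
                raise ValidationError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.members
        return frozenset(out)


@dataclass
class PPIEdgeTable:
    """Weighted undirected PPI edge list with per-node tissue scores.

    ``edges`` has columns ``node_a, node_b, confidence`` (confidence in
    [0, 1]); ``tissue_scores`` maps node id -> non-negative expression score
    in the tissue of interest (cerebellum in the motivating study).
    """

    edges: pd.DataFrame
    tissue_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if (e["node_a"] == e["node_b"]).any():
                bad = e.loc[e["node_a"] == e["node_b"]].iloc[0]
                raise ValidationError(f"self-loop on node {bad['node_a']!r}")
            conf = e["confidence"].astype(float)
            if ((conf < 0) | (conf > 1)).any():
                raise ValidationError("confidence outside [0, 1]")
            key = e.apply(
                lambda r: tuple(sorted((r["node_a"], r["node_b"]))), axis=1
            )
            if key.duplicated().any():
                raise ValidationError(
                    f"duplicate unordered pair: {key[key.duplicated()].iloc[0]}"
                )

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# expression matrices


def write_expression(study: ExpressionStudy, matrix_path, design_path) -> None:
    m = study.fpkm.copy()
    m.index.name = "gene_id"
    m.to_csv(matrix_path, sep="\t", float_format="%.6g")
    study.design.to_csv(design_path, sep="\t", index=False)


def read_expression(matrix_path, design_path, model_id: str | None = None) -> ExpressionStudy:
    m = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    design = pd.read_csv(design_path, sep="\t", dtype={"sample_id": str})
    missing_cols = set(DESIGN_COLUMNS) - set(design.columns)
    if missing_cols:
        raise ValidationError(f"design missing columns: {sorted(missing_cols)}")
    m.columns = m.columns.astype(str)
    m.index = m.index.astype(str)
    if model_id is None:
        model_id = Path(matrix_path).stem
    return ExpressionStudy(model_id=model_id, fpkm=m, design=design)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line ``set_id <TAB> description <TAB> member...``."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(parts)} fields, need >= 3"
                )
            sid, desc, *members = parts
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                logger.warning(
                    "%s:%d: %d duplicate members in set %s deduplicated",
                    path, lineno, len(members) - len(uniq), sid,
                )
            if not uniq:
                raise ValidationError(f"{path}:{lineno}: set {sid!r} has no members")
            sets[sid] = GeneSet(sid, desc, frozenset(uniq))
    if not sets:
        logger.warning("%s: empty GMT file, empty collection loaded", path)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(collection.sets):
            gs = collection.sets[sid]
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# PPI edge tables and tissue scores


def write_ppi(table: PPIEdgeTable, edges_path, tissue_path) -> None:
    table.edges.to_csv(edges_path, sep="\t", index=False, float_format="%.6g")
    ts = pd.DataFrame(
        sorted(table.tissue_scores.items()), columns=["node", "tissue_score"]
    )
    ts.to_csv(tissue_path, sep="\t", index=False, float_format="%.6g")


def read_ppi(edges_path, tissue_path) -> PPIEdgeTable:
    edges = pd.read_csv(
        edges_path, sep="\t", dtype={"node_a": str, "node_b": str}
    )
    if len(edges) == 0:
        edges = pd.DataFrame(columns=["node_a", "node_b", "confidence"])
    ts = pd.read_csv(tissue_path, sep="\t", dtype={"node": str})
    scores = dict(zip(ts["node"], ts["tissue_score"].astype(float)))
    return PPIEdgeTable(edges=edges, tissue_scores=scores)


# ---------------------------------------------------------------------------
# ortholog map


def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str})
    need = {"source_id", "target_id", "rank_score"}
    if not need.issubset(df.columns):
        raise ValidationError(f"ortholog map missing columns {need - set(df.columns)}")
    if df.duplicated(["source_id", "target_id"]).any():
        raise ValidationError("duplicate (source, target) pair in ortholog map")
    if (df["rank_score"] < 0).any():
        raise ValidationError("negative rank score in ortholog map")
    return df


def write_ortholog_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# drug tables


def read_drug_targets(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "target_id": str})
    if len(df) == 0:
        return pd.DataFrame(
            columns=["drug_id", "target_id", "interaction_score", "approval_status"]
        )
    if df.duplicated(["drug_id", "target_id"]).any():
        raise ValidationError("duplicate (drug, target) pair")
    score = df["interaction_score"].astype(float)
    if ((score < 0) | (score > 1)).any():
        raise ValidationError("interaction score outside [0, 1]")
    return df


def write_drug_targets(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bbb_calls(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"drug_id": str, "algorithm": str, "fingerprint": str, "call": str},
    )
    if len(df) == 0:
        return pd.DataFrame(columns=["drug_id", "algorithm", "fingerprint", "call"])
    if df.duplicated(["drug_id", "algorithm", "fingerprint"]).any():
        raise ValidationError("duplicate (drug, algorithm, fingerprint) call")
    return df


def write_bbb_calls(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# graphs

NETWORK_FORMATS = ("edgelist", "graphml", "sif")


def write_network(graph: nx.Graph, path, format: str = "edgelist") -> None:
    """Serialize a graph with its node attributes.

    ``edgelist`` writes a TSV with a companion ``<path>.nodes.tsv`` holding
    node attributes; ``graphml`` keeps attributes inline; ``sif`` writes the
    Cytoscape simple-interaction format (one ``a pp b`` line per edge,
    isolated nodes on their own line).
    """
    path = Path(path)
    if format == "edgelist":
        rows = [
            {"node_a": a, "node_b": b, **{k: _attr_str(v) for k, v in d.items()}}
            for a, b, d in sorted(graph.edges(data=True))
        ]
        cols = ["node_a", "node_b"]
        extra = sorted({k for r in rows for k in r} - set(cols))
        pd.DataFrame(rows, columns=cols + extra).to_csv(path, sep="\t", index=False)
        nrows = [
            {"node": n, **{k: _attr_str(v) for k, v in d.items()}}
            for n, d in sorted(graph.nodes(data=True))
        ]
        ncols = ["node"] + sorted({k for r in nrows for k in r} - {"node"})
        pd.DataFrame(nrows, columns=ncols).to_csv(
            path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False
        )
    elif format == "graphml":
        g = graph.copy()
        for _, d in g.nodes(data=True):
            for k, v in list(d.items()):
                d[k] = _attr_str(v)
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            seen: set[str] = set()
            for a, b in sorted(graph.edges()):
                fh.write(f"{a}\tpp\t{b}\n")
                seen |= {a, b}
            for n in sorted(set(graph.nodes()) - seen):
                fh.write(f"{n}\n")
    else:
        raise ValueError(f"unsupported network format {format!r}; use {NETWORK_FORMATS}")


def read_network(path, format: str = "edgelist") -> nx.Graph:
    path = Path(path)
    if format == "edgelist":
        g = nx.Graph()
        df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
        for _, row in df.iterrows():
            attrs = {
                k: row[k] for k in df.columns if k not in ("node_a", "node_b")
            }
            g.add_edge(row["node_a"], row["node_b"], **attrs)
        nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
        if nodes_path.exists():
            ndf = pd.read_csv(nodes_path, sep="\t", dtype={"node": str})
            for _, row in ndf.iterrows():
                g.add_node(row["node"], **{
                    k: row[k] for k in ndf.columns if k != "node"
                })
        return g
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    g.add_edge(parts[0], parts[2])
                elif parts[0]:
                    g.add_node(parts[0])
        return g
    raise ValueError(f"unsupported network format {format!r}; use {NETWORK_FORMATS}")


def _attr_str(v):
    if isinstance(v, (frozenset, set, tuple, list)):
        return "|".join(sorted(map(str, v)))
    return v
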