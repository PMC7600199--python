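"""Drug-target bipartite overlay and the strict 8/8 BBB consensus rule.

The overlay restricts a drug-target interaction table to the prioritized
target proteins, keeping only interactions whose score is at or above a
confidence threshold (default 0.5, inclusive) and dropping drugs left
without any surviving edge.  Blood-brain-barrier permeability is decided
by strict consensus over exactly 8 predictor calls per drug — 2 algorithms
(ADABoost, SVM) x 4 chemical fingerprints (MACCS, Openbabel, Molprint,
PubChem): a drug is ``permeable`` only if all 8 calls are positive, any
negative call makes it ``not-permeable``, and a missing or partial call
set yields ``incomplete`` — never silently permeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .synthetic_data import ALGORITHMS, FINGERPRINTS

DEFAULT_SCORE_THRESHOLD = 0.5
N_CALLS = len(ALGORITHMS) * len(FINGERPRINTS)  # 8

VERDICTS = ("permeable", "not-permeable", "incomplete")


@dataclass
class DrugOverlay:
    """Bipartite drug-target graph with per-drug BBB verdicts."""

    graph: nx.Graph
    score_threshold: float = DEFAULT_SCORE_THRESHOLD
    verdicts: dict[str, str] = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "drug"
        )

    @property
    def targets(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "target"
        )

    def target_degrees(self) -> dict[str, int]:
        return {t: self.graph.degree(t) for t in self.targets}

    def verdict_table(self) -> pd.DataFrame:
        rows = [
            {
                "drug": d,
                "n_targets": self.graph.degree(d),
                "verdict": self.verdicts.get(d, "incomplete"),
            }
            for d in self.drugs
        ]
        return pd.DataFrame(rows, columns=["drug", "n_targets", "verdict"])


def build_overlay(
    targets,
    table: pd.DataFrame,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> DrugOverlay:
    """Bipartite overlay of drugs on the prioritized targets.

    Keeps only rows whose target is listed and whose interaction score is
    >= ``score_threshold`` (inclusive).  Drugs with no surviving edge are
    absent; targets remain as nodes even when no drug binds them, so
    per-target drug counts are always reportable.
    """
    target_set = set(targets)
    if not target_set:
        raise ValueError("empty target list")
    g = nx.Graph()
    for t in sorted(target_set):
        g.add_node(t, kind="target")
    for _, row in table.iterrows():
        if row["target_id"] not in target_set:
            continue
        score = float(row["interaction_score"])
        if score < score_threshold:
            continue
        g.add_node(row["drug_id"], kind="drug",
                   approval_status=row.get("approval_status", ""))
        g.add_edge(row["drug_id"], row["target_id"], score=score)
    return DrugOverlay(graph=g, score_threshold=score_threshold)


def bbb_consensus(overlay: DrugOverlay, calls: pd.DataFrame) -> dict[str, str]:
    """Apply the strict 8/8 positive-call consensus to the overlay's drugs.

    Monotone in the calls: flipping any positive call negative can only
    move a verdict away from ``permeable``.
    """
    if len(calls) and calls.duplicated(["drug_id", "algorithm", "fingerprint"]).any():
        dupe = calls[calls.duplicated(["drug_id", "algorithm", "fingerprint"])].iloc[0]
        raise ValueError(
            f"duplicate call for {dupe['drug_id']} "
            f"({dupe['algorithm']}/{dupe['fingerprint']})"
        )
    expected_keys = {(a, f) for a in ALGORITHMS for f in FINGERPRINTS}
    verdicts: dict[str, str] = {}
    grouped = dict(tuple(calls.groupby("drug_id"))) if len(calls) else {}
    for drug in overlay.drugs:
        sub = grouped.get(drug)
        if sub is None:
            verdicts[drug] = "incomplete"
            continue
        keys = set(zip(sub["algorithm"], sub["fingerprint"]))
        if keys != expected_keys:
            verdicts[drug] = "incomplete"
        elif (sub["call"] == "BBB+").all():
            verdicts[drug] = "permeable"
        else:
            verdicts[drug] = "not-permeable"
    overlay.verdicts = verdicts
    return verdicts
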