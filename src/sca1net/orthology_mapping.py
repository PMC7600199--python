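"""Mapping of mouse-model DEG tables onto the human gene namespace.

An ortholog map is a rank-scored table (source_id, target_id, rank_score);
higher ranks mean stronger orthology support, as produced by
multi-predictor integration tools.  Mapping is deterministic: genes with no
mapping at or above ``min_rank`` are dropped (and counted), a source with
several surviving targets keeps the highest-rank one (ties broken by
lexicographic target id), and when several sources land on the same target
the pair with the highest rank wins (ties broken by lexicographic source
id), so one output row exists per target gene per time-point.
"""

from __future__ import annotations

import logging

import pandas as pd

from .differential_expression import DEGTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_RANK = 8  # top rank class in the simulated map


def map_to_target_namespace(
    deg_table: DEGTable, ortholog_map: pd.DataFrame, min_rank: int = DEFAULT_MIN_RANK
) -> DEGTable:
    if len(ortholog_map) == 0:
        raise ValueError("empty ortholog map")
    m = ortholog_map[ortholog_map["rank_score"] >= min_rank].copy()

    # one target per source: highest rank, ties to the lexicographically
    # smallest target id
    m = m.sort_values(
        ["source_id", "rank_score", "target_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop_duplicates("source_id", keep="first")
    best = m.set_index("source_id")

    rec = deg_table.records
    mapped = rec.merge(
        best[["target_id", "rank_score"]], left_on="gene", right_index=True,
        how="left",
    )
    dropped = mapped["target_id"].isna()
    n_dropped_genes = mapped.loc[dropped, "gene"].nunique()
    if n_dropped_genes:
        logger.info(
            "%d genes dropped: no ortholog at rank >= %d", n_dropped_genes, min_rank
        )
    mapped = mapped[~dropped].copy()

    # many-to-one collisions per time-point: highest rank wins, ties to the
    # lexicographically smallest source id
    mapped = mapped.sort_values(
        ["time_point", "target_id", "rank_score", "gene"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    collided = mapped.duplicated(["time_point", "target_id"], keep="first")
    if collided.any():
        for _, row in mapped[collided].iterrows():
            logger.info(
                "collision on %s at %s: dropped source %s (rank %s)",
                row["target_id"], row["time_point"], row["gene"], row["rank_score"],
            )
    mapped = mapped[~collided].copy()
    mapped["gene"] = mapped["target_id"]
    mapped = mapped.drop(columns=["target_id", "rank_score"])
    mapped = mapped.sort_values(["time_point", "gene"], kind="mergesort").reset_index(
        drop=True
    )
    return DEGTable(
        deg_table.model_id, mapped, deg_table.fc_threshold, deg_table.p_threshold
    )
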