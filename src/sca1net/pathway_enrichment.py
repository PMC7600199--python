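"""Gene-set over-representation, cross-model common pathways and
direction concordance of shared DEGs.

Over-representation uses the one-sided hypergeometric upper tail (the exact
test behind standard enrichment web tools): for a DEG list of size n drawn
from a background of size N, a set with K background members and k overlap
has p = sum_{i>=k} C(K,i) C(N-K, n-i) / C(N,n).  The background is the
intersection of the measured gene universe with the collection's universe,
so set sizes K are background-restricted.

Stage matching pairs the two models' time-points (in the motivating study
Day 2 cells to week-5 mice, Day 5 to week 12, Day 10 to week 28) and
common pathways are the per-stage intersections of each model's
significant sets, with persistence across all stages flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .differential_expression import DEGTable
from .io_formats import STAGES, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int           # overlap with the DEG list
    K: int           # set size within the background
    n: int           # DEG list size within the background
    N: int           # background size
    p_value: float
    overlap_genes: tuple[str, ...]


@dataclass(frozen=True)
class StageMatching:
    """Ordered one-to-one pairing of the two models' time-points per stage."""

    pairs: tuple[tuple[str, str, str], ...]  # (stage, model_a_tp, model_b_tp)

    def __post_init__(self) -> None:
        stages = [s for s, _, _ in self.pairs]
        a_tps = [a for _, a, _ in self.pairs]
        b_tps = [b for _, _, b in self.pairs]
        if len(set(a_tps)) != len(a_tps) or len(set(b_tps)) != len(b_tps):
            raise ValueError("stage matching must be one-to-one")
        if stages != [s for s in STAGES if s in stages]:
            raise ValueError(f"stages must be ordered as {STAGES}")

    @classmethod
    def default(cls) -> "StageMatching":
        # both synthetic models label their comparisons by stage directly
        return cls(tuple((s, s, s) for s in STAGES))

    def stages(self) -> list[str]:
        return [s for s, _, _ in self.pairs]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); exact, in [0, 1]."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    deg_ids,
    collection: GeneSetCollection,
    background_ids,
) -> list[EnrichmentResult]:
    """One-sided over-representation of a DEG list in every gene set.

    Genes outside the background are ignored (with a logged count).
    Results are sorted by ascending p-value, ties by set id.
    """
    background = set(background_ids)
    if not background:
        raise ValueError("empty background")
    degs = set(deg_ids)
    outside = degs - background
    if outside:
        logger.info("%d DEG ids outside the background ignored", len(outside))
        degs &= background
    if len(degs) > len(background):
        raise ValueError("DEG list larger than background")
    N = len(background)
    n = len(degs)
    results = []
    for gs in collection:
        members = gs.members & background
        K = len(members)
        if K == 0:
            continue
        overlap = tuple(sorted(members & degs))
        k = len(overlap)
        p = hypergeom_upper_tail(k, N, K, n)
        results.append(EnrichmentResult(gs.set_id, k, K, n, N, p, overlap))
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "overlap_genes": "|".join(r.overlap_genes),
            }
            for r in results
        ],
        columns=["set_id", "k", "K", "n", "N", "p_value", "overlap_genes"],
    )


def significant_pathways(
    results: list[EnrichmentResult], alpha: float = DEFAULT_ALPHA
) -> list[str]:
    """Set ids with p strictly below alpha, sorted by (p, set id)."""
    return [r.set_id for r in results if r.p_value < alpha]


def common_pathways(
    results_a: dict[str, list[EnrichmentResult]],
    results_b: dict[str, list[EnrichmentResult]],
    matching: StageMatching,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[dict[str, list[str]], list[str]]:
    """Per-stage intersection of both models' significant pathways.

    ``results_a`` / ``results_b`` map each model's time-point label to its
    enrichment results.  Returns ``(per_stage, persistent)`` where
    ``persistent`` lists pathways common at every matched stage — the
    dysregulated-at-all-further-time-points pattern.
    """
    per_stage: dict[str, list[str]] = {}
    for stage, tp_a, tp_b in matching.pairs:
        if tp_a not in results_a or tp_b not in results_b:
            raise KeyError(f"missing enrichment results for stage {stage!r}")
        collections_differ = {r.set_id for r in results_a[tp_a]} != {
            r.set_id for r in results_b[tp_b]
        }
        if collections_differ:
            logger.warning(
                "stage %s: the two models were enriched on different set universes",
                stage,
            )
        sig_a = set(significant_pathways(results_a[tp_a], alpha))
        sig_b = set(significant_pathways(results_b[tp_b], alpha))
        per_stage[stage] = sorted(sig_a & sig_b)
    stages = matching.stages()
    persistent = sorted(
        set.intersection(*(set(per_stage[s]) for s in stages)) if stages else set()
    )
    return per_stage, persistent


def direction_concordance(
    deg_a: DEGTable, deg_b: DEGTable
) -> dict:
    """Direction agreement of genes DEG in both models.

    A gene is *shared* when it is a DEG at >= 1 time-point in each model;
    its per-model direction is the sign of the log2FC of its
    largest-|log2FC| DEG call.  Concordance (both up or both down) is
    tested against 0.5 with a two-sided exact binomial (sign) test.
    """
    def directions(t: DEGTable) -> dict[str, int]:
        r = t.records[t.records["is_deg"]]
        if r.empty:
            return {}
        idx = r.groupby("gene")["log2fc"].apply(lambda s: s.abs().idxmax())
        return {
            g: (1 if t.records.loc[i, "log2fc"] > 0 else -1)
            for g, i in idx.items()
        }

    dir_a = directions(deg_a)
    dir_b = directions(deg_b)
    shared = sorted(set(dir_a) & set(dir_b))
    n_shared = len(shared)
    n_up = sum(1 for g in shared if dir_a[g] == 1 and dir_b[g] == 1)
    n_down = sum(1 for g in shared if dir_a[g] == -1 and dir_b[g] == -1)
    n_disc = n_shared - n_up - n_down
    if n_shared == 0:
        p = math.nan  # undefined: no shared DEGs to test
    else:
        p = float(stats.binomtest(n_up + n_down, n_shared, 0.5).pvalue)
    return {
        "n_shared": n_shared,
        "n_up_both": n_up,
        "n_down_both": n_down,
        "n_discordant": n_disc,
        "p_value": p,
        "shared_genes": shared,
    }
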