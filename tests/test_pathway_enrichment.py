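import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from conftest import make_study
from oracles import exact_hypergeom_tail
from sca1net.differential_expression import DEGTable
from sca1net.io_formats import GeneSet, GeneSetCollection
from sca1net.pathway_enrichment import (
    StageMatching,
    common_pathways,
    direction_concordance,
    enrich,
    hypergeom_upper_tail,
    significant_pathways,
    EnrichmentResult,
)


def _collection(**sets):
    return GeneSetCollection(
        {k: GeneSet(k, k, frozenset(v)) for k, v in sets.items()}
    )


def test_hand_computed_tail_value():
    # N=20, K=5, n=6, k=5: only C(5,5)*C(15,1) = 15 of C(20,6) = 38760 draws
    assert hypergeom_upper_tail(5, 20, 5, 6) == pytest.approx(15 / 38760, rel=1e-12)


def test_zero_overlap_gives_p_one():
    assert hypergeom_upper_tail(0, 20, 5, 6) == 1.0


def test_exact_agreement_with_enumeration_oracle():
    cases = [
        (12, 5, 4), (12, 3, 6), (10, 4, 4), (9, 2, 5), (8, 8, 3), (11, 6, 6),
    ]
    for N, K, n in cases:
        for k in range(0, min(K, n) + 1):
            oracle = exact_hypergeom_tail(k, N, K, n)
            ours = hypergeom_upper_tail(k, N, K, n)
            assert ours == pytest.approx(float(oracle), rel=1e-10), (N, K, n, k)


def test_tail_monotone_nonincreasing_in_k():
    N, K, n = 40, 12, 9
    ps = [hypergeom_upper_tail(k, N, K, n) for k in range(min(K, n) + 1)]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def test_enrich_background_restriction_and_sorting():
    coll = _collection(P1=["g1", "g2", "g3"], P2=["g4", "g5", "gX"])
    bg = [f"g{i}" for i in range(1, 10)]  # gX outside the background
    res = enrich(["g1", "g2", "g4"], coll, bg)
    by_id = {r.set_id: r for r in res}
    assert by_id["P1"].K == 3 and by_id["P2"].K == 2  # gX not counted
    assert by_id["P1"].k == 2 and by_id["P2"].k == 1
    assert [r.p_value for r in res] == sorted(r.p_value for r in res)


def test_enrich_ignores_degs_outside_background():
    coll = _collection(P1=["g1", "g2"])
    res = enrich(["g1", "zz"], coll, ["g1", "g2", "g3"])
    assert res[0].n == 1  # 'zz' ignored


def test_enrich_saturated_list_gives_p_one():
    coll = _collection(P1=["g1", "g2"], P2=["g3"])
    bg = ["g1", "g2", "g3", "g4"]
    res = enrich(bg, coll, bg)
    assert all(r.p_value == 1.0 for r in res)
    assert all(r.k == r.K for r in res)


def test_enrich_empty_background_rejected():
    with pytest.raises(ValueError, match="background"):
        enrich(["g1"], _collection(P1=["g1"]), [])


def _res(set_id, p):
    return EnrichmentResult(set_id, 1, 1, 1, 10, p, ("g",))


def test_significant_pathways_strict_alpha():
    res = [_res("A", 0.049), _res("B", 0.05), _res("C", 0.51)]
    assert significant_pathways(res, alpha=0.05) == ["A"]
    assert significant_pathways([], alpha=0.05) == []


def test_common_pathways_intersection_and_persistence():
    matching = StageMatching.default()
    ra = {s: [_res("P1", 0.01), _res("P2", 0.02), _res("P3", 0.9)]
          for s in ("early", "middle", "late")}
    rb = {
        "early": [_res("P1", 0.01), _res("P2", 0.5), _res("P3", 0.01)],
        "middle": [_res("P1", 0.04), _res("P2", 0.04), _res("P3", 0.9)],
        "late": [_res("P1", 0.001), _res("P2", 0.2), _res("P3", 0.2)],
    }
    per_stage, persistent = common_pathways(ra, rb, matching)
    assert per_stage == {"early": ["P1"], "middle": ["P1", "P2"], "late": ["P1"]}
    assert persistent == ["P1"]  # common at every stage


def test_common_pathways_disjoint_significance_empty():
    matching = StageMatching.default()
    ra = {s: [_res("P1", 0.01), _res("P2", 0.9)] for s in ("early", "middle", "late")}
    rb = {s: [_res("P1", 0.9), _res("P2", 0.01)] for s in ("early", "middle", "late")}
    per_stage, persistent = common_pathways(ra, rb, matching)
    assert all(v == [] for v in per_stage.values())
    assert persistent == []


def test_stage_matching_must_be_one_to_one():
    with pytest.raises(ValueError, match="one-to-one"):
        StageMatching((("early", "D2", "W5"), ("middle", "D2", "W12")))


def _deg_table(model, entries):
    rec = pd.DataFrame(
        [(g, tp, 2.0, 1.0, 2.0 ** l, l, p, deg)
         for g, tp, l, p, deg in entries],
        columns=["gene", "time_point", "mean_case", "mean_control", "fc",
                 "log2fc", "p_value", "is_deg"],
    )
    return DEGTable(model, rec)


def test_concordance_exact_binomial_examples():
    # 10 shared genes, 9 concordant: p = 2 * (C(10,9) + C(10,10)) / 2^10
    a_rows = [(f"g{i}", "early", 1.0, 0.01, True) for i in range(10)]
    b_rows = [(f"g{i}", "early", 1.0 if i < 9 else -1.0, 0.01, True)
              for i in range(10)]
    res = direction_concordance(_deg_table("a", a_rows), _deg_table("b", b_rows))
    assert res["n_shared"] == 10
    assert res["n_up_both"] == 9 and res["n_discordant"] == 1
    assert res["p_value"] == pytest.approx(22 / 1024, rel=1e-12)


def test_concordance_two_genes_all_up():
    a_rows = [("g0", "early", 1.0, 0.01, True), ("g1", "early", 0.9, 0.01, True)]
    res = direction_concordance(_deg_table("a", a_rows), _deg_table("b", a_rows))
    assert (res["n_shared"], res["n_up_both"], res["n_down_both"],
            res["n_discordant"]) == (2, 2, 0, 0)
    assert res["p_value"] == pytest.approx(0.5)


def test_concordance_empty_overlap_p_undefined():
    a = _deg_table("a", [("g0", "early", 1.0, 0.01, True)])
    b = _deg_table("b", [("g1", "early", 1.0, 0.01, True)])
    res = direction_concordance(a, b)
    assert res["n_shared"] == 0
    assert math.isnan(res["p_value"])


def test_concordance_direction_from_largest_magnitude_call():
    # gene DEG at two time-points with opposite signs: the larger |log2FC|
    # (the late -2.0) defines the model-level direction
    a = _deg_table("a", [("g0", "early", 1.0, 0.01, True),
                         ("g0", "late", -2.0, 0.01, True)])
    b = _deg_table("b", [("g0", "early", -0.8, 0.01, True)])
    res = direction_concordance(a, b)
    assert res["n_down_both"] == 1 and res["n_discordant"] == 0


def test_planted_shared_pathways_recovered_per_stage(small_config):
    """Every planted shared pathway surfaces as common from its onset stage
    onward; the unshared distractor never does."""
    from sca1net.synthetic_data import (
        collection_from_memberships, simulate_study_pair,
    )
    from sca1net.differential_expression import deg_analysis
    from sca1net.orthology_mapping import map_to_target_namespace

    a, b, manifest = simulate_study_pair(small_config)
    coll = collection_from_memberships(manifest.pathway_memberships)
    deg_a = deg_analysis(a)
    deg_b = map_to_target_namespace(deg_analysis(b), manifest.ortholog_map)
    bg = sorted(set(a.genes) & coll.universe())
    ra = {tp: enrich(deg_a.degs(tp), coll, bg) for tp in ("early", "middle", "late")}
    rb = {tp: enrich(deg_b.degs(tp), coll, bg) for tp in ("early", "middle", "late")}
    per_stage, persistent = common_pathways(ra, rb, StageMatching.default())
    assert per_stage == {
        "early": ["PW000"],
        "middle": ["PW000", "PW001"],
        "late": ["PW000", "PW001", "PW002"],
    }
    assert persistent == ["PW000"]
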