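import numpy as np
import pandas as pd
import pytest

from sca1net.io_formats import STAGES
from sca1net.synthetic_data import (
    PlantedPathway,
    SimulationConfig,
    simulate_drug_tables,
    simulate_interactome,
    simulate_null_comparison,
    simulate_study_pair,
)


def test_no_planted_pathways_means_zero_ground_truth():
    cfg = SimulationConfig(n_genes=50, n_pathways=3, genes_per_pathway=(5, 8), seed=1)
    _, _, manifest = simulate_study_pair(cfg)
    assert manifest.true_log2fc["cells"] == {}
    assert manifest.true_log2fc["mice"] == {}


def test_onset_persists_at_all_later_stages_in_both_models():
    cfg = SimulationConfig(
        n_genes=60, n_pathways=2, genes_per_pathway=(5, 6),
        planted_pathways=[PlantedPathway("PW000", "early", 1.0, "up", shared=True)],
        seed=2,
    )
    _, _, manifest = simulate_study_pair(cfg)
    members = manifest.pathway_memberships["PW000"]
    for model in ("cells", "mice"):
        per_model = manifest.true_log2fc[model]
        assert len(per_model) == len(members)
        for per_stage in per_model.values():
            assert set(per_stage) == set(STAGES)
            assert all(v == 1.0 for v in per_stage.values())


def test_unshared_pathway_absent_from_mouse_truth():
    cfg = SimulationConfig(
        n_genes=60, n_pathways=2, genes_per_pathway=(5, 6),
        planted_pathways=[PlantedPathway("PW001", "middle", 1.0, shared=False)],
        seed=2,
    )
    _, _, manifest = simulate_study_pair(cfg)
    assert manifest.true_log2fc["cells"]
    assert manifest.true_log2fc["mice"] == {}


def test_fixed_seed_reproducibility():
    cfg = SimulationConfig(n_genes=40, n_pathways=2, genes_per_pathway=(4, 6),
                           planted_pathways=[PlantedPathway("PW000", "late", 0.8)],
                           seed=11)
    a1, b1, m1 = simulate_study_pair(cfg)
    a2, b2, m2 = simulate_study_pair(cfg)
    assert a1 == a2 and b1 == b2
    assert m1.true_log2fc == m2.true_log2fc
    assert m1.ortholog_map.equals(m2.ortholog_map)
    p1 = simulate_interactome(cfg, m1.pathway_memberships)
    p2 = simulate_interactome(cfg, m2.pathway_memberships)
    assert p1.edges.equals(p2.edges) and p1.tissue_scores == p2.tissue_scores


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(frac_downregulated=1.5).validate()
    with pytest.raises(ValueError):
        PlantedPathway("P", "early", float("nan"))
    with pytest.raises(ValueError):
        PlantedPathway("P", "dawn", 1.0)


def test_planted_effect_recovered_at_low_noise():
    """Mean empirical log2FC of perturbed genes approaches the planted
    effect as noise vanishes (within 3 standard errors over replicates)."""
    effects = []
    for seed in range(200):
        cfg = SimulationConfig(
            n_genes=30, n_pathways=1, genes_per_pathway=(6, 6),
            noise_sd=1e-3,
            planted_pathways=[PlantedPathway("PW000", "early", 1.0, "up")],
            seed=seed,
        )
        a, _, m = simulate_study_pair(cfg)
        members = m.pathway_memberships["PW000"]
        case = a.group_matrix("D2").loc[members].mean(axis=1)
        ctrl = a.group_matrix("D0").loc[members].mean(axis=1)
        effects.extend(np.log2(case / ctrl))
    effects = np.asarray(effects)
    se = effects.std(ddof=1) / np.sqrt(len(effects))
    assert abs(effects.mean() - 1.0) < 3 * max(se, 1e-6)


def test_frac_downregulated_matches_sign_draws():
    cfg = SimulationConfig(
        n_genes=900, n_pathways=60, genes_per_pathway=(10, 14),
        frac_downregulated=0.6,
        planted_pathways=[PlantedPathway(f"PW{i:03d}", "early", 1.0, "mixed")
                          for i in range(60)],
        seed=5,
    )
    _, _, m = simulate_study_pair(cfg)
    signs = [per["early"] for per in m.true_log2fc["cells"].values()]
    frac_down = np.mean([s < 0 for s in signs])
    n = len(signs)
    tol = 3 * np.sqrt(0.6 * 0.4 / n)
    assert abs(frac_down - 0.6) < tol


def test_interactome_zero_probability_gives_empty_table():
    cfg = SimulationConfig(n_genes=20, n_pathways=1, genes_per_pathway=(4, 4),
                           ppi_within_pathway_prob=0.0, ppi_background_prob=0.0,
                           seed=3)
    _, _, m = simulate_study_pair(cfg)
    # suppress the always-on hub wiring by querying an empty membership
    ppi = simulate_interactome(cfg, {})
    assert len(ppi) == 0


def test_interactome_complete_within_pathway():
    cfg = SimulationConfig(n_genes=10, n_pathways=1, genes_per_pathway=(4, 4),
                           ppi_within_pathway_prob=1.0, ppi_background_prob=0.0,
                           seed=3)
    _, _, m = simulate_study_pair(cfg)
    members = m.pathway_memberships["PW000"]
    ppi = simulate_interactome(cfg, m.pathway_memberships)
    pairs = {frozenset(p) for p in zip(ppi.edges["node_a"], ppi.edges["node_b"])}
    expected = {frozenset({a, b}) for i, a in enumerate(members)
                for b in members[i + 1:]}
    assert pairs == expected  # all 6 within-pathway pairs, nothing else


def test_interactome_hub_connected_to_all_pathway_members():
    cfg = SimulationConfig(n_genes=40, n_pathways=1, genes_per_pathway=(8, 8),
                           ppi_within_pathway_prob=0.0, ppi_background_prob=0.0,
                           seed=9)
    _, _, m = simulate_study_pair(cfg)
    hub = m.pathway_memberships["PW000"][0]
    ppi = simulate_interactome(cfg, m.pathway_memberships)
    incident = set(ppi.edges["node_a"]) | set(ppi.edges["node_b"])
    assert hub in incident
    deg = (ppi.edges["node_a"] == hub).sum() + (ppi.edges["node_b"] == hub).sum()
    assert deg == len(m.pathway_memberships["PW000"]) - 1


def test_drug_tables_structure_and_planted_positives():
    cfg = SimulationConfig(seed=4)
    dt, bbb, planted = simulate_drug_tables(cfg, ["GENE0001", "GENE0002"])
    assert len(dt) == 2 * cfg.n_drugs_per_target
    counts = bbb.groupby("drug_id").size()
    assert (counts == 8).all()
    for drug in dt["drug_id"]:
        calls = bbb[bbb["drug_id"] == drug]
        n_pos = (calls["call"] == "BBB+").sum()
        if drug in planted["bbb_positive"]:
            assert n_pos == 8
        else:
            assert n_pos < 8


def test_drug_tables_empty_targets():
    dt, bbb, planted = simulate_drug_tables(SimulationConfig(seed=1), [])
    assert len(dt) == 0 and len(bbb) == 0 and planted["bbb_positive"] == []


def test_null_comparison_shapes_and_nonnegative(rng):
    case, ctrl = simulate_null_comparison(100, 3, rng=rng)
    assert case.shape == (100, 3) and ctrl.shape == (100, 3)
    assert (case > 0).all() and (ctrl > 0).all()
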