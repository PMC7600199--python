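"""Synthetic two-model aggregation study generator with planted ground truth.

Emulates the statistical structure of a paired in vitro / in vivo polyQ
aggregation experiment: a cell model sampled at one baseline (Day 0) plus
three aggregation time-points, and a mouse model sampled at three ages each
with its own age-matched control group, three replicates throughout.
Pathway-level perturbations are planted with a stage-dependent onset and
persist at all later stages; most planted effects are downregulations, as
is characteristic of polyQ-aggregation transcriptomes.

FPKM values are generated directly (no read-level simulation): per-gene
log2 baselines are Gaussian (i.e. log-normal FPKM), replicate noise is
additive Gaussian on the log2 scale, and planted effects shift the case
mean by a known log2 fold-change from the onset stage onward.  Every
quantity a downstream stage should recover is recorded in a
:class:`GroundTruthManifest`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    STAGES,
    CONTROL_LABEL,
    ExpressionStudy,
    GeneSet,
    GeneSetCollection,
    PPIEdgeTable,
)

MODEL_A = "cells"
MODEL_B = "mice"

# group labels mirror the motivating study's sampling points
_A_GROUPS = {"early": "D2", "middle": "D5", "late": "D10"}
_A_CONTROL = "D0"
_B_GROUPS = {"early": "W5", "middle": "W12", "late": "W28"}

ALGORITHMS = ("ADABoost", "SVM")
FINGERPRINTS = ("MACCS", "Openbabel", "Molprint", "PubChem")


@dataclass(frozen=True)
class PlantedPathway:
    """A pathway perturbed from ``onset`` stage onward.

    ``direction`` is ``up``, ``down`` or ``mixed``; ``mixed`` draws each
    member gene's sign independently (down with probability
    ``frac_downregulated``).  ``shared`` pathways are perturbed in both
    models; unshared ones only in the cell model and therefore must never
    surface as cross-model common pathways.
    """

    pathway_id: str
    onset: str
    effect: float
    direction: str = "mixed"
    shared: bool = True

    def __post_init__(self) -> None:
        if self.onset not in STAGES:
            raise ValueError(f"onset must be one of {STAGES}, got {self.onset!r}")
        if self.direction not in ("up", "down", "mixed"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not np.isfinite(self.effect):
            raise ValueError("effect log2FC must be finite")


@dataclass
class SimulationConfig:
    n_genes: int = 600
    n_pathways: int = 12
    genes_per_pathway: tuple[int, int] = (10, 18)
    n_replicates: int = 3
    time_points: tuple[str, ...] = (CONTROL_LABEL,) + STAGES
    planted_pathways: list[PlantedPathway] = field(default_factory=list)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    noise_sd: float = 0.25
    ppi_within_pathway_prob: float = 0.45
    ppi_background_prob: float = 0.002
    within_confidence_range: tuple[float, float] = (0.95, 1.0)
    background_confidence_range: tuple[float, float] = (0.30, 1.0)
    tissue_score_range: tuple[float, float] = (0.0, 10.0)
    frac_downregulated: float = 0.6
    ortholog_one_to_one_frac: float = 0.9
    n_drugs_per_target: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_pathways < 0 or self.n_replicates <= 0:
            raise ValueError("dimensions must be positive")
        lo, hi = self.genes_per_pathway
        if lo <= 0 or hi < lo:
            raise ValueError("genes_per_pathway range invalid")
        for p in (
            self.ppi_within_pathway_prob,
            self.ppi_background_prob,
            self.frac_downregulated,
            self.ortholog_one_to_one_frac,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for pp in self.planted_pathways:
            if not np.isfinite(pp.effect):
                raise ValueError("planted effect non-finite")
        if self.n_pathways and self.n_genes < hi:
            raise ValueError("gene universe smaller than a single pathway")


@dataclass
class GroundTruthManifest:
    """Everything a downstream stage should recover, recorded at planting.

    ``true_log2fc`` holds only the non-zero entries, keyed
    model -> gene (in that model's namespace) -> stage.
    """

    true_log2fc: dict[str, dict[str, dict[str, float]]]
    perturbed_pathways: list[dict]
    pathway_memberships: dict[str, list[str]]
    planted_hubs: list[str]
    ortholog_map: pd.DataFrame
    drug_target_pairs: list[tuple[str, str]] = field(default_factory=list)
    bbb_positive_drugs: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "true_log2fc": self.true_log2fc,
            "perturbed_pathways": self.perturbed_pathways,
            "pathway_memberships": self.pathway_memberships,
            "planted_hubs": self.planted_hubs,
            "ortholog_map": self.ortholog_map.to_dict(orient="records"),
            "drug_target_pairs": [list(p) for p in self.drug_target_pairs],
            "bbb_positive_drugs": self.bbb_positive_drugs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_log2fc=d["true_log2fc"],
            perturbed_pathways=d["perturbed_pathways"],
            pathway_memberships=d["pathway_memberships"],
            planted_hubs=d["planted_hubs"],
            ortholog_map=pd.DataFrame(
                d["ortholog_map"], columns=["source_id", "target_id", "rank_score"]
            ),
            drug_target_pairs=[tuple(p) for p in d["drug_target_pairs"]],
            bbb_positive_drugs=d["bbb_positive_drugs"],
        )


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(n)]


def _mouse_ids(n: int) -> list[str]:
    return [f"Mus{i:04d}" for i in range(n)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent child streams per artifact, all reproducible from config.seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _draw_memberships(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Disjoint pathway memberships drawn without replacement.

    Disjointness keeps the planted ground truth unambiguous: a gene's true
    fold-change is determined by at most one pathway.
    """
    genes = _gene_ids(config.n_genes)
    pool = list(genes)
    memberships: dict[str, list[str]] = {}
    lo, hi = config.genes_per_pathway
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if size > len(pool):
            # pool exhausted: fall back to sampling from the full universe
            chosen = list(rng.choice(genes, size=size, replace=False))
        else:
            idx = rng.choice(len(pool), size=size, replace=False)
            chosen = [pool[j] for j in sorted(idx)]
            pool = [g for j, g in enumerate(pool) if j not in set(idx)]
        memberships[f"PW{i:03d}"] = chosen
    return memberships


def _plant_effects(
    config: SimulationConfig,
    memberships: dict[str, list[str]],
    rng: np.random.Generator,
) -> dict[str, dict[str, float]]:
    """Per-gene signed log2FC at each stage (human namespace), planted
    pathway by planted pathway; effects persist from onset onward."""
    effects: dict[str, dict[str, float]] = {}
    for pp in config.planted_pathways:
        if pp.pathway_id not in memberships:
            raise ValueError(f"planted pathway {pp.pathway_id!r} not in collection")
        onset_idx = STAGES.index(pp.onset)
        for gene in memberships[pp.pathway_id]:
            if pp.direction == "up":
                sign = 1.0
            elif pp.direction == "down":
                sign = -1.0
            else:
                sign = -1.0 if rng.random() < config.frac_downregulated else 1.0
            lfc = sign * abs(pp.effect)
            per_stage = effects.setdefault(gene, {})
            for stage in STAGES[onset_idx:]:
                per_stage[stage] = per_stage.get(stage, 0.0) + lfc
    return effects


def _sample_matrix(
    baselines: np.ndarray,
    shift: np.ndarray,
    n_reps: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """FPKM = 2**(baseline + shift + N(0, noise_sd)), genes x replicates."""
    log2 = (
        baselines[:, None]
        + shift[:, None]
        + rng.normal(0.0, noise_sd, size=(len(baselines), n_reps))
    )
    return np.exp2(log2)


def simulate_ortholog_map(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Mouse-to-human ortholog map with integer rank scores.

    90% of mouse genes (by default) map 1:1 to their true human ortholog at
    the top rank class (score 10); the rest additionally carry a spurious
    low-rank mapping (score 1-4) to a random other human gene, exercising
    the high-rank-score filter downstream.
    """
    if rng is None:
        rng = _rng(config, 3)
    human = _gene_ids(config.n_genes)
    mouse = _mouse_ids(config.n_genes)
    rows = []
    for i, (src, tgt) in enumerate(zip(mouse, human)):
        rows.append({"source_id": src, "target_id": tgt, "rank_score": 10})
        if rng.random() >= config.ortholog_one_to_one_frac:
            j = int(rng.integers(config.n_genes))
            if j == i:
                j = (j + 1) % config.n_genes
            rows.append(
                {
                    "source_id": src,
                    "target_id": human[j],
                    "rank_score": int(rng.integers(1, 5)),
                }
            )
    return pd.DataFrame(rows, columns=["source_id", "target_id", "rank_score"])


def simulate_study_pair(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, ExpressionStudy, GroundTruthManifest]:
    """Generate the paired cell-model and mouse-model expression studies.

    The cell model compares every aggregation time-point to a single Day-0
    baseline; the mouse model carries an age-matched control group per
    time-point.  Mouse genes are the model-B namespace images of the human
    universe, linked through the generated ortholog map.
    """
    config.validate()
    rng_mem = _rng(config, 0)
    rng_fx = _rng(config, 1)
    rng_expr = _rng(config, 2)

    memberships = _draw_memberships(config, rng_mem)
    effects_human = _plant_effects(config, memberships, rng_fx)
    ortho = simulate_ortholog_map(config)

    human = _gene_ids(config.n_genes)
    mouse = _mouse_ids(config.n_genes)
    h2m = dict(zip(human, mouse))

    base_a = rng_expr.normal(
        config.baseline_log_mean, config.baseline_log_sd, config.n_genes
    )
    base_b = rng_expr.normal(
        config.baseline_log_mean, config.baseline_log_sd, config.n_genes
    )

    shared_flags = {pp.pathway_id: pp.shared for pp in config.planted_pathways}
    gene_pw = {
        g: pid for pid, members in memberships.items() for g in members
    }

    def shift_vector(model: str, stage: str) -> np.ndarray:
        out = np.zeros(config.n_genes)
        for gi, g in enumerate(human):
            lfc = effects_human.get(g, {}).get(stage, 0.0)
            if lfc == 0.0:
                continue
            if model == MODEL_B and not shared_flags.get(gene_pw.get(g), True):
                continue
            out[gi] = lfc
        return out

    n_rep = config.n_replicates
    noise = config.noise_sd

    # --- model A: single Day-0 baseline + three aggregation time-points
    cols_a: dict[str, np.ndarray] = {}
    design_a = []
    ctrl = _sample_matrix(base_a, np.zeros(config.n_genes), n_rep, noise, rng_expr)
    for r in range(n_rep):
        sid = f"{_A_CONTROL}_r{r + 1}"
        cols_a[sid] = ctrl[:, r]
        design_a.append((sid, _A_CONTROL, CONTROL_LABEL, r + 1, "control"))
    for stage in STAGES:
        mat = _sample_matrix(base_a, shift_vector(MODEL_A, stage), n_rep, noise, rng_expr)
        grp = _A_GROUPS[stage]
        for r in range(n_rep):
            sid = f"{grp}_r{r + 1}"
            cols_a[sid] = mat[:, r]
            design_a.append((sid, grp, stage, r + 1, "case"))
    study_a = ExpressionStudy(
        model_id=MODEL_A,
        fpkm=pd.DataFrame(cols_a, index=pd.Index(human, name="gene_id")),
        design=pd.DataFrame(
            design_a, columns=["sample_id", "group", "time_point", "replicate", "role"]
        ),
    )

    # --- model B: per-age case and control groups
    cols_b: dict[str, np.ndarray] = {}
    design_b = []
    for stage in STAGES:
        grp = _B_GROUPS[stage]
        case = _sample_matrix(base_b, shift_vector(MODEL_B, stage), n_rep, noise, rng_expr)
        ctrl = _sample_matrix(base_b, np.zeros(config.n_genes), n_rep, noise, rng_expr)
        for r in range(n_rep):
            sid = f"{grp}_r{r + 1}"
            cols_b[sid] = case[:, r]
            design_b.append((sid, grp, stage, r + 1, "case"))
        for r in range(n_rep):
            sid = f"{grp}c_r{r + 1}"
            cols_b[sid] = ctrl[:, r]
            design_b.append((sid, f"{grp}c", stage, r + 1, "control"))
    study_b = ExpressionStudy(
        model_id=MODEL_B,
        fpkm=pd.DataFrame(cols_b, index=pd.Index(mouse, name="gene_id")),
        design=pd.DataFrame(
            design_b, columns=["sample_id", "group", "time_point", "replicate", "role"]
        ),
    )

    true_a = {
        g: {s: v for s, v in per.items() if v != 0.0}
        for g, per in effects_human.items()
    }
    true_b = {}
    for g, per in effects_human.items():
        if not shared_flags.get(gene_pw.get(g), True):
            continue
        true_b[h2m[g]] = {s: v for s, v in per.items() if v != 0.0}

    hubs = [
        memberships[pp.pathway_id][0]
        for pp in config.planted_pathways
        if memberships.get(pp.pathway_id)
    ]
    manifest = GroundTruthManifest(
        true_log2fc={MODEL_A: true_a, MODEL_B: true_b},
        perturbed_pathways=[asdict(pp) for pp in config.planted_pathways],
        pathway_memberships=memberships,
        planted_hubs=hubs,
        ortholog_map=ortho,
    )
    return study_a, study_b, manifest


def collection_from_memberships(
    memberships: dict[str, list[str]]
) -> GeneSetCollection:
    return GeneSetCollection(
        {
            pid: GeneSet(pid, f"synthetic pathway {pid}", frozenset(members))
            for pid, members in memberships.items()
        }
    )


def simulate_interactome(
    config: SimulationConfig, pathway_memberships: dict[str, list[str]]
) -> PPIEdgeTable:
    """Planted-module PPI graph over the human gene universe.

    Within-pathway pairs are wired densely with confidences drawn from the
    high (planted) range; background pairs are sparse with a broad
    confidence distribution.  The first member of each pathway acts as a
    planted hub connected to every other member.  Tissue scores are uniform
    over ``tissue_score_range`` for background genes; pathway members draw
    from the upper half of the range so planted modules survive a
    nervous-system expression filter.
    """
    config.validate()
    genes = _gene_ids(config.n_genes)
    if not genes:
        raise ValueError("empty gene universe")
    rng = _rng(config, 4)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    within_pairs: set[tuple[int, int]] = set()
    hub_pairs: set[tuple[int, int]] = set()
    member_idx: set[int] = set()
    for members in pathway_memberships.values():
        idxs = sorted(index[g] for g in members)
        member_idx.update(idxs)
        if not idxs:
            continue
        hub = idxs[0]
        for a_pos, a in enumerate(idxs):
            for b in idxs[a_pos + 1:]:
                within_pairs.add((a, b))
                if a == hub or b == hub:
                    hub_pairs.add((a, b))

    rows: list[tuple[str, str, float]] = []
    lo_w, hi_w = config.within_confidence_range
    for a, b in sorted(within_pairs):
        planted_hub = (a, b) in hub_pairs
        if planted_hub or rng.random() < config.ppi_within_pathway_prob:
            conf = rng.uniform(lo_w, hi_w)
            rows.append((genes[a], genes[b], conf))

    # vectorized sparse background over all remaining unordered pairs
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < config.ppi_background_prob
    lo_b, hi_b = config.background_confidence_range
    for a, b in zip(iu[mask], ju[mask]):
        a, b = int(a), int(b)
        if (a, b) in within_pairs:
            continue
        rows.append((genes[a], genes[b], rng.uniform(lo_b, hi_b)))

    lo_t, hi_t = config.tissue_score_range
    mid = lo_t + 0.5 * (hi_t - lo_t)
    tissue = {}
    for g in genes:
        if index[g] in member_idx:
            tissue[g] = float(rng.uniform(mid, hi_t))
        else:
            tissue[g] = float(rng.uniform(lo_t, hi_t))

    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    return PPIEdgeTable(edges=edges, tissue_scores=tissue)


def simulate_drug_tables(
    config: SimulationConfig, targets: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drug-target interactions plus an 8-call BBB prediction table.

    Every drug carries exactly one call per (algorithm, fingerprint)
    combination; roughly half the drugs are planted fully BBB-positive (the
    only ones a strict 8/8 consensus may accept).  Returns
    ``(drug_target_table, bbb_call_table, planted)`` where ``planted``
    records the fully-positive drugs and the planted (drug, target) pairs.
    """
    if len(targets) == 0:
        empty_dt = pd.DataFrame(
            columns=["drug_id", "target_id", "interaction_score", "approval_status"]
        )
        empty_bbb = pd.DataFrame(columns=["drug_id", "algorithm", "fingerprint", "call"])
        return empty_dt, empty_bbb, {"bbb_positive": [], "pairs": []}
    rng = _rng(config, 5)
    dt_rows = []
    bbb_rows = []
    planted_pos: list[str] = []
    pairs: list[tuple[str, str]] = []
    k = 0
    for target in targets:
        for _ in range(config.n_drugs_per_target):
            drug = f"DRUG{k:03d}"
            k += 1
            score = float(np.round(rng.uniform(0.0, 1.0), 3))
            status = "approved" if rng.random() < 0.7 else "clinical-trial"
            dt_rows.append((drug, target, score, status))
            pairs.append((drug, target))
            fully_positive = bool(rng.random() < 0.5)
            if fully_positive:
                planted_pos.append(drug)
                flips: set[int] = set()
            else:
                n_neg = int(rng.integers(1, 9))
                flips = set(rng.choice(8, size=n_neg, replace=False).tolist())
            for ci, (alg, fp) in enumerate(
                (a, f) for a in ALGORITHMS for f in FINGERPRINTS
            ):
                call = "BBB-" if ci in flips else "BBB+"
                bbb_rows.append((drug, alg, fp, call))
    dt = pd.DataFrame(
        dt_rows, columns=["drug_id", "target_id", "interaction_score", "approval_status"]
    )
    bbb = pd.DataFrame(bbb_rows, columns=["drug_id", "algorithm", "fingerprint", "call"])
    return dt, bbb, {"bbb_positive": planted_pos, "pairs": pairs}


def simulate_null_comparison(
    n_genes: int,
    n_replicates: int,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One no-effect case/control FPKM draw (genes x replicates each).

    Used for null calibration of the DEG test: both groups share the same
    per-gene log-normal baseline and log2-scale Gaussian noise.
    """
    if config is None:
        config = SimulationConfig()
    if rng is None:
        rng = _rng(config, 6)
    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    zero = np.zeros(n_genes)
    case = _sample_matrix(base, zero, n_replicates, config.noise_sd, rng)
    ctrl = _sample_matrix(base, zero, n_replicates, config.noise_sd, rng)
    return case, ctrl
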