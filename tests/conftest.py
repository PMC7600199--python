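import numpy as np
import pandas as pd
import pytest

from sca1net.io_formats import ExpressionStudy
from sca1net.synthetic_data import PlantedPathway, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small paired-study configuration with three shared planted pathways
    (one per onset stage) and one unshared distractor."""
    return SimulationConfig(
        n_genes=400,
        n_pathways=8,
        genes_per_pathway=(10, 14),
        noise_sd=0.05,
        planted_pathways=[
            PlantedPathway("PW000", "early", 1.0),
            PlantedPathway("PW001", "middle", 1.0),
            PlantedPathway("PW002", "late", 1.0),
            PlantedPathway("PW003", "middle", 1.0, shared=False),
        ],
        seed=7,
    )


def make_study(case: np.ndarray, control: np.ndarray, model_id="toy",
               time_point="early") -> ExpressionStudy:
    """Two-group study from raw FPKM arrays (genes x replicates each)."""
    case = np.atleast_2d(case)
    control = np.atleast_2d(control)
    genes = [f"g{i}" for i in range(case.shape[0])]
    cols = {}
    design = []
    for r in range(case.shape[1]):
        sid = f"case_r{r + 1}"
        cols[sid] = case[:, r]
        design.append((sid, "case", time_point, r + 1, "case"))
    for r in range(control.shape[1]):
        sid = f"ctrl_r{r + 1}"
        cols[sid] = control[:, r]
        design.append((sid, "ctrl", "control", r + 1, "control"))
    return ExpressionStudy(
        model_id=model_id,
        fpkm=pd.DataFrame(cols, index=pd.Index(genes, name="gene_id")),
        design=pd.DataFrame(
            design, columns=["sample_id", "group", "time_point", "replicate", "role"]
        ),
    )
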