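"""Per-time-point fold-change, t-test and DEG calling on FPKM matrices.

The fold-change of a gene is the ratio of its mean case FPKM to its mean
control FPKM (a pseudocount guards the zero-control case), log2
transformed.  A two-sample t-test on replicate FPKM values supplies the
p-value, and a gene is called differentially expressed when
``|log2FC| > fc_threshold`` and ``p < p_threshold`` — both inequalities
strict.  No multiple-testing correction is applied at this stage; the
selection is deliberately on raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionStudy

DEFAULT_FC_THRESHOLD = 0.5   # on the log2 scale
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_PSEUDOCOUNT = 0.25   # FPKM units, added to both group means


@dataclass
class DEGTable:
    """Per-gene, per-time-point differential-expression records.

    ``records`` columns: gene, time_point, mean_case, mean_control, fc,
    log2fc, p_value, is_deg.  Thresholds are carried for provenance.
    """

    model_id: str
    records: pd.DataFrame
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    p_threshold: float = DEFAULT_P_THRESHOLD

    def degs(self, time_point: str | None = None) -> list[str]:
        """Gene ids flagged as DEG, optionally restricted to one time-point."""
        r = self.records
        mask = r["is_deg"]
        if time_point is not None:
            mask = mask & (r["time_point"] == time_point)
        return sorted(r.loc[mask, "gene"].unique())

    def time_points(self) -> list[str]:
        return list(dict.fromkeys(self.records["time_point"]))

    def write(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, path, model_id: str, fc_threshold=DEFAULT_FC_THRESHOLD,
             p_threshold=DEFAULT_P_THRESHOLD) -> "DEGTable":
        rec = pd.read_csv(path, sep="\t", dtype={"gene": str, "time_point": str})
        return cls(model_id, rec, fc_threshold, p_threshold)


def compute_fold_change(
    study: ExpressionStudy,
    case_group: str,
    control_group: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene FC and log2FC between two design groups.

    FC = (mean case FPKM + pseudocount) / (mean control FPKM + pseudocount);
    the pseudocount (default 0.25 FPKM) keeps the ratio finite when a gene
    is absent from the control group.
    """
    case = study.group_matrix(case_group)
    ctrl = study.group_matrix(control_group)
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    fc = (mean_case + pseudocount) / (mean_ctrl + pseudocount)
    if not np.all(np.isfinite(fc)) or (fc <= 0).any():
        bad = fc.index[~np.isfinite(fc) | (fc <= 0)][0]
        raise ValueError(
            f"non-finite fold change for gene {bad!r}; "
            "use a positive pseudocount when control means can be zero"
        )
    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "fc": fc,
            "log2fc": np.log2(fc),
        }
    )


def t_test_pvalues(
    case: np.ndarray, control: np.ndarray, test: str = "welch"
) -> np.ndarray:
    """Vectorized two-sided two-sample t-test, one row per gene.

    ``welch`` (unequal variances) is the default; ``student`` pools.  Rows
    where both groups are constant get p = 1 when the means are equal
    (no evidence of change) and p = 0 when they differ (an exact, noiseless
    difference).
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need at least 2 replicates per group for a t-test")
    if test not in ("welch", "student"):
        raise ValueError(f"unknown test {test!r}; use 'welch' or 'student'")
    import warnings

    with warnings.catch_warnings():
        # constant rows trip scipy's precision warning; they are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(case, control, axis=1, equal_var=(test == "student"))
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (case.std(axis=1) == 0) & (control.std(axis=1) == 0)
    if degenerate.any():
        eq = np.isclose(case.mean(axis=1), control.mean(axis=1))
        p[degenerate & eq] = 1.0
        p[degenerate & ~eq] = 0.0
    p = np.nan_to_num(p, nan=1.0)
    return np.clip(p, 0.0, 1.0)


def deg_test(
    study: ExpressionStudy,
    case_group: str,
    control_group: str,
    test: str = "welch",
) -> pd.Series:
    """Per-gene two-sided t-test p-values between two design groups."""
    case = study.group_matrix(case_group)
    ctrl = study.group_matrix(control_group)
    p = t_test_pvalues(case.values, ctrl.values, test=test)
    return pd.Series(p, index=case.index, name="p_value")


def call_degs(
    fold_changes: pd.DataFrame,
    p_values: pd.Series,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Apply the DEG rule: |log2FC| > fc_threshold AND p < p_threshold."""
    if set(fold_changes.index) != set(p_values.index):
        raise ValueError("fold-change and p-value gene universes differ")
    p = p_values.reindex(fold_changes.index)
    out = fold_changes.copy()
    out["p_value"] = p
    out["is_deg"] = (out["log2fc"].abs() > fc_threshold) & (p < p_threshold)
    return out


def deg_analysis(
    study: ExpressionStudy,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    test: str = "welch",
) -> DEGTable:
    """Run fold-change + t-test + DEG calling for every comparison in a study."""
    frames = []
    for time_point, case_group, control_group in study.comparisons():
        fc = compute_fold_change(study, case_group, control_group, pseudocount)
        p = deg_test(study, case_group, control_group, test=test)
        called = call_degs(fc, p, fc_threshold, p_threshold)
        called.insert(0, "time_point", time_point)
        called.insert(0, "gene", called.index)
        frames.append(called.reset_index(drop=True))
    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["gene", "time_point", "mean_case", "mean_control",
                     "fc", "log2fc", "p_value", "is_deg"]
        )
    )
    return DEGTable(study.model_id, records, fc_threshold, p_threshold)
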