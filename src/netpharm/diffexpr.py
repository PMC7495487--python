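"""Case/control differential expression on log2 intensity matrices.

This is a deliberately transparent joint-analysis stage for multi-batch
microarray studies: a location-only batch adjustment using known batch
labels, a per-gene Welch two-sample t-test on log2 values, Benjamini-
Hochberg adjustment across genes, and the conventional volcano rule
(adjusted P < 0.05 and |log2 fold change| > 1, both strict) to call
differentially expressed genes. Surrogate-variable estimation and
empirical-Bayes variance moderation are intentionally out of scope: the
thresholds, not the test internals, define the screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .target_assembly import TargetSet

logger = logging.getLogger(__name__)

__all__ = ["ExpressionStudy", "batch_adjust", "de_test", "volcano_filter"]

GROUP_CASE = "case"
GROUP_CONTROL = "control"


@dataclass
class ExpressionStudy:
    """A log2 expression matrix with per-sample group and batch labels.

    ``matrix`` is genes x samples; ``groups`` and ``batches`` are indexed
    by sample name and aligned with the matrix columns.
    """

    matrix: pd.DataFrame
    groups: pd.Series
    batches: pd.Series

    def __post_init__(self) -> None:
        cols = list(self.matrix.columns)
        if list(self.groups.index) != cols or list(self.batches.index) != cols:
            raise ValueError("groups/batches must be indexed by the matrix columns")
        bad = set(self.groups.unique()) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == GROUP_CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == GROUP_CONTROL])


def batch_adjust(study: ExpressionStudy) -> ExpressionStudy:
    """Shift each gene's per-batch mean to its pooled mean.

    A location-only adjustment: for each gene, every batch's sample values
    are translated so the batch mean equals the gene's mean over all
    samples. Group labels are untouched; with a single batch the transform
    is the identity.
    """
    batches = study.batches
    if batches.nunique() <= 1:
        logger.info("single batch: batch adjustment is the identity")
        return ExpressionStudy(study.matrix.copy(), study.groups, study.batches)
    m = study.matrix.copy()
    pooled = m.mean(axis=1)
    for b in batches.unique():
        cols = list(batches.index[batches == b])
        offset = m[cols].mean(axis=1) - pooled
        m[cols] = m[cols].sub(offset, axis=0)
    return ExpressionStudy(m, study.groups, study.batches)


def de_test(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene Welch test of case vs control on log2 values.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean case
    minus mean control), ``p_raw`` (two-sided Welch p), ``p_adj``
    (Benjamini-Hochberg across all tested genes) and ``passes`` (default
    volcano rule). Genes with zero variance in both groups and equal means
    get p = 1 rather than NaN.
    """
    case = study.matrix[study.case_samples].to_numpy(dtype=float)
    ctrl = study.matrix[study.control_samples].to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need >= 2 samples in each group for the Welch test")

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p_raw = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p_raw = np.asarray(p_raw, dtype=float)

    degenerate = ~np.isfinite(p_raw)
    if degenerate.any():
        # zero within-group variance in both groups: p=1 when means agree,
        # p=0 when a nonzero difference is measured without noise
        equal = np.isclose(log2fc, 0.0)
        p_raw[degenerate & equal] = 1.0
        p_raw[degenerate & ~equal] = 0.0
        logger.info("%d gene(s) with degenerate variance handled", int(degenerate.sum()))

    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    result = pd.DataFrame(
        {"log2fc": log2fc, "p_raw": p_raw, "p_adj": p_adj},
        index=study.matrix.index,
    )
    result["passes"] = (result["p_adj"] < 0.05) & (result["log2fc"].abs() > 1.0)
    return result


def volcano_filter(
    de: pd.DataFrame, p_max: float = 0.05, lfc_min: float = 1.0
) -> TargetSet:
    """Call DEGs by the volcano rule: p_adj < p_max and |log2fc| > lfc_min.

    Both inequalities are strict. Returns a TargetSet labelled ``"DEG"``
    with provenance tag ``"diffexpr"``.
    """
    kept = de.index[(de["p_adj"] < p_max) & (de["log2fc"].abs() > lfc_min)]
    symbols = {str(g).strip().upper() for g in kept}
    return TargetSet(
        label="DEG", symbols=symbols, provenance={s: {"diffexpr"} for s in symbols}
    )
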