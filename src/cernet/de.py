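"""Two-group differential expression with BH false-discovery-rate control.

logFC is the difference of group means on the log2 scale
(``mean(group_b) - mean(group_a)``, conventionally day8 minus day0).
Unpaired comparisons use Welch's t-test (unequal variances,
Welch-Satterthwaite degrees of freedom); paired comparisons use the
one-sample t-test on within-pair differences. Genes pass when
``|logFC| > lfc_min`` and ``q < fdr_max`` — both strict, matching the
usual ``|logFC| > 1`` convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

#: Output columns of a DE table.
DE_COLUMNS = ("logFC", "t", "p", "q", "direction")


def differential_expression(
    mat: ExpressionMatrix,
    group_a: str,
    group_b: str,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-gene logFC, t-statistic, p and BH q for group_b vs group_a.

    Parameters
    ----------
    mat
        Gene-level log2 matrix.
    group_a, group_b
        Group labels; logFC = mean(group_b) − mean(group_a), so ``up`` means
        higher in ``group_b``.
    paired
        Pair sample i of group_a with sample i of group_b (column order
        within group) and test the within-pair differences.

    Returns
    -------
    DataFrame indexed by gene with columns logFC, t, p, q, direction.
    Zero-variance genes get t = 0, p = 1 (a constant gene carries no evidence).
    """
    if mat.scale != "log2":
        raise ValueError("differential expression expects a log2-scale matrix")
    if mat.level != "gene":
        raise ValueError("differential expression expects a gene-level matrix")
    a = mat.values[mat.group_samples(group_a)].to_numpy(dtype=float)
    b = mat.values[mat.group_samples(group_b)].to_numpy(dtype=float)
    if paired:
        if a.shape[1] != b.shape[1]:
            raise ValueError(
                f"paired mode needs equal group sizes, got {a.shape[1]} vs {b.shape[1]}"
            )
        if a.shape[1] < 2:
            raise ValueError("paired mode needs at least 2 pairs")
        diff = b - a
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_1samp(diff, popmean=0.0, axis=1)
        t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    else:
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError("each group needs at least 2 samples")
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    # zero-variance guard: undefined t -> no evidence
    bad = ~np.isfinite(t) | ~np.isfinite(p)
    t = np.where(bad, 0.0, t)
    p = np.where(bad, 1.0, p)
    logfc = b.mean(axis=1) - a.mean(axis=1)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "q": adjust_bh(p),
            "direction": np.where(logfc > 0, "up", "down"),
        },
        index=mat.values.index,
    )
    table.index.name = "gene"
    return table


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over tails j>=i of p_(j)·m/j on the sorted p-values, clipped
    to 1 and mapped back to the input order; permutation-equivariant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_thresholds(
    table: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05
) -> tuple[pd.DataFrame, int, int]:
    """Flag genes with |logFC| > lfc_min and q < fdr_max (both strict).

    Returns the table with a ``passed`` column plus the up/down counts of
    the passed set.
    """
    if lfc_min < 0:
        raise ValueError(f"lfc_min must be >= 0, got {lfc_min}")
    out = table.copy()
    out["passed"] = (out["logFC"].abs() > lfc_min) & (out["q"] < fdr_max)
    n_up = int((out["passed"] & (out["logFC"] > 0)).sum())
    n_down = int((out["passed"] & (out["logFC"] < 0)).sum())
    return out, n_up, n_down


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")
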