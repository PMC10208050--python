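"""RT-qPCR relative quantification (2^-dCt) and group comparisons.

Replicate Ct values are averaged on the Ct scale, dCt is taken against a
reference gene measured in the same sample (e.g. GAPDH), and relative
expression is 2^-dCt. One PCR cycle corresponds to a factor of two in
template, so a global per-sample Ct shift (loading/efficiency) cancels in
dCt. Two groups are compared with Welch's t-test, three or more with
one-way ANOVA; the dispatched test name is returned alongside the
statistic and p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("sample", "group", "gene", "replicate", "ct")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "gene": str})
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table {path} missing columns {missing}")
    validate_ct_table(df)
    return df


def validate_ct_table(ct: pd.DataFrame) -> None:
    vals = ct["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or (vals <= 0).any():
        raise ValueError("Ct values must be finite and > 0")


def relative_expression(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Per (sample, gene) mean Ct, dCt against the reference gene, and 2^-dCt.

    Replicates are averaged first (arithmetic mean of Ct). The reference
    gene's own relative expression is exactly 1.
    """
    validate_ct_table(ct)
    mean_ct = ct.groupby(["sample", "gene"], sort=True)["ct"].mean()
    try:
        ref = mean_ct.xs(reference_gene, level="gene", drop_level=True)
    except KeyError:
        raise ValueError(
            f"reference gene {reference_gene!r} absent from the Ct table"
        ) from None
    missing = sorted(set(ct["sample"]) - set(ref.index))
    if missing:
        raise ValueError(f"samples missing the reference gene {reference_gene!r}: {missing}")
    out = mean_ct.reset_index().rename(columns={"ct": "mean_ct"})
    out["delta_ct"] = out["mean_ct"] - out["sample"].map(ref)
    out["rel_expr"] = np.exp2(-out["delta_ct"])
    groups = ct.drop_duplicates("sample").set_index("sample")["group"]
    out["group"] = out["sample"].map(groups)
    return out


def compare_groups(
    rel: pd.DataFrame,
    gene: str,
    groups: list[str] | None = None,
    log_scale: bool = False,
) -> tuple[float, float, str]:
    """Compare 2^-dCt of one gene across groups.

    Two groups dispatch to Welch's t-test, more to one-way ANOVA. With
    ``log_scale`` the comparison runs on log2 relative expression (i.e. on
    -dCt), which is symmetric in fold change.

    Returns (statistic, two-sided p, test name).
    """
    sub = rel[rel["gene"] == gene]
    if groups is None:
        groups = sorted(sub["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = []
    for g in groups:
        x = sub.loc[sub["group"] == g, "rel_expr"].to_numpy(dtype=float)
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples for gene {gene!r}")
        arrays.append(np.log2(x) if log_scale else x)
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: no evidence of any difference
        return 0.0, 1.0, "welch_t" if len(arrays) == 2 else "anova"
    if len(arrays) == 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        stat, p, name = float(res.statistic), float(res.pvalue), "welch_t"
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.f_oneway(*arrays)
        stat, p, name = float(res.statistic), float(res.pvalue), "anova"
    if not np.isfinite(stat):
        stat, p = 0.0, 1.0
    return stat, p, name


def summarize_genes(rel: pd.DataFrame, reference_gene: str, log_scale: bool = False) -> pd.DataFrame:
    """Per-gene group means, fold difference, test statistic, p and BH q.

    Fold difference is mean rel_expr of the last group over the first
    (groups in lexicographic order), mirroring case-vs-control reporting.
    """
    from .de import adjust_bh

    genes = sorted(g for g in rel["gene"].unique() if g != reference_gene)
    groups = sorted(rel["group"].unique())
    rows = []
    for gene in genes:
        stat, p, name = compare_groups(rel, gene, log_scale=log_scale)
        sub = rel[rel["gene"] == gene]
        means = {f"mean_{g}": sub.loc[sub["group"] == g, "rel_expr"].mean() for g in groups}
        fold = means[f"mean_{groups[-1]}"] / means[f"mean_{groups[0]}"]
        rows.append({"gene": gene, **means, "fold_change": fold, "statistic": stat, "p": p, "test": name})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = adjust_bh(df["p"].to_numpy())
    return df
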