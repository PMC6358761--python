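"""Expression binning, group clustering, and 2^-ΔΔCT qPCR quantification.

Expression values are binned at the survey's printed thresholds
(>6 extremely high, (4,6] high, (2,4] medium, (0,2] low, <=0 none) and genes
are grouped by average-linkage hierarchical clustering of their profiles.
qPCR fold changes use the 2^-ΔΔCT method with the reference-gene ΔCT at the
baseline timepoint, and replicate significance is a two-sided equal-variance
Student's t-test on ΔCT values (* p<0.05, ** p<0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind

from trihelix.errors import ValidationError

BIN_THRESHOLDS = (0.0, 2.0, 4.0, 6.0)
BIN_LABELS = ("none", "low", "medium", "high", "extremely_high")

CT_COLUMNS = ["gene", "condition", "replicate", "ct_target", "ct_reference"]


def bin_expression(value: float) -> str:
    """Category of one expression value at the printed thresholds."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValidationError("expression value is NaN")
    if value > 6:
        return "extremely_high"
    if value > 4:
        return "high"
    if value > 2:
        return "medium"
    if value > 0:
        return "low"
    return "none"


def bin_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`bin_expression` elementwise to a genes x conditions table."""
    if matrix.isna().any().any():
        raise ValidationError("expression matrix contains NaN")
    return matrix.map(bin_expression)


def cluster_genes(
    matrix: pd.DataFrame, k: int = 5, method: str = "average", metric: str = "euclidean"
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of gene expression profiles cut at ``k``
    groups; returns (labels indexed like the matrix, the linkage matrix).
    Rows are processed in id order so the partition is deterministic and
    permutation-invariant as a set."""
    if k > len(matrix):
        raise ValidationError(f"k={k} exceeds number of genes {len(matrix)}")
    ordered = matrix.sort_index(kind="stable")
    Z = linkage(ordered.values, method=method, metric=metric)
    labels = fcluster(Z, t=k, criterion="maxclust")
    series = pd.Series(labels, index=ordered.index, name="group")
    return series.reindex(matrix.index), Z


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    if not np.isfinite(df[["ct_target", "ct_reference"]].values).all():
        raise ValidationError("Ct values must be finite")
    return df


def ddct_fold_change(ct: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Relative expression by 2^-ΔΔCT.

    Per replicate, ΔCT = Ct_target - Ct_reference; ΔΔCT is taken against the
    mean baseline ΔCT of the same gene; the table reports the per-replicate
    fold changes' mean and SD and the fold change of the mean ΔΔCT.
    """
    df = ct.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    base = df[df["condition"] == baseline].groupby("gene")["dct"].mean()
    missing = sorted(set(df["gene"]) - set(base.index))
    if missing:
        raise ValidationError(f"baseline '{baseline}' missing for genes: {missing}")
    rows = []
    for (gene, condition), group in df.groupby(["gene", "condition"], sort=True):
        ddct_reps = group["dct"].to_numpy() - base[gene]
        fold_reps = 2.0 ** (-ddct_reps)
        rows.append(
            {
                "gene": gene,
                "condition": condition,
                "ddct": float(ddct_reps.mean()),
                "fold_change": float(2.0 ** (-ddct_reps.mean())),
                "fold_mean": float(fold_reps.mean()),
                "fold_sd": float(fold_reps.std(ddof=1)) if len(fold_reps) > 1 else 0.0,
                "n_replicates": int(len(fold_reps)),
            }
        )
    return pd.DataFrame(rows)


def significance(ct: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Two-sample equal-variance Student's t-test of replicate ΔCT values at
    each condition against the baseline replicates of the same gene; stars
    follow the usual convention (* p<0.05, ** p<0.01)."""
    df = ct.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    rows = []
    for gene, gdf in df.groupby("gene", sort=True):
        base = gdf[gdf["condition"] == baseline]["dct"].to_numpy()
        if len(base) < 2:
            raise ValidationError(f"gene {gene}: baseline needs >= 2 replicates")
        for condition, cdf in gdf.groupby("condition", sort=True):
            if condition == baseline:
                continue
            treat = cdf["dct"].to_numpy()
            if len(treat) < 2:
                raise ValidationError(
                    f"gene {gene} condition {condition}: need >= 2 replicates"
                )
            if np.ptp(treat) == 0 and np.ptp(base) == 0:
                p = 1.0 if treat[0] == base[0] else 0.0
            else:
                p = float(ttest_ind(treat, base, equal_var=True).pvalue)
            stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
            rows.append({"gene": gene, "condition": condition, "p_value": p, "stars": stars})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldChangeResult:
    """Joined fold-change and significance table for one qPCR experiment."""

    table: pd.DataFrame

    @classmethod
    def from_ct(cls, ct: pd.DataFrame, baseline: str) -> "FoldChangeResult":
        fc = ddct_fold_change(ct, baseline)
        sig = significance(ct, baseline)
        merged = fc.merge(sig, on=["gene", "condition"], how="left")
        merged["stars"] = merged["stars"].fillna("")
        return cls(table=merged)
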