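"""Ethanol-responsive gene detection.

Differential expression is called within each strain separately: a
one-way ANOVA (pretreatment as the factor) on the 2-3 saline vs 2-3
ethanol libraries of that strain, BH-corrected across genes within the
strain at FDR < 0.05.  A strain-by-pretreatment two-way ANOVA across the
whole panel is also available (it flags GxE structure but is not used
for DE calls).  Fold changes are ratios of size-factor-normalized count
means (ethanol / saline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import bh_fdr

__all__ = [
    "per_strain_de",
    "all_strain_de",
    "two_way_anova",
    "de_summary",
    "SetPartition",
    "set_partition",
    "pct",
]


def pct(k: float, n: float) -> int:
    """Percentage rounded half-up to the nearest integer (as reported)."""
    if n == 0:
        raise ValueError("percentage of an empty set")
    return int(np.floor(100.0 * k / n + 0.5))


def per_strain_de(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    strain: str,
    norm_counts: pd.DataFrame | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame | None:
    """One-way pretreatment ANOVA for every gene within one strain.

    Returns None when the strain has fewer than 2 libraries in either
    pretreatment (such strains are excluded from DE, as in the study
    design).  With two groups the ANOVA F equals the pooled-variance
    t-statistic squared; p-values come from F(1, n-2).  Genes with zero
    residual variance but unequal means are flagged degenerate (p NaN);
    genes constant across all libraries get F = 0, p = 1.
    """
    sub = meta[meta["strain"] == strain]
    sal = sub.index[sub["pretreatment"] == "sal"]
    et = sub.index[sub["pretreatment"] == "Et"]
    if len(sal) < 2 or len(et) < 2:
        return None
    a = expr.loc[sal].to_numpy(dtype=float)
    b = expr.loc[et].to_numpy(dtype=float)
    n1, n2 = len(sal), len(et)
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    ss = ((a - m1) ** 2).sum(axis=0) + ((b - m2) ** 2).sum(axis=0)
    df2 = n1 + n2 - 2
    sp2 = ss / df2
    num = (m1 - m2) ** 2 / (1.0 / n1 + 1.0 / n2)

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = num / sp2
    p = stats.f.sf(f_stat, 1, df2)
    degenerate = (sp2 == 0) & (num > 0)
    flat = (sp2 == 0) & (num == 0)
    f_stat = np.where(flat, 0.0, f_stat)
    p = np.where(flat, 1.0, p)
    f_stat = np.where(degenerate, np.nan, f_stat)
    p = np.where(degenerate, np.nan, p)

    out = pd.DataFrame({
        "gene_id": expr.columns,
        "strain": strain,
        "F": f_stat,
        "p": p,
        "degenerate": degenerate,
    })
    out["q"], out["significant"] = bh_fdr(out["p"].to_numpy(), alpha=fdr_alpha)

    if norm_counts is not None:
        c_sal = norm_counts.loc[sal].mean(axis=0).to_numpy()
        c_et = norm_counts.loc[et].mean(axis=0).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(c_sal > 0, c_et / c_sal, np.inf)
        out["fold_change"] = fc
        out["direction"] = np.where(c_et > c_sal, "up", "down")
    return out


def all_strain_de(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    norm_counts: pd.DataFrame | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-strain DE for every eligible strain, concatenated."""
    frames = []
    for strain in meta["strain"].unique():
        res = per_strain_de(expr, meta, strain, norm_counts, fdr_alpha)
        if res is not None:
            frames.append(res)
    if not frames:
        raise ValueError("no strain has >= 2 libraries in both pretreatments")
    return pd.concat(frames, ignore_index=True)


def _rss(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (n x G) on design X, per column."""
    q, _ = np.linalg.qr(x)
    resid = y - q @ (q.T @ y)
    return (resid**2).sum(axis=0)


def two_way_anova(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Strain-by-pretreatment two-way ANOVA per gene.

    Sequential (strain, pretreatment, interaction) sums of squares via
    nested OLS fits sharing one design across genes; F denominators use
    the full-model residual.  Strains lacking either pretreatment are
    dropped with a report column left to the caller's logs.
    """
    keep_strains = [
        s for s, sub in meta.groupby("strain")
        if set(sub["pretreatment"]) >= {"sal", "Et"}
    ]
    if len(keep_strains) < 2:
        raise ValueError("need >= 2 strains observed in both pretreatments")
    sub = meta[meta["strain"].isin(keep_strains)]
    y = expr.loc[sub.index].to_numpy(dtype=float)
    n = len(sub)

    strain_d = pd.get_dummies(sub["strain"]).to_numpy(dtype=float)
    pre_d = (sub["pretreatment"] == "Et").to_numpy(dtype=float)[:, None]
    cell_d = pd.get_dummies(
        sub["strain"].astype(str) + ":" + sub["pretreatment"].astype(str)
    ).to_numpy(dtype=float)

    x0 = np.ones((n, 1))
    x1 = strain_d
    x2 = np.hstack([strain_d, pre_d])
    x3 = cell_d
    rss0, rss1, rss2, rss3 = (_rss(y, x) for x in (x0, x1, x2, x3))

    k = len(keep_strains)
    df_strain, df_pre, df_int = k - 1, 1, k - 1
    df_res = n - 2 * k
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (need replicates)")
    mse = rss3 / df_res
    with np.errstate(divide="ignore", invalid="ignore"):
        f_strain = ((rss0 - rss1) / df_strain) / mse
        f_pre = ((rss1 - rss2) / df_pre) / mse
        f_int = ((rss2 - rss3) / df_int) / mse
    return pd.DataFrame({
        "gene_id": expr.columns,
        "F_strain": f_strain,
        "p_strain": stats.f.sf(f_strain, df_strain, df_res),
        "F_pretreatment": f_pre,
        "p_pretreatment": stats.f.sf(f_pre, df_pre, df_res),
        "F_interaction": f_int,
        "p_interaction": stats.f.sf(f_int, df_int, df_res),
        "SS_strain": rss0 - rss1,
        "SS_pretreatment": rss1 - rss2,
        "SS_interaction": rss2 - rss3,
        "SS_residual": rss3,
        "SS_total": rss0,
    })


def de_summary(de: pd.DataFrame) -> dict:
    """Accounting of per-strain DE calls.

    Returns per-strain significant counts, per-gene number of significant
    strains, gene-level direction (up / down / mixed across strains), and
    the fold-change range among significant calls.
    """
    sig = de[de["significant"]]
    per_strain = (
        de.groupby("strain")["significant"].sum().astype(int).sort_index()
    )
    per_gene = sig.groupby("gene_id").size() if len(sig) else pd.Series(dtype=int)
    n_genes = int(per_gene.size)

    directions = {}
    if "direction" in de.columns and len(sig):
        for gene, sub in sig.groupby("gene_id"):
            dirs = set(sub["direction"])
            directions[gene] = dirs.pop() if len(dirs) == 1 else "mixed"
    n_up = sum(1 for d in directions.values() if d == "up")
    n_down = sum(1 for d in directions.values() if d == "down")
    n_mixed = sum(1 for d in directions.values() if d == "mixed")

    summary = {
        "per_strain_counts": per_strain,
        "per_gene_strain_counts": per_gene,
        "n_de_genes": n_genes,
        "n_single_strain": int((per_gene == 1).sum()),
        "n_multi_strain": int((per_gene > 1).sum()),
        "n_up": n_up,
        "n_down": n_down,
        "n_mixed": n_mixed,
    }
    if n_genes:
        summary["pct_single_strain"] = pct(summary["n_single_strain"], n_genes)
        summary["pct_up"] = pct(n_up, n_genes)
        summary["pct_down"] = pct(n_down, n_genes)
    if "fold_change" in de.columns and len(sig):
        fc = sig["fold_change"].to_numpy()
        fc = fc[np.isfinite(fc) & (fc > 0)]  # zero/inf ratios have no range
        up = fc[fc >= 1.0]
        down = fc[fc < 1.0]
        summary["fold_change_up_range"] = (
            (float(up.min()), float(up.max())) if len(up) else None
        )
        summary["fold_change_down_range"] = (
            (float(1.0 / down.max()), float(1.0 / down.min())) if len(down) else None
        )
    return summary


@dataclass
class SetPartition:
    """Two-set accounting: sizes, union, exclusive and shared counts."""

    n_a: int
    n_b: int
    n_union: int
    n_a_only: int
    n_b_only: int
    n_both: int


def set_partition(n_a: int, n_b: int, n_union: int) -> SetPartition:
    """Exclusive/shared counts from two set sizes and their union size."""
    if not (max(n_a, n_b) <= n_union <= n_a + n_b):
        raise ValueError(
            f"impossible set sizes: |A|={n_a}, |B|={n_b}, |A∪B|={n_union}"
        )
    return SetPartition(
        n_a=n_a, n_b=n_b, n_union=n_union,
        n_a_only=n_union - n_b, n_b_only=n_union - n_a,
        n_both=n_a + n_b - n_union,
    )
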