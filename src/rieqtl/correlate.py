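"""Genetic correlations on strain means and candidate-gene intersection.

Because RI strain means are replicable genetic units, a Pearson
correlation between two strain-mean traits estimates the extent of
shared genetic variance.  Expression-to-behavior correlations are
BH-corrected across genes within one behavior x pretreatment family
(FDR < 0.10); hub-gene analyses use nominal p < 0.01 with a
linkage-disequilibrium proximity annotation (> 20 Mb or a different
chromosome counts as distal).  Candidate genes are the intersection of
significant cis-eQTLs with behavior-correlated genes, optionally flagged
when they fall inside a supplied behavioral QTL interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import bh_fdr

__all__ = [
    "pearson_with_p",
    "corr_to_behavior",
    "hub_correlates",
    "behavior_vs_de_count",
    "candidate_genes",
]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return r, float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _column_correlations(
    mat: pd.DataFrame, y: pd.Series
) -> pd.DataFrame:
    """Vectorized Pearson r/p of every column of ``mat`` against ``y``.

    Rows are aligned on the index; strains missing the target value are
    pairwise-dropped.  Constant columns (or a constant target) get NaN
    with a flag.
    """
    common = mat.index.intersection(y.dropna().index)
    if len(common) < 3:
        raise ValueError("fewer than 3 strains shared between tables")
    x = mat.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    n = len(common)
    xc = x - x.mean(axis=0)
    yc = yv - yv.mean()
    ssx = (xc**2).sum(axis=0)
    ssy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / np.sqrt(ssx * ssy)
    undefined = (ssx == 0) | (ssy == 0)
    r = np.where(undefined, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(undefined, np.nan, p)
    return pd.DataFrame(
        {"r": r, "n": n, "p": p, "undefined": undefined},
        index=mat.columns,
    )


def corr_to_behavior(
    means: pd.DataFrame,
    behavior: pd.Series,
    group: str,
    trait: str,
    fdr_alpha: float = 0.10,
) -> pd.DataFrame:
    """Gene-expression vs behavior correlations with BH FDR across genes."""
    out = _column_correlations(means, behavior)
    out.insert(0, "trait", trait)
    out.insert(1, "group", group)
    out["q"], out["significant"] = bh_fdr(out["p"].to_numpy(), alpha=fdr_alpha)
    out.index.name = "gene_id"
    return out


def hub_correlates(
    hub_gene: str,
    means: pd.DataFrame,
    annotation: pd.DataFrame,
    p_cut: float = 0.01,
    ld_mb: float = 20.0,
    behavior: pd.Series | None = None,
) -> pd.DataFrame:
    """Genes correlated to a hub gene at nominal p < p_cut.

    Each correlate is annotated ``distal`` when it lies on a different
    chromosome than the hub or more than ``ld_mb`` Mb away on the same
    chromosome (LD unlikely); optionally its correlation to a behavior
    is attached.  The hub itself is returned (r = 1, proximal).
    """
    if hub_gene not in means.columns:
        raise ValueError(f"hub gene {hub_gene!r} absent from expression matrix")
    hub = means[hub_gene]
    if hub.std() == 0:
        raise ValueError("hub gene expression is constant")
    out = _column_correlations(means, hub)
    out = out[(out["p"] < p_cut) & ~out["undefined"]].copy()

    hub_chrom = str(annotation.loc[hub_gene, "chrom"])
    hub_mb = float(annotation.loc[hub_gene, "start_mb"])
    ann = annotation.reindex(out.index)
    same = ann["chrom"].astype(str) == hub_chrom
    dist = (ann["start_mb"] - hub_mb).abs()
    out["distal"] = ~same | (dist > ld_mb)
    out["distance_mb"] = np.where(same, dist, np.inf)
    if behavior is not None:
        beh = _column_correlations(means[out.index], behavior)
        out["r_behavior"] = beh["r"]
        out["p_behavior"] = beh["p"]
    out.index.name = "gene_id"
    return out


def behavior_vs_de_count(
    de_counts: pd.Series, behavior: pd.Series
) -> tuple[float, float]:
    """Correlation of a behavior with the per-strain number of DE genes.

    Returns (r, p); (nan, nan) when either vector is constant.
    """
    common = de_counts.index.intersection(behavior.dropna().index)
    if len(common) < 3:
        raise ValueError("fewer than 3 strains with both values")
    return pearson_with_p(
        de_counts.loc[common].to_numpy(dtype=float),
        behavior.loc[common].to_numpy(dtype=float),
    )


def candidate_genes(
    eqtl_calls: pd.DataFrame,
    corr_results: pd.DataFrame,
    annotation: pd.DataFrame,
    behavior_qtls: list[tuple[str, float, float]] | None = None,
    corr_alpha: float = 0.10,
) -> pd.DataFrame:
    """Genes with a significant cis-eQTL AND a behavior correlation.

    ``eqtl_calls`` and ``corr_results`` must come from the same
    pretreatment group; the golden flag is carried through and
    ``in_behavior_qtl`` is set when the gene start lies inside one of the
    supplied (chrom, lo_mb, hi_mb) intervals.
    """
    cis = eqtl_calls[
        eqtl_calls["significant"] & (eqtl_calls["cis_trans"] == "cis")
    ].set_index("gene_id")
    corr = corr_results[corr_results["q"] < corr_alpha]
    genes = cis.index.intersection(corr.index)
    rows = []
    for gene in genes:
        chrom = str(annotation.loc[gene, "chrom"])
        mb = float(annotation.loc[gene, "start_mb"])
        in_qtl = False
        interval = None
        for (qc, lo, hi) in behavior_qtls or []:
            if chrom == str(qc) and lo <= mb <= hi:
                in_qtl, interval = True, (qc, lo, hi)
                break
        rows.append({
            "gene_id": gene,
            "behavior": corr.loc[gene, "trait"],
            "group": corr.loc[gene, "group"],
            "chrom": chrom,
            "start_mb": mb,
            "r": corr.loc[gene, "r"],
            "q": corr.loc[gene, "q"],
            "peak_lrs": cis.loc[gene, "peak_lrs"],
            "golden": bool(cis.loc[gene, "golden"]),
            "in_behavior_qtl": in_qtl,
            "qtl_interval": interval,
        })
    return pd.DataFrame(rows)
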