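"""Expression filtering and normalization.

Above-background filtering uses RPLG (reads per length of gene):
RPLG = reads * read_length / gene_length, so RPLG = 1 is ~1X coverage at
100 bp reads.  A gene is retained when its median RPLG exceeds 1
(strictly) in the saline or the ethanol library group.  Counts are then
normalized by median-of-ratios size factors and variance-stabilized with
a shifted log2, and all genetic analyses downstream run on per-strain
means within each pretreatment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .sim import CountsMatrix

__all__ = [
    "compute_rplg",
    "filter_expressed",
    "size_factors",
    "vst_transform",
    "strain_means",
]


def compute_rplg(
    counts: CountsMatrix,
    gene_lengths: pd.Series,
    read_length: float = 100.0,
) -> pd.DataFrame:
    """Reads-per-length-of-gene table (libraries x genes).

    Genes with non-positive length are rejected (reported via warning and
    absent from the output).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    lengths = gene_lengths.reindex(counts.counts.columns)
    bad = lengths.index[lengths.isna() | (lengths <= 0)]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} genes with missing or non-positive length"
        )
    keep = lengths.index[lengths > 0]
    return counts.counts[keep] * read_length / lengths[keep]


def filter_expressed(
    rplg: pd.DataFrame,
    meta: pd.DataFrame,
    cutoff: float = 1.0,
) -> pd.DataFrame:
    """Median-RPLG filter: keep genes with median > cutoff in either group.

    Returns a frame indexed by gene with ``median_sal``, ``median_Et`` and
    ``kept`` (strict inequality: a median exactly at the cutoff drops the
    gene unless the other group rescues it).
    """
    groups = {}
    for grp in ("sal", "Et"):
        libs = meta.index[meta["pretreatment"] == grp]
        if len(libs) == 0:
            raise ValueError(f"no libraries in pretreatment group {grp!r}")
        groups[grp] = rplg.loc[libs].median(axis=0)
    out = pd.DataFrame(
        {"median_sal": groups["sal"], "median_Et": groups["Et"]}
    )
    out["kept"] = (out["median_sal"] > cutoff) | (out["median_Et"] > cutoff)
    out.index.name = "gene_id"
    return out


def size_factors(counts: CountsMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    Reference genes are those with a positive count in every library;
    factor_i = median_g counts[i, g] / geomean_g.  Falls back to
    total-count ratios (with a warning) when no reference gene exists.
    """
    mat = counts.counts.to_numpy(dtype=float)
    ref = (mat > 0).all(axis=0)
    if ref.sum() == 0:
        warnings.warn("no gene is positive in all libraries; "
                      "falling back to total-count size factors")
        totals = mat.sum(axis=1)
        factors = totals / totals.mean()
    else:
        logmat = np.log(mat[:, ref])
        log_geomean = logmat.mean(axis=0)
        factors = np.exp(np.median(logmat - log_geomean[None, :], axis=1))
    return pd.Series(factors, index=counts.counts.index, name="size_factor")


def vst_transform(counts: CountsMatrix, factors: pd.Series) -> pd.DataFrame:
    """Variance-stabilized expression: log2(count / size_factor + 1).

    A shifted log of normalized counts; monotone in counts and flattens
    the negative-binomial mean-variance trend, which is the property the
    linear-model analyses downstream rely on.
    """
    f = factors.reindex(counts.counts.index)
    if (f <= 0).any() or f.isna().any():
        raise ValueError("size factors must be positive for all libraries")
    return np.log2(counts.counts.div(f, axis=0) + 1.0)


def strain_means(
    expr: pd.DataFrame, meta: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per-pretreatment strain-mean expression (strains x genes).

    Strains without any library in a pretreatment are dropped from that
    group's frame (reported via warning).
    """
    out = {}
    all_strains = meta["strain"].unique()
    for grp in ("sal", "Et"):
        sub = meta[meta["pretreatment"] == grp]
        means = expr.loc[sub.index].groupby(sub["strain"]).mean()
        means.index.name = "strain_id"
        dropped = set(all_strains) - set(means.index)
        if dropped:
            warnings.warn(
                f"strains missing from group {grp!r}: {sorted(dropped)}"
            )
        out[grp] = means
    return out
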