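"""Broad-sense heritability of expression in an RI panel.

For each gene and pretreatment group, library-level variance-stabilized
values are fit with a one-way random-intercept model (strain random):

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, V_B),  e_ij ~ N(0, V_W)

by REML (profile likelihood over the variance ratio V_B/V_W with the
non-negativity constraint), giving H^2 = V_B / (V_B + V_W).  The null of
no heritability sits on the boundary of the parameter space, so the LRT
null distribution is the 50:50 mixture of a point mass at zero and a
chi-square with one degree of freedom.

Because strains here are replicate genetic units, no kinship matrix is
involved; RNA pooling within strains deflates V_W and hence inflates H^2
relative to mouse-level heritability — deliberately not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = ["HeritabilityResult", "fit_h2", "lrt_h2", "bh_fdr", "h2_table"]

_LAMBDA_MAX = 1e8


@dataclass
class HeritabilityResult:
    v_b: float
    v_w: float
    h2: float
    lrt_stat: float
    p_value: float
    loglik_full: float
    loglik_null: float
    flag: str = ""
    gene: str | None = None
    group: str | None = None


def _group_stats(values: np.ndarray, strains: np.ndarray):
    labels, inverse = np.unique(strains, return_inverse=True)
    n_i = np.bincount(inverse).astype(float)
    sums = np.bincount(inverse, weights=values)
    ybar = sums / n_i
    ss_w = float(np.sum((values - ybar[inverse]) ** 2))
    return labels, n_i, ybar, ss_w


def _profile_reml(lam: float, n_i: np.ndarray, ybar: np.ndarray, ss_w: float):
    """Profile REML log-likelihood at variance ratio lam = V_B / V_W."""
    n_total = n_i.sum()
    w = n_i / (1.0 + n_i * lam)
    mu = float(np.sum(w * ybar) / np.sum(w))
    q = ss_w + float(np.sum(w * (ybar - mu) ** 2))
    v_w = q / (n_total - 1.0)
    ll = -0.5 * (
        (n_total - 1.0) * (np.log(2.0 * np.pi * v_w) + 1.0)
        + float(np.sum(np.log1p(n_i * lam)))
        + np.log(float(np.sum(w)))
    )
    return ll, v_w


def fit_h2(values, strains, gene: str | None = None, group: str | None = None) -> HeritabilityResult:
    """REML fit of the one-way random-effects model for a single gene.

    Requires >= 2 strains and at least one strain with >= 2 libraries.
    """
    values = np.asarray(values, dtype=float)
    strains = np.asarray(strains)
    if values.shape != strains.shape:
        raise ValueError("values and strain labels differ in length")
    labels, n_i, ybar, ss_w = _group_stats(values, strains)
    if len(labels) < 2:
        raise ValueError("need at least 2 strains")
    if (n_i < 2).all():
        raise ValueError("need at least one strain with >= 2 libraries")

    if np.ptp(values) == 0.0:
        return HeritabilityResult(0.0, 0.0, 0.0, 0.0, 1.0, np.nan, np.nan,
                                  flag="constant", gene=gene, group=group)
    if ss_w == 0.0:
        # strain means distinct but zero within-strain spread: H^2 -> 1
        v_b = float(np.var(ybar, ddof=1))
        return HeritabilityResult(v_b, 0.0, 1.0, np.inf, 0.0, np.inf, np.nan,
                                  flag="zero_within", gene=gene, group=group)

    ll0, vw0 = _profile_reml(0.0, n_i, ybar, ss_w)
    grid = np.concatenate([[0.0], np.exp(np.linspace(np.log(1e-6), np.log(_LAMBDA_MAX), 80))])
    lls = np.array([_profile_reml(l, n_i, ybar, ss_w)[0] for l in grid])
    k = int(np.argmax(lls))
    lam_hat, ll_hat = grid[k], lls[k]
    if 0 < k < len(grid) - 1:
        res = optimize.minimize_scalar(
            lambda l: -_profile_reml(l, n_i, ybar, ss_w)[0],
            bounds=(grid[k - 1], grid[k + 1]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun > ll_hat:
            lam_hat, ll_hat = float(res.x), float(-res.fun)
    _, v_w = _profile_reml(lam_hat, n_i, ybar, ss_w)
    v_b = lam_hat * v_w
    h2 = lam_hat / (1.0 + lam_hat)
    stat = max(0.0, 2.0 * (ll_hat - ll0))
    return HeritabilityResult(
        v_b=float(v_b), v_w=float(v_w), h2=float(h2),
        lrt_stat=float(stat), p_value=lrt_h2(stat),
        loglik_full=float(ll_hat), loglik_null=float(ll0),
        gene=gene, group=group,
    )


def lrt_h2(lrt_stat: float) -> float:
    """Boundary-corrected LRT p-value: 0.5 chi2_0 + 0.5 chi2_1 mixture."""
    if np.isnan(lrt_stat):
        return np.nan
    if lrt_stat <= 0.0:
        return 1.0
    return float(0.5 * stats.chi2.sf(lrt_stat, df=1))


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up q-values and rejection flags.

    NaN p-values propagate to NaN q-values and are never rejected; the BH
    family is the non-missing entries.  Rejection is q < alpha.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.sum():
        _, q_ok, _, _ = multipletests(p[ok], method="fdr_bh")
        q[ok] = q_ok
        reject[ok] = q_ok < alpha
    return q, reject


def h2_table(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene, per-group heritability with BH FDR within each group."""
    frames = []
    for grp in ("sal", "Et"):
        sub = meta[meta["pretreatment"] == grp]
        strains = sub["strain"].to_numpy()
        block = expr.loc[sub.index]
        rows = []
        for gene in block.columns:
            fit = fit_h2(block[gene].to_numpy(), strains, gene=gene, group=grp)
            rows.append((gene, grp, fit.v_b, fit.v_w, fit.h2,
                         fit.lrt_stat, fit.p_value, fit.flag))
        df = pd.DataFrame(rows, columns=[
            "gene_id", "group", "V_B", "V_W", "H2", "lrt_stat", "p", "flag"])
        df["q"], df["significant"] = bh_fdr(df["p"].to_numpy(), alpha=fdr_alpha)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
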