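"""Haley-Knott eQTL mapping on strain means.

For each gene and pretreatment group the per-strain mean expression is
regressed on expected genotype dosage at every evaluation position
(markers plus optional pseudomarkers); association is summarized as the
likelihood ratio statistic

    LRS = n * ln(RSS0 / RSS1)       (LOD = LRS / (2 ln 10))

where RSS0/RSS1 are the intercept-only and single-dosage OLS residual
sums of squares.  Genome-wide significance is calibrated per trait by
permuting strain labels and recording the maximum LRS of each rescan
(thresholds at genome-wide p < 0.10 / 0.05 / 0.001).

Peaks within 5 Mb of the gene's start on the same chromosome are cis,
all others trans.  "Golden" pretreatment-unique eQTLs additionally
require the other condition's scan to stay below its own suggestive
(p < 0.10) threshold everywhere within 25 Mb of the gene (cis) or of the
peak (trans; the trans peak must itself lie > 25 Mb from the gene or on
a different chromosome).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim import GenotypeMatrix, haldane_r, ri_transition

__all__ = [
    "EqtlScan",
    "EqtlCall",
    "genotype_probs",
    "hk_scan",
    "perm_thresholds",
    "genomewide_p",
    "classify_cis_trans",
    "golden_filter",
    "gene_seed",
    "map_eqtls",
]

#: 1 - r^2 below this is treated as a perfect fit; the LRS is capped at
#: n * ln(1 / _RSS_EPS) and flagged.
_RSS_EPS = 1e-12

THRESHOLD_PS = (0.10, 0.05, 0.001)


@dataclass
class EqtlScan:
    """Genome-scan profile for one trait (gene x group or a behavior)."""

    positions: pd.DataFrame  # chrom, pos_mb, pos_cm, is_marker
    lrs: np.ndarray
    n: int
    thresholds: dict[float, float] = field(default_factory=dict)
    capped: bool = False
    gene: str | None = None
    group: str | None = None

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.lrs))

    @property
    def peak(self) -> tuple[str, float, float]:
        i = self.peak_index
        row = self.positions.iloc[i]
        return str(row["chrom"]), float(row["pos_mb"]), float(self.lrs[i])

    @property
    def lod(self) -> np.ndarray:
        return self.lrs / (2.0 * np.log(10.0))


@dataclass
class EqtlCall:
    gene: str
    group: str
    peak_chrom: str
    peak_mb: float
    peak_lrs: float
    p_genomewide: float
    significant: bool
    cis_trans: str
    golden: bool
    distance_mb: float  # inf when gene and peak on different chromosomes


def genotype_probs(
    genos: GenotypeMatrix, step_cm: float | None = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Evaluation grid and expected dosages for a Haley-Knott scan.

    At markers the dosage is the observed allele.  Pseudomarkers are laid
    every ``step_cm`` between adjacent markers (``step_cm=None`` gives a
    marker-only grid); their dosage is the conditional expectation of the
    allele given the two flanking genotypes under the RI Markov chain,
    with per-flank transition probabilities R = 4r/(1+6r).
    """
    if step_cm is not None and step_cm <= 0:
        raise ValueError("step_cm must be positive (or None for markers only)")
    mmap = genos.marker_map
    alleles = genos.alleles.astype(float)
    pos_rows: list[tuple[str, float, float, bool]] = []
    dosage_cols: list[np.ndarray] = []
    for chrom, sub in mmap.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        mb = sub["pos_mb"].to_numpy()
        cm = sub["pos_cm"].to_numpy()
        for k in range(len(idx)):
            pos_rows.append((chrom, mb[k], cm[k], True))
            dosage_cols.append(alleles[:, idx[k]])
            if step_cm is None or k == len(idx) - 1:
                continue
            gap = cm[k + 1] - cm[k]
            n_pseudo = int(np.floor((gap - 1e-9) / step_cm))
            g_l = alleles[:, idx[k]]
            g_r = alleles[:, idx[k + 1]]
            for j in range(1, n_pseudo + 1):
                d_l = j * step_cm
                d_r = gap - d_l
                r_l = ri_transition(haldane_r(d_l))
                r_r = ri_transition(haldane_r(d_r))
                t1_l = np.where(g_l == 1, 1.0 - r_l, r_l)
                t1_r = np.where(g_r == 1, 1.0 - r_r, r_r)
                t0_l = np.where(g_l == 0, 1.0 - r_l, r_l)
                t0_r = np.where(g_r == 0, 1.0 - r_r, r_r)
                num1 = t1_l * t1_r
                dosage = num1 / (num1 + t0_l * t0_r)
                frac = d_l / gap
                pos_rows.append(
                    (chrom, mb[k] + frac * (mb[k + 1] - mb[k]), cm[k] + d_l, False)
                )
                dosage_cols.append(dosage)
    positions = pd.DataFrame(
        pos_rows, columns=["chrom", "pos_mb", "pos_cm", "is_marker"]
    )
    return positions, np.column_stack(dosage_cols)


def _scan_r2(trait: np.ndarray, dosages: np.ndarray) -> np.ndarray:
    """Squared correlation of the trait with every dosage column."""
    y = trait - trait.mean()
    ssy = float(y @ y)
    d = dosages - dosages.mean(axis=0)
    ssd = (d**2).sum(axis=0)
    if ssy == 0.0:
        return np.zeros(dosages.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (d.T @ y) ** 2 / (ssd * ssy)
    return np.where(ssd > 0, r2, 0.0)


def hk_scan(
    trait: np.ndarray,
    dosages: np.ndarray,
    positions: pd.DataFrame,
    gene: str | None = None,
    group: str | None = None,
) -> EqtlScan:
    """Haley-Knott regression scan; LRS = -n ln(1 - r^2) per position.

    Constant dosage columns score 0; a constant trait scores 0 everywhere;
    near-perfect fits are capped (flagged) rather than infinite.
    """
    trait = np.asarray(trait, dtype=float)
    n = len(trait)
    if n < 3:
        raise ValueError("need at least 3 strains")
    if dosages.shape[0] != n:
        raise ValueError("trait and dosage strain dimensions differ")
    r2 = _scan_r2(trait, dosages)
    one_minus = 1.0 - r2
    capped = bool((one_minus < _RSS_EPS).any())
    lrs = -n * np.log(np.maximum(one_minus, _RSS_EPS))
    return EqtlScan(positions=positions, lrs=lrs, n=n,
                    capped=capped, gene=gene, group=group)


def perm_thresholds(
    trait: np.ndarray,
    dosages: np.ndarray,
    n_perm: int = 1000,
    quantiles: dict[float, float] | None = None,
    seed: int = 0,
) -> tuple[dict[float, float], np.ndarray]:
    """Churchill-Doerge permutation thresholds for one trait.

    Shuffles trait values across strains ``n_perm`` times, records each
    rescan's genome-wide maximum LRS, and returns empirical quantiles
    (linear/type-7 interpolation) keyed by genome-wide p, plus the raw
    maxima for p-value computation.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if quantiles is None:
        quantiles = {p: 1.0 - p for p in THRESHOLD_PS}
    trait = np.asarray(trait, dtype=float)
    n = len(trait)
    rng = np.random.default_rng(seed)

    y = trait - trait.mean()
    ssy = float(y @ y)
    if ssy == 0.0:
        return {p: 0.0 for p in quantiles}, np.zeros(n_perm)
    d = dosages - dosages.mean(axis=0)
    ssd = (d**2).sum(axis=0)
    keep = ssd > 0
    dn = d[:, keep] / np.sqrt(ssd[keep])[None, :]
    yn = y / np.sqrt(ssy)

    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = yn[rng.permutation(n)]
    r = dn.T @ perms  # positions x perms
    max_r2 = (r**2).max(axis=0)
    perm_max = -n * np.log(np.maximum(1.0 - max_r2, _RSS_EPS))
    thresholds = {
        p: float(np.quantile(perm_max, q)) for p, q in quantiles.items()
    }
    return thresholds, perm_max


def genomewide_p(peak_lrs: float, perm_max: np.ndarray) -> float:
    """Permutation genome-wide p-value: (1 + #{max >= peak}) / (1 + N)."""
    return float((1 + np.sum(perm_max >= peak_lrs)) / (1 + len(perm_max)))


def classify_cis_trans(
    peak_chrom: str,
    peak_mb: float,
    gene_chrom: str,
    gene_start_mb: float,
    cis_mb: float = 5.0,
) -> tuple[str, float]:
    """cis iff same chromosome and |peak - gene start| <= cis_mb (inclusive).

    Returns the class and the peak-to-gene distance (inf across
    chromosomes).
    """
    if peak_chrom != gene_chrom:
        return "trans", np.inf
    dist = abs(peak_mb - gene_start_mb)
    return ("cis" if dist <= cis_mb else "trans"), dist


def golden_filter(
    cis_trans: str,
    peak_chrom: str,
    peak_mb: float,
    gene_chrom: str,
    gene_start_mb: float,
    other_scan: EqtlScan,
    own_positions: pd.DataFrame | None = None,
    window_mb: float = 25.0,
) -> bool:
    """Pretreatment-unique ("golden") eQTL rule.

    cis: golden iff the other condition's scan has no position within
    ``window_mb`` of the gene (same chromosome) reaching that scan's own
    suggestive (p < 0.10) threshold.  trans: the gene and peak must be on
    different chromosomes or > ``window_mb`` apart, and the other scan
    must stay below its suggestive threshold within ``window_mb`` of the
    peak (on the peak's chromosome).  Exceedance is evaluated
    position-wise (no local-maximum detection).
    """
    if own_positions is not None and not own_positions[["chrom", "pos_mb"]].equals(
        other_scan.positions[["chrom", "pos_mb"]]
    ):
        raise ValueError("scan position grids differ between conditions")
    t_sugg = other_scan.thresholds.get(0.10)
    if t_sugg is None:
        raise ValueError("other scan lacks the p<0.10 suggestive threshold")
    pos = other_scan.positions
    if cis_trans == "cis":
        window = (pos["chrom"] == gene_chrom) & (
            (pos["pos_mb"] - gene_start_mb).abs() <= window_mb
        )
    else:
        same = peak_chrom == gene_chrom
        if same and abs(peak_mb - gene_start_mb) <= window_mb:
            return False  # ineligible: trans peak too close to its gene
        window = (pos["chrom"] == peak_chrom) & (
            (pos["pos_mb"] - peak_mb).abs() <= window_mb
        )
    return not bool((other_scan.lrs[window.to_numpy()] >= t_sugg).any())


def gene_seed(base_seed: int, gene: str, group: str) -> int:
    """Deterministic per-(gene, group) permutation seed below 2^31."""
    h = zlib.crc32(f"{gene}|{group}".encode())
    return int((base_seed * 1000003 + h) % (2**31 - 1))


def map_eqtls(
    means: dict[str, pd.DataFrame],
    genos: GenotypeMatrix,
    annotation: pd.DataFrame,
    n_perm: int = 1000,
    step_cm: float | None = 1.0,
    seed: int = 0,
    alpha: float = 0.05,
    cis_mb: float = 5.0,
    golden_mb: float = 25.0,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Scan every gene in both pretreatment groups and classify peaks.

    ``means`` maps group -> strains x genes strain-mean expression;
    unannotated genes are skipped with a report column in the result.
    Permutation seeds derive deterministically from (seed, gene, group).
    Returns one row per gene x group with peak location, LRS, genome-wide
    p, thresholds, cis/trans class and the golden flag (golden is only
    defined for significant calls that are *unique*, i.e. not significant
    in the other condition).
    """
    positions, dosages = genotype_probs(genos, step_cm=step_cm)
    strain_order = {grp: list(df.index) for grp, df in means.items()}
    dosage_by_group = {}
    for grp, order in strain_order.items():
        sidx = [genos.strain_ids.index(s) for s in order]
        dosage_by_group[grp] = dosages[sidx, :]

    if genes is None:
        genes = [g for g in means["sal"].columns if g in means["Et"].columns]
    rows = []
    for gene in genes:
        if gene not in annotation.index:
            continue
        gene_chrom = str(annotation.loc[gene, "chrom"])
        gene_mb = float(annotation.loc[gene, "start_mb"])
        scans: dict[str, EqtlScan] = {}
        stats: dict[str, dict] = {}
        for grp in ("sal", "Et"):
            trait = means[grp][gene].to_numpy(dtype=float)
            scan = hk_scan(trait, dosage_by_group[grp], positions, gene, grp)
            thr, perm_max = perm_thresholds(
                trait, dosage_by_group[grp], n_perm=n_perm,
                seed=gene_seed(seed, gene, grp),
            )
            scan.thresholds = thr
            peak_chrom, peak_mb, peak_lrs = scan.peak
            scans[grp] = scan
            stats[grp] = {
                "peak_chrom": peak_chrom, "peak_mb": peak_mb,
                "peak_lrs": peak_lrs,
                "p_gw": genomewide_p(peak_lrs, perm_max),
                "significant": peak_lrs >= thr[alpha],
            }
        for grp in ("sal", "Et"):
            other = "Et" if grp == "sal" else "sal"
            st = stats[grp]
            cls, dist = classify_cis_trans(
                st["peak_chrom"], st["peak_mb"], gene_chrom, gene_mb, cis_mb
            )
            golden = False
            if st["significant"] and not stats[other]["significant"]:
                golden = golden_filter(
                    cls, st["peak_chrom"], st["peak_mb"], gene_chrom, gene_mb,
                    scans[other], own_positions=scans[grp].positions,
                    window_mb=golden_mb,
                )
            rows.append({
                "gene_id": gene, "group": grp,
                "gene_chrom": gene_chrom, "gene_start_mb": gene_mb,
                "peak_chrom": st["peak_chrom"], "peak_mb": st["peak_mb"],
                "peak_lrs": st["peak_lrs"], "p_genomewide": st["p_gw"],
                "T_0.10": scans[grp].thresholds[0.10],
                "T_0.05": scans[grp].thresholds[0.05],
                "T_0.001": scans[grp].thresholds[0.001],
                "significant": st["significant"],
                "cis_trans": cls, "distance_mb": dist, "golden": golden,
            })
    return pd.DataFrame(rows)
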