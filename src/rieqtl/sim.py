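"""Synthetic recombinant-inbred (RI) panel generator.

Emulates the statistical structure of a two-progenitor RI mouse panel
profiled by pooled RNA-seq under two pretreatments (saline / ethanol):

* genotypes are fixed mosaics of the two progenitor genomes, simulated as
  a Markov chain along each chromosome with the sib-mating map-expansion
  transition probability R = 4r/(1+6r);
* expression counts carry planted cis/trans eQTL effects, polygenic
  strain effects calibrated to a target broad-sense heritability,
  strain-specific ethanol (GxE) shifts, RNA pooling across mice, and
  negative-binomial counting noise;
* behaviors (sleep time and acute functional tolerance under each
  pretreatment) are linear in marker alleles and in the realized genetic
  values of chosen genes, so their genetic correlations to expression are
  known by construction.

Every stochastic routine takes an explicit integer seed; the emitted
:class:`SimTruth` records the planted architecture for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MOUSE_AUTOSOME_MB",
    "GenotypeMatrix",
    "CountsMatrix",
    "SimTruth",
    "haldane_r",
    "ri_transition",
    "default_marker_map",
    "validate_marker_map",
    "simulate_ri_genotypes",
    "random_truth",
    "simulate_counts",
    "simulate_behaviors",
    "BEHAVIORS",
]

#: Approximate mouse autosome lengths (chr1..chr19), Mb.
MOUSE_AUTOSOME_MB = [
    195.0, 182.0, 160.0, 157.0, 152.0, 150.0, 145.0, 129.0, 125.0, 131.0,
    122.0, 120.0, 120.0, 125.0, 104.0, 98.0, 95.0, 91.0, 61.0,
]

#: Behavior columns: sleep time / acute functional tolerance under
#: saline or ethanol pretreatment.
BEHAVIORS = ["ST_sal", "ST_Et", "AFT_sal", "AFT_Et"]

MARKER_MAP_COLUMNS = ["marker_id", "chrom", "pos_mb", "pos_cm"]


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane recombination fraction for a map distance in cM.

    r = 0.5 * (1 - exp(-2 d)) with d in Morgans; no interference.
    """
    d_morgan = np.asarray(d_cm, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


def ri_transition(r: np.ndarray | float) -> np.ndarray | float:
    """Probability that adjacent loci differ in a sib-mated RI strain.

    Map expansion for autosomes under brother-sister inbreeding:
    R = 4r / (1 + 6r).  R -> 4r as r -> 0 and R -> 1/2 as r -> 1/2.
    """
    r = np.asarray(r, dtype=float)
    return 4.0 * r / (1.0 + 6.0 * r)


def validate_marker_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Check the marker-map schema and per-chromosome monotonicity."""
    missing = [c for c in MARKER_MAP_COLUMNS if c not in marker_map.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    if marker_map["marker_id"].duplicated().any():
        raise ValueError("marker ids are not unique")
    if (marker_map["pos_mb"] < 0).any() or (marker_map["pos_cm"] < 0).any():
        raise ValueError("marker positions must be non-negative")
    for chrom, sub in marker_map.groupby("chrom", sort=False):
        for col in ("pos_mb", "pos_cm"):
            if not np.all(np.diff(sub[col].to_numpy()) > 0):
                raise ValueError(
                    f"marker map not strictly increasing in {col} on {chrom}"
                )
    return marker_map


def default_marker_map(
    n_markers: int = 2661,
    chrom_lengths_mb: list[float] | None = None,
    cm_per_mb: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Random marker map over the mouse autosomes.

    Markers are allocated to chromosomes proportionally to physical length
    and placed uniformly; genetic positions use a genome-average rate of
    ``cm_per_mb`` (default 0.5 cM/Mb for mouse).
    """
    if chrom_lengths_mb is None:
        chrom_lengths_mb = MOUSE_AUTOSOME_MB
    lengths = np.asarray(chrom_lengths_mb, dtype=float)
    rng = np.random.default_rng(seed)
    # proportional allocation, at least 2 markers per chromosome
    alloc = np.maximum(2, np.round(n_markers * lengths / lengths.sum()).astype(int))
    rows = []
    k = 0
    for i, (length, n_c) in enumerate(zip(lengths, alloc)):
        chrom = f"chr{i + 1}"
        pos = np.sort(rng.uniform(1.0, length, size=n_c))
        # break improbable ties to keep the map strictly monotone
        pos += np.arange(n_c) * 1e-9
        for p in pos:
            rows.append((f"m{k:05d}", chrom, float(p), float(p) * cm_per_mb))
            k += 1
    return pd.DataFrame(rows, columns=MARKER_MAP_COLUMNS)


@dataclass
class GenotypeMatrix:
    """Fully inbred biallelic genotypes for an RI panel.

    ``alleles[s, m]`` is 0 (short-sleep-progenitor allele) or 1
    (long-sleep-progenitor allele); no heterozygotes, no missing data.
    The marker map travels with the genotypes because every downstream
    consumer needs both.
    """

    strain_ids: list[str]
    marker_map: pd.DataFrame
    alleles: np.ndarray  # (n_strains, n_markers) int8

    def __post_init__(self) -> None:
        validate_marker_map(self.marker_map)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.strain_ids), len(self.marker_map)):
            raise ValueError("allele matrix shape does not match strains x markers")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("alleles must be coded 0/1")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.alleles,
            index=pd.Index(self.strain_ids, name="strain_id"),
            columns=self.marker_map["marker_id"].to_numpy(),
        )


@dataclass
class CountsMatrix:
    """Raw RNA-seq counts (libraries x genes) with per-library metadata.

    ``meta`` is indexed by library id with columns ``strain``,
    ``pretreatment`` ('sal' or 'Et') and ``replicate``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and metadata library ids differ")
        for col in ("strain", "pretreatment", "replicate"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata missing column {col!r}")
        bad = set(self.meta["pretreatment"]) - {"sal", "Et"}
        if bad:
            raise ValueError(f"unknown pretreatment labels: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class SimTruth:
    """Planted architecture of a simulated panel (for recovery tests).

    ``h2_target`` maps (gene, group) to the intended library-level
    broad-sense heritability; genes/groups absent from it receive no
    polygenic top-up (their between-strain variance is QTL-driven only).
    After :func:`simulate_counts` runs, ``realized`` holds the realized
    per-strain genetic values (strains x genes, one frame per group).
    """

    cis_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    trans_effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    h2_target: dict[tuple[str, str], float] = field(default_factory=dict)
    gxe_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    behavior_loci: dict[str, tuple[str, float]] = field(default_factory=dict)
    behavior_gene_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    realized: dict[str, pd.DataFrame] = field(default_factory=dict)

    def validate(self, marker_ids: set[str], gene_ids: set[str]) -> None:
        for gene, (marker, _) in self.cis_effects.items():
            if gene not in gene_ids or marker not in marker_ids:
                raise ValueError(f"cis effect references unknown gene/marker: {gene}")
        for gene, effects in self.trans_effects.items():
            if gene not in gene_ids:
                raise ValueError(f"trans effect references unknown gene: {gene}")
            for marker, _ in effects:
                if marker not in marker_ids:
                    raise ValueError(f"trans effect references unknown marker: {marker}")
        for (gene, group), h2 in self.h2_target.items():
            if gene not in gene_ids:
                raise ValueError(f"h2 target references unknown gene: {gene}")
            if group not in ("sal", "Et"):
                raise ValueError(f"h2 target references unknown group: {group}")
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"h2 target out of [0,1] for {gene}/{group}")
        for gene in self.gxe_genes:
            if gene not in gene_ids:
                raise ValueError(f"GxE shift references unknown gene: {gene}")
        for behavior, (marker, _) in self.behavior_loci.items():
            if marker not in marker_ids:
                raise ValueError(f"behavior locus references unknown marker: {marker}")
        for behavior, weights in self.behavior_gene_weights.items():
            for gene in weights:
                if gene not in gene_ids:
                    raise ValueError(f"behavior weight references unknown gene: {gene}")

    def to_json(self) -> str:
        payload = {
            "cis_effects": {g: list(v) for g, v in self.cis_effects.items()},
            "trans_effects": {
                g: [list(e) for e in v] for g, v in self.trans_effects.items()
            },
            "h2_target": {f"{g}|{grp}": h for (g, grp), h in self.h2_target.items()},
            "gxe_genes": self.gxe_genes,
            "behavior_loci": {b: list(v) for b, v in self.behavior_loci.items()},
            "behavior_gene_weights": self.behavior_gene_weights,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            cis_effects={g: tuple(v) for g, v in d["cis_effects"].items()},
            trans_effects={
                g: [tuple(e) for e in v] for g, v in d["trans_effects"].items()
            },
            h2_target={
                tuple(k.split("|")): h for k, h in d["h2_target"].items()
            },
            gxe_genes=d["gxe_genes"],
            behavior_loci={b: tuple(v) for b, v in d["behavior_loci"].items()},
            behavior_gene_weights=d["behavior_gene_weights"],
        )


def simulate_ri_genotypes(
    n_strains: int, marker_map: pd.DataFrame, seed: int
) -> GenotypeMatrix:
    """Simulate fully inbred RI genotypes along each chromosome.

    Each strain is an independent two-state Markov chain: the first
    marker allele on a chromosome is Bernoulli(1/2) and adjacent markers
    differ with probability R = 4r/(1+6r), with r the Haldane fraction
    of the cM gap.  This reproduces the ~4-fold map expansion of
    sib-mated RI panels in the tight-linkage limit.
    """
    validate_marker_map(marker_map)
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(seed)
    n_markers = len(marker_map)
    alleles = np.empty((n_strains, n_markers), dtype=np.int8)
    for _, sub in marker_map.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        gaps_cm = np.diff(sub["pos_cm"].to_numpy())
        flip_p = ri_transition(haldane_r(gaps_cm))
        col = rng.integers(0, 2, size=n_strains).astype(np.int8)
        alleles[:, idx[0]] = col
        for j, p in zip(idx[1:], flip_p):
            flips = rng.random(n_strains) < p
            col = np.where(flips, 1 - col, col).astype(np.int8)
            alleles[:, j] = col
    strain_ids = [f"RI{i + 1:03d}" for i in range(n_strains)]
    return GenotypeMatrix(strain_ids, marker_map.reset_index(drop=True), alleles)


def random_truth(
    marker_map: pd.DataFrame,
    gene_ids: list[str],
    strain_ids: list[str],
    seed: int,
    n_cis: int = 40,
    n_trans: int = 20,
    n_gxe: int = 30,
    cis_effect_sd: float = 0.8,
    trans_effect_sd: float = 0.5,
    gxe_shift_sd: float = 0.8,
    gxe_strain_frac: float = 0.15,
    h2_range: tuple[float, float] = (0.0, 0.9),
    behavior_weight: float = 1.5,
) -> SimTruth:
    """Draw a coherent random eQTL/GxE/behavior architecture.

    cis genes get one marker effect (their annotation will be placed near
    that marker); trans genes get a marker drawn independently of gene
    location; GxE genes get log2 ethanol shifts in a random subset of
    strains; each behavior gets one marker locus plus weight on one gene
    of the matching pretreatment group.
    """
    rng = np.random.default_rng(seed)
    markers = marker_map["marker_id"].to_numpy()
    genes = np.asarray(gene_ids)
    truth = SimTruth()

    chosen = rng.choice(len(genes), size=min(n_cis + n_trans, len(genes)), replace=False)
    cis_genes = genes[chosen[:n_cis]]
    trans_genes = genes[chosen[n_cis:]]
    for g in cis_genes:
        m = markers[rng.integers(len(markers))]
        eff = rng.normal(0.0, cis_effect_sd)
        eff = float(np.sign(eff) * max(abs(eff), 0.3))
        truth.cis_effects[str(g)] = (str(m), eff)
    for g in trans_genes:
        m = markers[rng.integers(len(markers))]
        eff = rng.normal(0.0, trans_effect_sd)
        eff = float(np.sign(eff) * max(abs(eff), 0.25))
        truth.trans_effects[str(g)] = [(str(m), eff)]

    # polygenic heritability targets for genes without planted QTLs
    qtl_genes = set(map(str, cis_genes)) | set(map(str, trans_genes))
    for g in genes:
        if str(g) in qtl_genes:
            continue
        for grp in ("sal", "Et"):
            truth.h2_target[(str(g), grp)] = float(rng.uniform(*h2_range))

    gxe_pool = [g for g in genes if str(g) not in qtl_genes]
    for g in rng.choice(gxe_pool, size=min(n_gxe, len(gxe_pool)), replace=False):
        n_hit = max(1, int(round(gxe_strain_frac * len(strain_ids))))
        hit = rng.choice(strain_ids, size=n_hit, replace=False)
        truth.gxe_genes[str(g)] = {
            str(s): float(rng.normal(0.0, gxe_shift_sd)) for s in hit
        }

    # weight each behavior on a cis-regulated gene when one exists, so the
    # candidate-gene intersection (cis eQTL AND behavior correlation) has
    # planted positives
    if len(cis_genes):
        pool = sorted(
            map(str, cis_genes),
            key=lambda g: -abs(truth.cis_effects[g][1]),
        )[: max(4, len(cis_genes) // 4)]
    else:
        pool = list(map(str, genes))
    for behavior in BEHAVIORS:
        m = markers[rng.integers(len(markers))]
        truth.behavior_loci[behavior] = (str(m), float(rng.normal(0.0, 1.0)))
        g = pool[rng.integers(len(pool))]
        truth.behavior_gene_weights[behavior] = {str(g): behavior_weight}
    return truth


def _vst_noise_var(mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Delta-method variance of log2(X+1) for X ~ NB(mu, dispersion)."""
    var = mu + dispersion * mu**2
    return var / ((mu + 1.0) * np.log(2.0)) ** 2


def simulate_counts(
    genos: GenotypeMatrix,
    truth: SimTruth,
    n_genes: int,
    reps_per_cell: int = 3,
    pool_size: int = 3,
    libsize_cv: float = 0.15,
    nb_dispersion: float = 0.02,
    seed: int = 0,
    within_sd: float = 0.5,
    base_log2_mean: float = 6.0,
    base_log2_sd: float = 1.8,
    gene_length_log_mean: float = 7.6,
    gene_length_log_sd: float = 0.6,
) -> tuple[CountsMatrix, pd.DataFrame]:
    """Simulate pooled RNA-seq libraries for every strain x pretreatment.

    Per gene g, strain s, group: the strain genetic value is
    sum(effect * allele) plus, when (g, group) has an ``h2_target``, a
    polygenic deviate whose between-strain variance tops the QTL variance
    up to h2/(1-h2) times the expected within-strain library variance
    (mouse noise / pool_size plus delta-method counting noise).  Each of
    ``reps_per_cell`` libraries averages ``pool_size`` mouse values
    (pooling divides within-strain latent variance by pool_size), ethanol
    libraries add the gene x strain GxE log2 shift, and counts are drawn
    negative-binomial with mean libsize_factor * 2**(baseline + latent).

    Returns the counts matrix and a gene annotation frame (gene, chrom,
    start_mb, length_bp); cis genes are annotated within ±2 Mb of their
    planted marker, all other genes uniformly at random.
    """
    if reps_per_cell not in (2, 3):
        raise ValueError("reps_per_cell must be 2 or 3 (study design)")
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    marker_ids = set(genos.marker_map["marker_id"])
    truth.validate(marker_ids, set(gene_ids))

    mmap = genos.marker_map.set_index("marker_id")
    chrom_len = {
        c: float(sub["pos_mb"].max()) + 3.0
        for c, sub in genos.marker_map.groupby("chrom", sort=False)
    }
    chroms = list(chrom_len)

    # --- gene annotation -------------------------------------------------
    ann_rows = []
    for g in gene_ids:
        length = int(np.round(np.exp(rng.normal(gene_length_log_mean, gene_length_log_sd))))
        length = max(length, 200)
        if g in truth.cis_effects:
            m = truth.cis_effects[g][0]
            chrom = mmap.loc[m, "chrom"]
            pos = float(mmap.loc[m, "pos_mb"]) + rng.uniform(-2.0, 2.0)
            pos = float(np.clip(pos, 0.1, chrom_len[chrom]))
        else:
            chrom = chroms[rng.integers(len(chroms))]
            pos = float(rng.uniform(0.1, chrom_len[chrom]))
        ann_rows.append((g, chrom, pos, length))
    annotation = pd.DataFrame(
        ann_rows, columns=["gene_id", "chrom", "start_mb", "length_bp"]
    ).set_index("gene_id")

    n_strains = genos.n_strains
    strains = genos.strain_ids
    allele_df = genos.to_frame()

    baseline = rng.normal(base_log2_mean, base_log2_sd, size=n_genes)

    # --- strain genetic values per group --------------------------------
    v_w_latent = within_sd**2 / pool_size
    genetic = {grp: np.zeros((n_strains, n_genes)) for grp in ("sal", "Et")}
    for j, g in enumerate(gene_ids):
        q = np.zeros(n_strains)
        effects = []
        if g in truth.cis_effects:
            effects.append(truth.cis_effects[g])
        effects.extend(truth.trans_effects.get(g, []))
        for marker, eff in effects:
            q = q + eff * allele_df[marker].to_numpy(dtype=float)
        var_q = float(np.var(q))
        mu_g = 2.0**baseline[j]
        v_w_lib = v_w_latent + float(_vst_noise_var(np.asarray(mu_g), nb_dispersion))
        # one polygenic deviate per gene, shared between pretreatment
        # groups (scaled per group): genetic architecture is common to
        # both conditions except for explicit GxE shifts
        p = rng.normal(0.0, 1.0, size=n_strains)
        p -= p.mean()
        sd = p.std()
        p = p / sd if sd > 0 else p
        for grp in ("sal", "Et"):
            gvals = q.copy()
            h2 = truth.h2_target.get((g, grp))
            if h2 is not None and h2 > 0.0:
                h2 = min(h2, 0.99)
                v_b_target = h2 / (1.0 - h2) * v_w_lib
                deficit = v_b_target - var_q
                if deficit > 0:
                    gvals = gvals + np.sqrt(deficit) * p
            genetic[grp][:, j] = gvals
    truth.realized = {
        grp: pd.DataFrame(genetic[grp], index=strains, columns=gene_ids)
        for grp in ("sal", "Et")
    }

    # --- libraries -------------------------------------------------------
    lib_rows = []
    latent = []
    for grp in ("sal", "Et"):
        for s_idx, s in enumerate(strains):
            gxe = np.zeros(n_genes)
            if grp == "Et":
                for j, g in enumerate(gene_ids):
                    shift = truth.gxe_genes.get(g, {}).get(s)
                    if shift:
                        gxe[j] = shift
            for rep in range(1, reps_per_cell + 1):
                mouse = genetic[grp][s_idx] + gxe + rng.normal(
                    0.0, within_sd, size=(pool_size, n_genes)
                )
                latent.append(mouse.mean(axis=0))
                lib_rows.append((f"{s}_{grp}_{rep}", s, grp, rep))
    latent = np.asarray(latent)
    meta = pd.DataFrame(
        lib_rows, columns=["library_id", "strain", "pretreatment", "replicate"]
    ).set_index("library_id")

    n_libs = len(meta)
    if libsize_cv > 0:
        sigma = np.sqrt(np.log1p(libsize_cv**2))
        libsize = rng.lognormal(-0.5 * sigma**2, sigma, size=n_libs)
    else:
        libsize = np.ones(n_libs)

    mu = libsize[:, None] * 2.0 ** (baseline[None, :] + latent)
    if nb_dispersion > 0:
        lam = rng.gamma(shape=1.0 / nb_dispersion, scale=nb_dispersion * mu)
    else:
        lam = mu
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=meta.index, columns=gene_ids)
    return CountsMatrix(counts_df, meta), annotation


def simulate_behaviors(
    genos: GenotypeMatrix,
    truth: SimTruth,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate strain-level behaviors from planted loci and gene weights.

    behavior(strain) = sum(locus effect * allele) + sum(weight * realized
    genetic value of gene in the matching pretreatment group) + N(0, sd^2).
    When :func:`simulate_counts` has not populated ``truth.realized``, the
    QTL part of the gene's genetic value is used instead.
    """
    rng = np.random.default_rng(seed)
    marker_ids = set(genos.marker_map["marker_id"])
    for behavior, (marker, _) in truth.behavior_loci.items():
        if marker not in marker_ids:
            raise ValueError(f"behavior locus references unknown marker: {marker}")
    allele_df = genos.to_frame()
    n = genos.n_strains
    table = pd.DataFrame(index=pd.Index(genos.strain_ids, name="strain_id"))
    for behavior in BEHAVIORS:
        value = np.zeros(n)
        if behavior in truth.behavior_loci:
            marker, eff = truth.behavior_loci[behavior]
            value += eff * allele_df[marker].to_numpy(dtype=float)
        group = "Et" if behavior.endswith("_Et") else "sal"
        weights = truth.behavior_gene_weights.get(behavior, {})
        for gene, w in weights.items():
            if group in truth.realized and gene in truth.realized[group].columns:
                gval = truth.realized[group][gene].to_numpy()
            else:
                gval = _qtl_values(genos, truth, gene)
            value += w * gval
        if noise_sd > 0:
            value += rng.normal(0.0, noise_sd, size=n)
        table[behavior] = value
    return table


def _qtl_values(genos: GenotypeMatrix, truth: SimTruth, gene: str) -> np.ndarray:
    allele_df = genos.to_frame()
    q = np.zeros(genos.n_strains)
    effects = []
    if gene in truth.cis_effects:
        effects.append(truth.cis_effects[gene])
    effects.extend(truth.trans_effects.get(gene, []))
    for marker, eff in effects:
        if marker not in allele_df.columns:
            raise ValueError(f"effect references unknown marker: {marker}")
        q = q + eff * allele_df[marker].to_numpy(dtype=float)
    return q
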