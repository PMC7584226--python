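"""Configuration, table I/O and the end-to-end pipeline.

All tabular interchange is TSV with header rows (genotypes are CSV);
gene/strain/marker ids are strings and positions are Mb floats.  The
pipeline runs: (simulate) -> RPLG filter -> size factors -> VST ->
strain means -> heritability -> per-strain DE -> eQTL mapping (+ golden)
-> genetic correlation (+ candidates), writing each stage's table and a
JSON manifest that makes a rerun with the same seed bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .sim import (
    BEHAVIORS,
    CountsMatrix,
    GenotypeMatrix,
    SimTruth,
    default_marker_map,
    random_truth,
    simulate_behaviors,
    simulate_counts,
    simulate_ri_genotypes,
    validate_marker_map,
)
from .quantify import (
    compute_rplg,
    filter_expressed,
    size_factors,
    strain_means,
    vst_transform,
)
from .heritability import h2_table
from .diffexpr import all_strain_de, de_summary, two_way_anova
from .eqtl import map_eqtls
from .correlate import behavior_vs_de_count, candidate_genes, corr_to_behavior

__all__ = [
    "PipelineConfig",
    "SimulateConfig",
    "simulate_dataset",
    "write_dataset",
    "read_tables",
    "run_pipeline",
]


@dataclass
class SimulateConfig:
    """Synthetic-panel settings; defaults mirror the study design."""

    n_strains: int = 40
    n_markers: int = 2661
    n_genes: int = 1000
    reps_per_cell: int = 3
    pool_size: int = 3
    libsize_cv: float = 0.15
    nb_dispersion: float = 0.02
    behavior_noise_sd: float = 0.5
    n_cis: int = 40
    n_trans: int = 20
    n_gxe: int = 30


@dataclass
class PipelineConfig:
    outdir: str = "rieqtl_out"
    genotypes: str | None = None
    marker_map: str | None = None
    counts: str | None = None
    meta: str | None = None
    annotation: str | None = None
    behavior: str | None = None

    rplg_cutoff: float = 1.0
    read_length: float = 100.0
    de_fdr: float = 0.05
    h2_fdr: float = 0.05
    corr_fdr: float = 0.10
    hub_p: float = 0.01
    cis_mb: float = 5.0
    golden_mb: float = 25.0
    ld_mb: float = 20.0
    eqtl_alpha: float = 0.05
    n_perm: int = 1000
    step_cm: float | None = 1.0
    seed: int = 0
    hub_gene: str | None = None

    simulate: SimulateConfig | None = None

    def __post_init__(self) -> None:
        for name in ("de_fdr", "h2_fdr", "corr_fdr", "hub_p", "eqtl_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("cis_mb", "golden_mb", "ld_mb", "rplg_cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulateConfig(**sim)
        return cfg


def simulate_dataset(cfg: SimulateConfig, seed: int):
    """Generate a full synthetic panel: genotypes, counts, behaviors, truth."""
    mmap = default_marker_map(n_markers=cfg.n_markers, seed=seed)
    genos = simulate_ri_genotypes(cfg.n_strains, mmap, seed=seed + 1)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    truth = random_truth(
        mmap, gene_ids, genos.strain_ids, seed=seed + 2,
        n_cis=cfg.n_cis, n_trans=cfg.n_trans, n_gxe=cfg.n_gxe,
    )
    counts, annotation = simulate_counts(
        genos, truth, cfg.n_genes,
        reps_per_cell=cfg.reps_per_cell, pool_size=cfg.pool_size,
        libsize_cv=cfg.libsize_cv, nb_dispersion=cfg.nb_dispersion,
        seed=seed + 3,
    )
    behavior = simulate_behaviors(genos, truth, cfg.behavior_noise_sd, seed=seed + 4)
    return genos, counts, annotation, behavior, truth


def write_dataset(
    outdir: str | Path,
    genos: GenotypeMatrix,
    counts: CountsMatrix,
    annotation: pd.DataFrame,
    behavior: pd.DataFrame,
    truth: SimTruth | None = None,
) -> dict[str, str]:
    """Write a dataset in the interchange formats; returns path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": str(out / "genotypes.csv"),
        "marker_map": str(out / "marker_map.tsv"),
        "counts": str(out / "counts.tsv"),
        "meta": str(out / "sample_meta.tsv"),
        "annotation": str(out / "gene_annotation.tsv"),
        "behavior": str(out / "behavior.tsv"),
    }
    genos.to_frame().to_csv(paths["genotypes"])
    genos.marker_map.to_csv(paths["marker_map"], sep="\t", index=False)
    counts.counts.to_csv(paths["counts"], sep="\t", index_label="library_id")
    counts.meta.to_csv(paths["meta"], sep="\t")
    annotation.to_csv(paths["annotation"], sep="\t")
    behavior.to_csv(paths["behavior"], sep="\t")
    if truth is not None:
        paths["truth"] = str(out / "truth.json")
        Path(paths["truth"]).write_text(truth.to_json())
    return paths


def read_tables(config: PipelineConfig):
    """Load and cross-validate the input tables.

    Strain ids must be consistent between genotypes and library metadata
    (a library naming an unknown strain is an error); genes missing from
    the annotation are dropped from the eQTL stage only, with a warning.
    """
    for name in ("genotypes", "marker_map", "counts", "meta", "annotation"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {p}")
    mmap = validate_marker_map(pd.read_csv(config.marker_map, sep="\t"))
    geno_df = pd.read_csv(config.genotypes, index_col=0)
    if list(geno_df.columns) != list(mmap["marker_id"]):
        raise ValueError("genotype columns do not match the marker map")
    genos = GenotypeMatrix(
        list(geno_df.index.astype(str)), mmap, geno_df.to_numpy()
    )
    counts_df = pd.read_csv(config.counts, sep="\t", index_col=0)
    meta = pd.read_csv(config.meta, sep="\t", index_col=0)
    unknown = set(meta["strain"]) - set(genos.strain_ids)
    if unknown:
        raise ValueError(f"libraries reference unknown strains: {sorted(unknown)}")
    counts = CountsMatrix(counts_df, meta)
    annotation = pd.read_csv(config.annotation, sep="\t", index_col=0)
    missing_ann = [g for g in counts.gene_ids if g not in annotation.index]
    if missing_ann:
        warnings.warn(
            f"{len(missing_ann)} genes lack annotation; "
            "they are excluded from the eQTL stage"
        )
    behavior = None
    if config.behavior and Path(config.behavior).exists():
        behavior = pd.read_csv(config.behavior, sep="\t", index_col=0)
        extra = set(behavior.index) - set(genos.strain_ids)
        if extra:
            raise ValueError(f"behavior table names unknown strains: {sorted(extra)}")
    return genos, counts, annotation, behavior


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; writes stage tables and a manifest.

    Returns an in-memory bundle of every stage result.  When the
    behavior table is absent the correlation/candidate stages are
    skipped with a notice; everything upstream still runs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = None
    if config.simulate is not None:
        genos, counts, annotation, behavior, truth = simulate_dataset(
            config.simulate, config.seed
        )
        paths = write_dataset(out / "simulated", genos, counts,
                              annotation, behavior, truth)
        for k, v in paths.items():
            if getattr(config, k, None) is None and k != "truth":
                setattr(config, k, v)
    else:
        genos, counts, annotation, behavior = read_tables(config)

    # --- quantification --------------------------------------------------
    rplg = compute_rplg(counts, annotation["length_bp"], config.read_length)
    expressed = filter_expressed(rplg, counts.meta, cutoff=config.rplg_cutoff)
    kept = expressed.index[expressed["kept"]].tolist()
    # genes without annotation cannot be RPLG-filtered (no length); they
    # stay in the expression analyses and are skipped by the eQTL stage
    kept += [g for g in counts.gene_ids if g not in annotation.index]
    factors = size_factors(counts)
    vst = vst_transform(counts, factors)[kept]
    norm_counts = counts.counts[kept].div(factors, axis=0)
    means = strain_means(vst, counts.meta)
    expressed.to_csv(out / "expressed_genes.tsv", sep="\t")
    for grp, df in means.items():
        df.to_csv(out / f"strain_means_{grp}.tsv", sep="\t")

    # --- heritability ----------------------------------------------------
    h2 = h2_table(vst, counts.meta, fdr_alpha=config.h2_fdr)
    h2.to_csv(out / "heritability.tsv", sep="\t", index=False)

    # --- differential expression -----------------------------------------
    de = all_strain_de(vst, counts.meta, norm_counts, fdr_alpha=config.de_fdr)
    de.to_csv(out / "de_per_strain.tsv", sep="\t", index=False)
    desum = de_summary(de)
    twoway = two_way_anova(vst, counts.meta)
    twoway.to_csv(out / "two_way_anova.tsv", sep="\t", index=False)

    # --- eQTL mapping -----------------------------------------------------
    calls = map_eqtls(
        means, genos, annotation,
        n_perm=config.n_perm, step_cm=config.step_cm, seed=config.seed,
        alpha=config.eqtl_alpha, cis_mb=config.cis_mb,
        golden_mb=config.golden_mb,
    )
    calls.to_csv(out / "eqtl_calls.tsv", sep="\t", index=False)

    # --- correlation & candidates ----------------------------------------
    correlations = None
    candidates = None
    behavior_de_corr = None
    if behavior is not None:
        corr_frames = []
        cand_frames = []
        for beh in behavior.columns:
            grp = "Et" if str(beh).endswith("_Et") else "sal"
            corr = corr_to_behavior(
                means[grp], behavior[beh], grp, str(beh),
                fdr_alpha=config.corr_fdr,
            )
            corr_frames.append(corr.reset_index())
            grp_calls = calls[calls["group"] == grp]
            cand = candidate_genes(
                grp_calls, corr, annotation, corr_alpha=config.corr_fdr
            )
            if len(cand):
                cand_frames.append(cand)
        correlations = pd.concat(corr_frames, ignore_index=True)
        correlations.to_csv(out / "behavior_correlations.tsv", sep="\t",
                            index=False)
        candidates = (
            pd.concat(cand_frames, ignore_index=True)
            if cand_frames else pd.DataFrame()
        )
        candidates.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)

        de_counts = de.groupby("strain")["significant"].sum()
        behavior_de_corr = {}
        for beh in behavior.columns:
            if de_counts.nunique() > 1:
                r, p = behavior_vs_de_count(de_counts, behavior[beh])
            else:
                r, p = float("nan"), float("nan")
            behavior_de_corr[str(beh)] = {"r": r, "p": p}
    else:
        warnings.warn("behavior table absent; correlation stage skipped")

    manifest = {
        "package": "rieqtl",
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "n_genes_input": len(counts.gene_ids),
        "n_genes_expressed": len(kept),
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "genotypes": genos, "counts": counts, "annotation": annotation,
        "behavior": behavior, "truth": truth,
        "expressed": expressed, "size_factors": factors, "vst": vst,
        "strain_means": means, "heritability": h2,
        "de": de, "de_summary": desum, "two_way": twoway,
        "eqtl_calls": calls, "correlations": correlations,
        "candidates": candidates, "behavior_de_corr": behavior_de_corr,
        "manifest": manifest,
    }


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return {k: v for k, v in d.items() if v is not None}
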