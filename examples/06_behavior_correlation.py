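"""Genetic correlation of expression with behavior, and candidate genes.

Strain means are replicable genetic units, so a Pearson correlation
between a gene's strain means and a behavior's strain means estimates
shared genetic variance.  Candidate genes for a behavior are those that
are both cis-regulated (significant cis-eQTL) and correlated to the
behavior (FDR < 0.10); a hub-gene analysis finds the network around one
gene of interest.
"""

from rieqtl import (
    PipelineConfig,
    SimulateConfig,
    corr_to_behavior,
    hub_correlates,
    run_pipeline,
)

cfg = PipelineConfig(
    outdir="scratch/example06", n_perm=200, seed=7,
    simulate=SimulateConfig(n_strains=40, n_markers=300, n_genes=300,
                            n_cis=30, n_trans=10, n_gxe=20),
)
res = run_pipeline(cfg)
truth = res["truth"]

corr = res["correlations"]
for trait, sub in corr.groupby("trait"):
    planted = list(truth.behavior_gene_weights.get(trait, {}))
    n_sig = int(sub["significant"].sum())
    hit = sub.set_index("gene_id").reindex(planted)["significant"].any()
    print(f"{trait}: {n_sig} correlated genes (FDR<0.10); "
          f"planted driver recovered: {bool(hit)}")

cand = res["candidates"]
print(f"candidate genes (cis-eQTL AND behavior correlation): {len(cand)}")
if len(cand):
    print(cand[["gene_id", "behavior", "chrom", "start_mb", "r", "golden"]]
          .to_string(index=False))

# hub analysis around the strongest planted cis gene
hub = max(truth.cis_effects, key=lambda g: abs(truth.cis_effects[g][1]))
if hub in res["strain_means"]["Et"].columns:
    hubs = hub_correlates(hub, res["strain_means"]["Et"],
                          res["annotation"], p_cut=0.01)
    print(f"hub {hub}: {len(hubs)} correlates at nominal p<0.01, "
          f"{int(hubs['distal'].sum())} distal (>20 Mb or other chromosome, "
          "so not attributable to linkage disequilibrium)")
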