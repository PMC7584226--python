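"""Expression filtering and normalization on simulated pooled libraries.

RPLG (reads per length of gene) puts counts on a coverage scale: a gene
is called expressed when its median RPLG exceeds 1 (one-fold coverage)
in either pretreatment group.  Counts are then normalized by
median-of-ratios size factors and variance-stabilized before any
genetic analysis.
"""

from rieqtl import (
    SimTruth,
    compute_rplg,
    default_marker_map,
    filter_expressed,
    simulate_counts,
    simulate_ri_genotypes,
    size_factors,
    strain_means,
    vst_transform,
)

mmap = default_marker_map(n_markers=200, seed=0)
genos = simulate_ri_genotypes(40, mmap, seed=1)
counts, annotation = simulate_counts(genos, SimTruth(), n_genes=300, seed=2)

rplg = compute_rplg(counts, annotation["length_bp"], read_length=100)
expressed = filter_expressed(rplg, counts.meta)
n_sal = int((expressed["median_sal"] > 1).sum())
n_et = int((expressed["median_Et"] > 1).sum())
n_union = int(expressed["kept"].sum())
print(f"expressed genes: saline {n_sal}, ethanol {n_et}, union {n_union}")
print("  (the union is the analysis set; genes below 1X coverage in both "
      "groups are background)")

factors = size_factors(counts)
print(f"size factors: min {factors.min():.3f}, max {factors.max():.3f} "
      "(library-depth correction)")

vst = vst_transform(counts, factors)
kept = expressed.index[expressed["kept"]]
means = strain_means(vst[kept], counts.meta)
print(f"strain-mean matrix (saline): {means['sal'].shape[0]} strains x "
      f"{means['sal'].shape[1]} genes - the input to all genetics")
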