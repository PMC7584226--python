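import warnings

import numpy as np
import pandas as pd
import pytest

from rieqtl import (
    GenotypeMatrix,
    SimTruth,
    default_marker_map,
    simulate_counts,
    simulate_ri_genotypes,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def tiny_map() -> pd.DataFrame:
    """Two chromosomes, five markers."""
    return pd.DataFrame({
        "marker_id": ["m0", "m1", "m2", "m3", "m4"],
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
        "pos_mb": [10.0, 30.0, 60.0, 5.0, 45.0],
        "pos_cm": [5.0, 15.0, 30.0, 2.5, 22.5],
    })


@pytest.fixture(scope="session")
def small_panel():
    """40-strain panel on a 100-marker map with a mixed architecture."""
    mmap = default_marker_map(n_markers=100, seed=7)
    genos = simulate_ri_genotypes(40, mmap, seed=8)
    truth = SimTruth()
    markers = mmap["marker_id"].to_numpy()
    gene_ids = [f"g{i:05d}" for i in range(60)]
    rng = np.random.default_rng(9)
    for g in gene_ids[:10]:
        truth.cis_effects[g] = (str(markers[rng.integers(len(markers))]), 1.0)
    for g in gene_ids[10:]:
        for grp in ("sal", "Et"):
            truth.h2_target[(g, grp)] = float(rng.uniform(0.1, 0.8))
    counts, annotation = simulate_counts(
        genos, truth, 60, reps_per_cell=3, seed=10,
        base_log2_mean=8.0, base_log2_sd=1.0,
    )
    return genos, truth, counts, annotation
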