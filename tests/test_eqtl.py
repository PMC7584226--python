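"""Haley-Knott scan, permutation thresholds, cis/trans and golden rules."""

import numpy as np
import pandas as pd
import pytest

from rieqtl import (
    GenotypeMatrix,
    classify_cis_trans,
    genotype_probs,
    golden_filter,
    hk_scan,
    map_eqtls,
    perm_thresholds,
    simulate_ri_genotypes,
)
from rieqtl.eqtl import EqtlScan, gene_seed
from rieqtl.sim import haldane_r, ri_transition


def single_marker_positions():
    return pd.DataFrame({
        "chrom": ["chr1"], "pos_mb": [1.0], "pos_cm": [0.5],
        "is_marker": [True],
    })


class TestGenotypeProbs:
    def test_marker_dosage_equals_observed_allele(self, tiny_map):
        genos = simulate_ri_genotypes(6, tiny_map, seed=1)
        pos, dos = genotype_probs(genos, step_cm=None)
        assert pos["is_marker"].all()
        assert np.array_equal(dos, genos.alleles.astype(float))

    def test_equal_flanks_pull_dosage_toward_allele(self):
        mmap = pd.DataFrame({
            "marker_id": ["a", "b"], "chrom": ["chr1", "chr1"],
            "pos_mb": [0.0, 8.0], "pos_cm": [0.0, 4.0],
        })
        genos = GenotypeMatrix(["s1", "s2"], mmap, np.array([[1, 1], [0, 0]]))
        _, dos = genotype_probs(genos, step_cm=2.0)
        interior = dos[:, 1]  # pseudomarker at 2 cM
        assert interior[0] > 0.5 and interior[1] < 0.5
        # tighter flanks -> closer to the shared allele
        mmap2 = mmap.assign(pos_mb=[0.0, 2.0], pos_cm=[0.0, 1.0])
        genos2 = GenotypeMatrix(["s1", "s2"], mmap2, np.array([[1, 1], [0, 0]]))
        _, dos2 = genotype_probs(genos2, step_cm=0.5)
        assert dos2[0, 1] > interior[0]

    def test_midpoint_matches_path_enumeration(self):
        """Midpoint of a 20 cM interval: conditional dosage equals the
        exhaustive enumeration over the 4 configurations of the two-step
        Markov chain."""
        gap = 20.0
        mmap = pd.DataFrame({
            "marker_id": ["a", "b"], "chrom": ["chr1", "chr1"],
            "pos_mb": [0.0, 40.0], "pos_cm": [0.0, gap],
        })
        alleles = np.array([[0, 1], [1, 1], [0, 0], [1, 0]])
        genos = GenotypeMatrix(["s1", "s2", "s3", "s4"], mmap, alleles)
        _, dos = genotype_probs(genos, step_cm=gap / 2)
        r_half = float(ri_transition(haldane_r(gap / 2)))

        def enumerate_mid(g_l, g_r):
            def step(a, b):
                return r_half if a != b else 1.0 - r_half
            probs = {m: step(g_l, m) * step(m, g_r) for m in (0, 1)}
            return probs[1] / (probs[0] + probs[1])

        for i, (gl, gr) in enumerate(alleles):
            assert dos[i, 1] == pytest.approx(enumerate_mid(gl, gr), abs=1e-12)

    def test_step_must_be_positive(self, tiny_map):
        genos = simulate_ri_genotypes(4, tiny_map, seed=0)
        with pytest.raises(ValueError):
            genotype_probs(genos, step_cm=-1.0)


class TestHkScan:
    def test_constant_trait_scores_zero(self, tiny_map):
        genos = simulate_ri_genotypes(8, tiny_map, seed=2)
        pos, dos = genotype_probs(genos, step_cm=None)
        scan = hk_scan(np.full(8, 3.0), dos, pos)
        assert np.allclose(scan.lrs, 0.0)

    def test_worked_example_eight_strains(self):
        """dosage (0,0,0,0,1,1,1,1), trait (1,1,2,2,3,3,4,4):
        RSS0 = 10, RSS1 = 2, LRS = 8 ln 5."""
        dos = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)[:, None]
        trait = np.array([1, 1, 2, 2, 3, 3, 4, 4], dtype=float)
        scan = hk_scan(trait, dos, single_marker_positions())
        assert scan.lrs[0] == pytest.approx(8 * np.log(5.0), rel=1e-12)

    def test_binary_dosage_equals_group_decomposition(self):
        """At a marker, LRS = n ln(SS_total / SS_within) for the two
        genotype groups."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            dos = rng.integers(0, 2, 20).astype(float)
            if dos.std() == 0:
                continue
            trait = rng.normal(0, 1, 20) + dos
            scan = hk_scan(trait, dos[:, None], single_marker_positions())
            ss_tot = np.sum((trait - trait.mean()) ** 2)
            ss_w = sum(
                np.sum((trait[dos == g] - trait[dos == g].mean()) ** 2)
                for g in (0, 1)
            )
            assert scan.lrs[0] == pytest.approx(20 * np.log(ss_tot / ss_w),
                                                abs=1e-8)

    def test_matches_independent_ols(self, tiny_map):
        """LRS equals n ln(RSS0/RSS1) from an lstsq-based regression."""
        genos = simulate_ri_genotypes(15, tiny_map, seed=4)
        pos, dos = genotype_probs(genos, step_cm=None)
        rng = np.random.default_rng(5)
        for _ in range(20):
            trait = rng.normal(0, 1, 15)
            scan = hk_scan(trait, dos, pos)
            for j in range(dos.shape[1]):
                x = np.column_stack([np.ones(15), dos[:, j]])
                if np.ptp(dos[:, j]) == 0:
                    assert scan.lrs[j] == 0.0
                    continue
                rss1 = np.sum((trait - x @ np.linalg.lstsq(x, trait, rcond=None)[0]) ** 2)
                rss0 = np.sum((trait - trait.mean()) ** 2)
                assert scan.lrs[j] == pytest.approx(15 * np.log(rss0 / rss1),
                                                    abs=1e-8)

    def test_affine_invariance(self, tiny_map):
        genos = simulate_ri_genotypes(12, tiny_map, seed=6)
        pos, dos = genotype_probs(genos, step_cm=None)
        trait = np.random.default_rng(7).normal(0, 1, 12)
        s1 = hk_scan(trait, dos, pos)
        s2 = hk_scan(-3.0 + 2.0 * trait, dos, pos)
        assert np.allclose(s1.lrs, s2.lrs, atol=1e-10)

    def test_perfect_fit_capped_and_flagged(self):
        dos = np.array([0, 0, 1, 1.0])[:, None]
        trait = np.array([1, 1, 2, 2.0])
        scan = hk_scan(trait, dos, single_marker_positions())
        assert scan.capped and np.isfinite(scan.lrs[0])


class TestPermutationThresholds:
    def test_constant_trait_all_zero(self, tiny_map):
        genos = simulate_ri_genotypes(10, tiny_map, seed=8)
        _, dos = genotype_probs(genos, step_cm=None)
        thr, perm_max = perm_thresholds(np.ones(10), dos, n_perm=100, seed=0)
        assert thr[0.05] == 0.0 and np.allclose(perm_max, 0.0)

    def test_threshold_monotonicity(self, tiny_map):
        genos = simulate_ri_genotypes(20, tiny_map, seed=9)
        _, dos = genotype_probs(genos, step_cm=None)
        trait = np.random.default_rng(10).normal(0, 1, 20)
        thr, _ = perm_thresholds(trait, dos, n_perm=200, seed=1)
        assert thr[0.10] <= thr[0.05] <= thr[0.001]

    def test_minimum_permutations_enforced(self, tiny_map):
        genos = simulate_ri_genotypes(10, tiny_map, seed=8)
        _, dos = genotype_probs(genos, step_cm=None)
        with pytest.raises(ValueError):
            perm_thresholds(np.ones(10), dos, n_perm=50, seed=0)

    def test_gene_seed_deterministic_and_bounded(self):
        s1 = gene_seed(17, "g00042", "sal")
        assert s1 == gene_seed(17, "g00042", "sal")
        assert s1 != gene_seed(17, "g00042", "Et")
        assert 0 <= s1 < 2**31


class TestClassification:
    @pytest.mark.parametrize("peak,gene,expected,dist", [
        (("chr4", 129.8), ("chr4", 129.5), "cis", 0.3),
        (("chr1", 15.0), ("chr1", 10.0), "cis", 5.0),   # inclusive boundary
        (("chr1", 15.1), ("chr1", 10.0), "trans", 5.1),
        (("chr2", 10.0), ("chr1", 10.0), "trans", np.inf),
    ])
    def test_cis_trans_rule(self, peak, gene, expected, dist):
        cls, d = classify_cis_trans(peak[0], peak[1], gene[0], gene[1])
        assert cls == expected
        assert d == dist or d == pytest.approx(dist)


def constructed_scan(exceed_mb=None, t010=10.0, chrom="chr1"):
    """Flat other-condition scan with one optional exceedance position."""
    pos = pd.DataFrame({
        "chrom": chrom, "pos_mb": np.arange(0.0, 200.0, 5.0),
        "pos_cm": np.arange(0.0, 100.0, 2.5), "is_marker": True,
    })
    lrs = np.full(len(pos), 1.0)
    if exceed_mb is not None:
        lrs[(pos["pos_mb"] - exceed_mb).abs().idxmin()] = 15.0
    return EqtlScan(positions=pos, lrs=lrs, n=40,
                    thresholds={0.10: t010, 0.05: 12.0, 0.001: 20.0})


class TestGoldenRule:
    GENE = ("chr1", 50.0)

    # (class, peak, other-scan exceedance position, expected golden)
    CASES = [
        ("cis", ("chr1", 52.0), None, True),       # other scan quiet
        ("cis", ("chr1", 52.0), 60.0, False),      # exceedance 10 Mb from gene
        ("cis", ("chr1", 52.0), 100.0, True),      # exceedance 50 Mb away
        ("trans", ("chr1", 120.0), None, True),    # eligible, quiet
        ("trans", ("chr1", 120.0), 110.0, False),  # exceedance near peak
        ("trans", ("chr1", 120.0), 50.0, True),    # exceedance near gene only
        ("trans", ("chr1", 60.0), None, False),    # peak within 25 Mb of gene
        ("trans", ("chr1", 60.0), 100.0, False),   # ineligible regardless
    ]

    @pytest.mark.parametrize("cls,peak,exceed,expected", CASES)
    def test_truth_table(self, cls, peak, exceed, expected):
        other = constructed_scan(exceed_mb=exceed)
        got = golden_filter(cls, peak[0], peak[1], *self.GENE, other)
        assert got is expected

    @pytest.mark.parametrize("cls,peak,exceed,expected", CASES)
    def test_matches_handwritten_oracle(self, cls, peak, exceed, expected):
        """Independent literal transcription of the published rule."""
        other = constructed_scan(exceed_mb=exceed)

        def oracle():
            t = other.thresholds[0.10]
            gene_chrom, gene_mb = self.GENE
            if cls == "trans":
                if peak[0] == gene_chrom and abs(peak[1] - gene_mb) <= 25:
                    return False
                center_chrom, center_mb = peak
            else:
                center_chrom, center_mb = gene_chrom, gene_mb
            for (_, row), lrs in zip(other.positions.iterrows(), other.lrs):
                if (row["chrom"] == center_chrom
                        and abs(row["pos_mb"] - center_mb) <= 25
                        and lrs >= t):
                    return False
            return True

        got = golden_filter(cls, peak[0], peak[1], *self.GENE, other)
        assert got is oracle() is expected

    def test_trans_peak_on_other_chromosome_eligible(self):
        other = constructed_scan(exceed_mb=None, chrom="chr2")
        other.positions["chrom"] = "chr2"
        got = golden_filter("trans", "chr2", 50.0, "chr1", 50.0, other)
        assert got is True

    def test_mismatched_grids_rejected(self):
        other = constructed_scan()
        own = other.positions.iloc[:-1]
        with pytest.raises(ValueError):
            golden_filter("cis", "chr1", 52.0, "chr1", 50.0, other,
                          own_positions=own)


class TestMapEqtls:
    def test_planted_cis_effects_recovered(self, small_panel):
        from rieqtl import size_factors, strain_means, vst_transform

        genos, truth, counts, annotation = small_panel
        v = vst_transform(counts, size_factors(counts))
        means = strain_means(v, counts.meta)
        calls = map_eqtls(means, genos, annotation, n_perm=150,
                          step_cm=None, seed=0,
                          genes=list(truth.cis_effects))
        sal = calls[calls["group"] == "sal"]
        detected = sal["significant"] & (sal["cis_trans"] == "cis")
        assert detected.mean() >= 0.8

    def test_golden_rare_when_architecture_shared(self, small_panel):
        """The planted effects are identical in both pretreatments, so
        pretreatment-unique (golden) calls should be a small minority of
        significant calls (threshold noise only)."""
        from rieqtl import size_factors, strain_means, vst_transform

        genos, truth, counts, annotation = small_panel
        v = vst_transform(counts, size_factors(counts))
        means = strain_means(v, counts.meta)
        calls = map_eqtls(means, genos, annotation, n_perm=150,
                          step_cm=None, seed=1,
                          genes=list(truth.cis_effects))
        n_sig = int(calls["significant"].sum())
        assert n_sig > 0
        assert calls["golden"].sum() / n_sig <= 0.15
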