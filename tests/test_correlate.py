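"""Strain-mean genetic correlations, hub analysis and candidates."""

import numpy as np
import pandas as pd
import pytest

from rieqtl import (
    behavior_vs_de_count,
    candidate_genes,
    corr_to_behavior,
    hub_correlates,
    pearson_with_p,
)


def strain_index(n):
    return pd.Index([f"s{i}" for i in range(n)], name="strain_id")


class TestPearson:
    def test_affine_relation_gives_unit_correlation(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 3.0 - 2.0 * x)
        assert r == pytest.approx(-1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_undefined(self):
        r, p = pearson_with_p(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)

    def test_matches_definitional_formula_n6(self):
        """Six strain pairs: r and p from the covariance definition and
        the t transform t = r sqrt((n-2)/(1-r^2))."""
        from scipy import stats

        x = np.array([1.0, 2.0, 2.5, 3.1, 4.0, 5.5])
        y = np.array([2.2, 1.8, 3.0, 3.5, 3.2, 5.0])
        r, p = pearson_with_p(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r_def = cov / (x.std() * y.std())
        t = r_def * np.sqrt(4 / (1 - r_def**2))
        p_def = 2 * stats.t.sf(abs(t), df=4)
        assert r == pytest.approx(r_def, rel=1e-12)
        assert p == pytest.approx(p_def, rel=1e-12)


class TestCorrToBehavior:
    def test_planted_gene_found_constant_behavior_flagged(self):
        rng = np.random.default_rng(0)
        idx = strain_index(40)
        means = pd.DataFrame(
            rng.normal(0, 1, (40, 30)), index=idx,
            columns=[f"g{j}" for j in range(30)],
        )
        means["gflat"] = 1.0
        behavior = pd.Series(means["g0"] * 2.0 + 1.0, index=idx)
        res = corr_to_behavior(means, behavior, "Et", "AFT_Et")
        assert res.loc["g0", "r"] == pytest.approx(1.0)
        assert res.loc["g0", "significant"]
        assert res.loc["gflat", "undefined"]

    def test_constant_behavior_all_undefined(self):
        idx = strain_index(10)
        means = pd.DataFrame(np.random.default_rng(1).normal(0, 1, (10, 3)),
                             index=idx, columns=list("abc"))
        res = corr_to_behavior(means, pd.Series(2.0, index=idx), "sal", "ST_sal")
        assert res["undefined"].all()

    def test_pairwise_strain_dropping(self):
        idx = strain_index(8)
        means = pd.DataFrame({"g0": np.arange(8.0)}, index=idx)
        behavior = pd.Series(np.arange(8.0), index=idx)
        behavior.iloc[0] = np.nan
        res = corr_to_behavior(means, behavior, "sal", "ST_sal")
        assert res.loc["g0", "n"] == 7

    def test_null_panel_yields_no_correlates(self):
        """Independent expression and behavior: nominal rate ~ alpha and
        BH at FDR < 0.10 finds nothing."""
        rng = np.random.default_rng(2)
        idx = strain_index(40)
        means = pd.DataFrame(rng.normal(0, 1, (40, 500)), index=idx,
                             columns=[f"g{j}" for j in range(500)])
        behavior = pd.Series(rng.normal(0, 1, 40), index=idx)
        res = corr_to_behavior(means, behavior, "sal", "ST_sal")
        rate = (res["p"] < 0.01).mean()
        se = np.sqrt(0.01 * 0.99 / 500)
        assert abs(rate - 0.01) <= 2 * se + 1e-9
        assert res["significant"].sum() == 0


class TestHub:
    def annotation(self, genes, hub_chrom="chr4", hub_mb=129.5):
        ann = pd.DataFrame({
            "chrom": hub_chrom, "start_mb": hub_mb, "length_bp": 1000,
        }, index=pd.Index(genes, name="gene_id"))
        return ann

    def test_recovers_driven_targets(self):
        """Hub driving 50 targets at r ~ 0.6 over 40 strains: >= 90%
        recovered at nominal p < 0.01."""
        rng = np.random.default_rng(3)
        idx = strain_index(40)
        hub = rng.normal(0, 1, 40)
        cols = {"hub": hub}
        for j in range(50):
            cols[f"t{j}"] = 0.6 * hub + np.sqrt(1 - 0.36) * rng.normal(0, 1, 40)
        for j in range(100):
            cols[f"n{j}"] = rng.normal(0, 1, 40)
        means = pd.DataFrame(cols, index=idx)
        ann = self.annotation(means.columns)
        res = hub_correlates("hub", means, ann, p_cut=0.01)
        targets = [f"t{j}" for j in range(50)]
        assert np.mean([t in res.index for t in targets]) >= 0.9
        # hub correlates with itself, proximal at distance 0
        assert "hub" in res.index and not res.loc["hub", "distal"]

    def test_ld_distance_boundary(self):
        rng = np.random.default_rng(4)
        idx = strain_index(30)
        hub = rng.normal(0, 1, 30)
        means = pd.DataFrame({
            "hub": hub, "near": hub + rng.normal(0, 0.1, 30),
            "far": hub + rng.normal(0, 0.1, 30),
            "other": hub + rng.normal(0, 0.1, 30),
        }, index=idx)
        ann = self.annotation(means.columns)
        ann.loc["near", "start_mb"] = 129.5 + 19.9
        ann.loc["far", "start_mb"] = 129.5 + 20.1
        ann.loc["other", "chrom"] = "chr7"
        res = hub_correlates("hub", means, ann, p_cut=0.01, ld_mb=20.0)
        assert not res.loc["near", "distal"]
        assert res.loc["far", "distal"]
        assert res.loc["other", "distal"]

    def test_constant_hub_rejected(self):
        idx = strain_index(10)
        means = pd.DataFrame({"hub": 1.0, "g": np.arange(10.0)}, index=idx)
        with pytest.raises(ValueError):
            hub_correlates("hub", means, self.annotation(means.columns))


class TestBehaviorVsDeCount:
    def test_proportional_counts_give_unit_correlation(self):
        idx = strain_index(10)
        counts = pd.Series(np.arange(10.0), index=idx)
        r, p = behavior_vs_de_count(counts, 3.0 * counts + 1.0)
        assert r == pytest.approx(1.0)

    def test_constant_counts_flagged(self):
        idx = strain_index(10)
        counts = pd.Series(0.0, index=idx)
        r, p = behavior_vs_de_count(counts, pd.Series(np.arange(10.0), index=idx))
        assert np.isnan(r)


class TestCandidates:
    def fixtures(self):
        calls = pd.DataFrame({
            "gene_id": ["g_cis", "g_cisonly", "g_trans", "g_weak"],
            "group": "Et",
            "significant": [True, True, True, False],
            "cis_trans": ["cis", "cis", "trans", "cis"],
            "peak_lrs": [30.0, 25.0, 20.0, 8.0],
            "golden": [True, False, False, False],
        })
        corr = pd.DataFrame({
            "trait": "AFT_Et", "group": "Et",
            "r": [0.7, 0.1, 0.8, 0.75],
            "q": [0.01, 0.9, 0.02, 0.03],
        }, index=pd.Index(["g_cis", "g_cisonly", "g_trans", "g_weak"],
                          name="gene_id"))
        ann = pd.DataFrame({
            "chrom": ["chr4", "chr4", "chr2", "chr5"],
            "start_mb": [129.5, 50.0, 10.0, 20.0],
        }, index=corr.index)
        return calls, corr, ann

    def test_intersection_rules(self):
        calls, corr, ann = self.fixtures()
        out = candidate_genes(calls, corr, ann,
                              behavior_qtls=[("chr4", 120.0, 140.0)])
        assert list(out["gene_id"]) == ["g_cis"]  # others excluded
        rec = out.iloc[0]
        assert rec["golden"] and rec["in_behavior_qtl"]

    def test_output_subset_of_both_sets(self):
        calls, corr, ann = self.fixtures()
        out = candidate_genes(calls, corr, ann)
        cis_set = set(calls.loc[calls["significant"]
                                & (calls["cis_trans"] == "cis"), "gene_id"])
        corr_set = set(corr.index[corr["q"] < 0.10])
        assert set(out["gene_id"]) <= cis_set & corr_set
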