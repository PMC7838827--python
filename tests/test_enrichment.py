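import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from nascenttx import enrichment as enr
from nascenttx.genomic_io import GenomeLayout


class TestSuperEnhancers:
    def _peaks(self, positions, signals, gap=50_000):
        return pd.DataFrame([
            {"chrom": "chr1", "start": p, "end": p + 1_000,
             "name": f"p{i}", "signal": s}
            for i, (p, s) in enumerate(zip(positions, signals))])

    def test_stitching_rule(self):
        near = self._peaks([0, 11_000], [1, 1])
        far = self._peaks([0, 21_000], [1, 1])
        assert len(enr.call_super_enhancers(near)) == 1
        assert len(enr.call_super_enhancers(far)) == 2

    def test_single_outlier_flagged(self):
        positions = np.arange(50) * 100_000
        signals = np.ones(50)
        signals[-1] = 100.0
        out = enr.call_super_enhancers(self._peaks(positions, signals))
        assert int(out["is_super"].sum()) == 1
        assert out.loc[out["is_super"], "signal"].iloc[0] == 100.0

    def test_all_equal_signals_no_supers(self):
        out = enr.call_super_enhancers(
            self._peaks(np.arange(10) * 100_000, np.ones(10)))
        assert not out["is_super"].any()

    def test_invariant_to_uniform_signal_scaling(self):
        rng = np.random.default_rng(0)
        signals = rng.pareto(2.0, 40) + 0.1
        positions = np.arange(40) * 100_000
        a = enr.call_super_enhancers(self._peaks(positions, signals))
        b = enr.call_super_enhancers(self._peaks(positions, signals * 7.3))
        pd.testing.assert_series_equal(a["is_super"], b["is_super"])

    def test_fewer_than_three_regions_all_typical(self):
        with pytest.warns(UserWarning, match="inflection"):
            out = enr.call_super_enhancers(
                self._peaks([0, 100_000], [1.0, 50.0]))
        assert not out["is_super"].any()


class TestChicSupport:
    def _fixtures(self, score, distance=50_000):
        promoters = pd.DataFrame([{"gene_id": "g", "chrom": "chr1",
                                   "tss": 100_000, "strand": "+"}])
        enh_mid = 100_000 + distance
        enhancers = pd.DataFrame([{"enhancer_id": "e", "chrom": "chr1",
                                   "start": enh_mid - 500,
                                   "end": enh_mid + 500}])
        pairs = pd.DataFrame([{"enhancer_id": "e", "gene_id": "g",
                               "method": "CN", "distance": distance,
                               "r": 0.9, "skip": False}])
        interactions = pd.DataFrame([{
            "bait_chrom": "chr1", "bait_start": 98_000, "bait_end": 102_000,
            "hit_chrom": "chr1", "hit_start": enh_mid - 2_000,
            "hit_end": enh_mid + 2_000, "score": score}])
        return pairs, interactions, promoters, enhancers

    def test_score_at_threshold_supported(self):
        out, frac = enr.chic_support(*self._fixtures(3.0))
        assert frac == 1.0

    def test_score_below_threshold_unsupported(self):
        out, frac = enr.chic_support(*self._fixtures(2.9))
        assert frac == 0.0

    def test_short_pairs_excluded_from_denominator(self):
        out, frac = enr.chic_support(*self._fixtures(5.0, distance=8_000))
        assert out.empty and np.isnan(frac)


class TestNullEnsemble:
    def test_plus_one_rule(self):
        ens = enr.NullEnsemble(10.0, np.zeros(100))
        assert ens.p_value == pytest.approx(1 / 101)

    def test_p_never_zero_and_at_most_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ens = enr.NullEnsemble(rng.normal(), rng.normal(size=37))
            assert 0.0 < ens.p_value <= 1.0


class TestFisher:
    def test_symmetric_table(self):
        odds, p = enr.fisher_enrichment(10, 10, 10, 10)
        assert odds == 1.0 and p == pytest.approx(1.0)

    def test_cross_product_and_hypergeom_oracle(self):
        odds, p = enr.fisher_enrichment(20, 10, 10, 20)
        assert odds == pytest.approx(4.0)
        # exhaustive hypergeometric oracle for the two-sided p-value
        M, n, N = 60, 30, 30
        probs = hypergeom.pmf(np.arange(0, 31), M, n, N)
        p_obs = hypergeom.pmf(20, M, n, N)
        expected = probs[probs <= p_obs * (1 + 1e-9)].sum()
        assert p == pytest.approx(expected, rel=1e-6)

    def test_zero_cross_products(self):
        assert enr.fisher_enrichment(0, 10, 10, 0)[0] == 0.0
        assert enr.fisher_enrichment(10, 0, 0, 10)[0] == np.inf

    def test_negative_cell_raises(self):
        with pytest.raises(ValueError):
            enr.fisher_enrichment(-1, 2, 3, 4)


class TestMatchedSampling:
    def test_preserves_size_and_decile_histograms(self):
        rng = np.random.default_rng(0)
        background = pd.DataFrame({
            "maf": rng.uniform(0.05, 0.5, 2_000),
            "gene_density": rng.integers(0, 10, 2_000).astype(float),
        })
        observed = background.sample(150, random_state=1)
        drawn = enr.matched_sample(observed, background,
                                   ["maf", "gene_density"],
                                   np.random.default_rng(2))
        assert len(drawn) == len(observed)
        for col in ("maf", "gene_density"):
            ref = background[col].to_numpy()
            obs_bins = enr._decile_bins(observed[col].to_numpy(), ref)
            drawn_bins = enr._decile_bins(drawn[col].to_numpy(), ref)
            h_obs = np.bincount(obs_bins, minlength=10)
            h_drawn = np.bincount(drawn_bins, minlength=10)
            assert np.abs(h_obs - h_drawn).max() <= 1

    def test_snp_background_too_small_raises(self):
        bg = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [1, 2],
                           "maf": [0.1, 0.2]})
        trait = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1, 2, 3],
                              "maf": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="background"):
            enr.sample_matched_snp_nulls(trait, bg, pd.DataFrame(
                columns=["chrom", "start", "end"]))


class TestSnpNulls:
    def test_planted_enrichment_detected(self, small_genome, small_truth):
        from nascenttx import synthetic

        _, snps, _ = synthetic.simulate_ancillary(
            small_genome, small_truth, seed=9, snp_enrichment=5.0,
            n_background_snps=3_000, n_trait_snps=400)
        trait = snps[snps["set"] == "trait"].reset_index(drop=True)
        bg = snps[snps["set"] == "background"].reset_index(drop=True)
        ens = enr.sample_matched_snp_nulls(
            trait, bg, small_genome.truth_enhancers, n_sets=400, seed=0)
        assert ens.observed > np.quantile(ens.null_values, 0.999)
        assert ens.p_value <= 1 / 400

    def test_empty_trait_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            enr.sample_matched_snp_nulls(
                pd.DataFrame(columns=["chrom", "pos", "maf"]),
                pd.DataFrame({"chrom": ["chr1"], "pos": [1], "maf": [0.1]}),
                pd.DataFrame(columns=["chrom", "start", "end"]))

    def test_zero_sets_raises(self):
        snp = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "maf": [0.1]})
        with pytest.raises(ValueError, match="n_sets"):
            enr.sample_matched_snp_nulls(snp, snp, pd.DataFrame(
                columns=["chrom", "start", "end"]), n_sets=0)


class TestRegionOverlap:
    LAYOUT = GenomeLayout((("chr1", 1_000_000),))
    GENES = pd.DataFrame({"chrom": ["chr1"], "start": [400_000],
                          "end": [420_000]})

    def test_reference_equal_query_full_overlap(self):
        q = pd.DataFrame({"chrom": "chr1",
                          "start": [10_000, 50_000], "end": [11_000, 52_000]})
        ens = enr.region_overlap_enrichment(q, q, self.LAYOUT, self.GENES,
                                            n_sets=5, seed=0)
        assert ens.observed == 1.0

    def test_disjoint_chromosomes_zero_overlap(self):
        q = pd.DataFrame({"chrom": ["chr1"], "start": [10_000],
                          "end": [11_000]})
        ref = pd.DataFrame({"chrom": ["chr2"], "start": [10_000],
                            "end": [11_000]})
        ens = enr.region_overlap_enrichment(q, ref, self.LAYOUT, self.GENES,
                                            n_sets=5, seed=0)
        assert ens.observed == 0.0
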