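import hashlib

import numpy as np
import pandas as pd
import pytest

from nascenttx import synthetic


def dataset_hash(genome, truth=None, coverage=None):
    h = hashlib.sha256()
    h.update(genome.genes.genes.to_csv().encode())
    h.update(genome.enhancer_states.to_csv().encode())
    h.update(genome.truth_tus.to_csv().encode())
    if truth is not None:
        h.update(truth.gene_activity.to_csv().encode())
        h.update(truth.enhancer_activity.to_csv().encode())
    if coverage is not None:
        for sample in sorted(coverage):
            for strand in "+-":
                h.update(coverage[sample][strand].concat().tobytes())
    return h.hexdigest()


class TestGenerateGenome:
    def test_requested_feature_counts_and_tss_clearance(self):
        g = synthetic.generate_genome(1, 10_000_000, 100, 150, seed=7)
        assert len(g.genes.genes) == 100
        assert len(g.enhancer_states) == 150
        # the constructor itself asserts >= 1 kbp TSS clearance; re-check
        tss = g.genes.tss()
        for _, s in g.enhancer_states.iterrows():
            assert not any(s["start"] - 1_000 < t < s["end"] + 1_000
                           for t in tss.values)

    def test_same_seed_identical_different_seed_differs(self):
        a = synthetic.generate_genome(1, 10_000_000, 100, 150, seed=7)
        b = synthetic.generate_genome(1, 10_000_000, 100, 150, seed=7)
        c = synthetic.generate_genome(1, 10_000_000, 100, 150, seed=8)
        assert dataset_hash(a) == dataset_hash(b)
        assert dataset_hash(a) != dataset_hash(c)

    def test_placement_failure_names_constraint(self):
        with pytest.raises(ValueError, match="placement failure"):
            synthetic.generate_genome(1, 200_000, 50, 50, seed=0)


class TestGeneratePrograms:
    def test_frac_specific_one_all_one_hot(self, small_genome):
        tr = synthetic.generate_programs(small_genome, 6, 1.0, seed=0)
        assert ((tr.enhancer_activity > 0).sum(axis=1) == 1).all()

    def test_frac_specific_zero_all_ubiquitous(self, small_genome):
        tr = synthetic.generate_programs(small_genome, 6, 0.0, seed=0)
        assert (tr.enhancer_activity > 0).all().all()

    def test_invalid_frac_specific_raises(self, small_genome):
        with pytest.raises(ValueError, match="frac_specific"):
            synthetic.generate_programs(small_genome, 6, 1.5, seed=0)

    def test_coupling_gives_correlated_links(self):
        g = synthetic.generate_genome(2, 12_000_000, 120, 160, seed=3)
        tr = synthetic.generate_programs(g, 14, 0.3, seed=4, coupling=0.9,
                                         link_fraction=1.0)
        assert len(tr.ep_links) >= 100
        rs = []
        for e, gene in tr.ep_links:
            ev = tr.enhancer_activity.loc[e].to_numpy()
            gv = tr.gene_activity.loc[gene].to_numpy()
            if ev.std() > 0 and gv.std() > 0:
                rs.append(np.corrcoef(ev, gv)[0, 1])
        assert np.mean(rs) > 0.6


class TestSimulateCoverage:
    def test_zero_activity_zero_background_all_zero(self, small_genome):
        tr = synthetic.generate_programs(small_genome, 2, 0.0, seed=0,
                                         background_rate=1e-12)
        tr.gene_activity[:] = 0.0
        tr.enhancer_activity[:] = 0.0
        cov = synthetic.simulate_coverage(small_genome, tr, seed=0,
                                          noise="none")
        total = sum(cov[s][st].total() for s in cov for st in "+-")
        assert total == 0

    def test_background_total_within_poisson_ci(self, small_genome):
        tr = synthetic.generate_programs(small_genome, 2, 0.0, seed=0,
                                         background_rate=0.05, dispersion=0.0)
        tr.gene_activity[:] = 0.0
        tr.enhancer_activity[:] = 0.0
        tr.depth_factor[:] = 1.0
        cov = synthetic.simulate_coverage(small_genome, tr, seed=1)
        n_bins = small_genome.layout.total_bins()
        total = cov["CL01_rep1"]["+"].total()
        expected = 0.05 * n_bins
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_depth_doubling_doubles_totals(self, small_genome):
        # replicates share the cell line's rate track; only depth differs
        tr = synthetic.generate_programs(small_genome, 2, 0.0, seed=0,
                                         n_replicates=2)
        tr.depth_factor[:] = [1.0, 2.0, 1.0, 1.0]
        ratios = []
        for seed in range(10):
            cov = synthetic.simulate_coverage(small_genome, tr, seed=seed)
            t1 = sum(cov["CL01_rep1"][s].total() for s in "+-")
            t2 = sum(cov["CL01_rep2"][s].total() for s in "+-")
            ratios.append(t2 / t1)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_marginal_mean_matches_poisson_lognormal(self, small_genome):
        """E[count] = lambda * exp(sigma^2 / 2) for the bin noise model."""
        sigma = 0.5
        tr = synthetic.generate_programs(small_genome, 2, 0.0, seed=0,
                                         n_replicates=1, dispersion=sigma,
                                         background_rate=0.4)
        tr.gene_activity[:] = 0.0
        tr.enhancer_activity[:] = 0.0
        tr.depth_factor[:] = 1.0
        cov = synthetic.simulate_coverage(small_genome, tr, seed=5)
        vals = np.concatenate([cov["CL01_rep1"][s].concat() for s in "+-"])
        expected = 0.4 * np.exp(sigma ** 2 / 2)
        se = np.sqrt(vals.var() / len(vals))
        assert abs(vals.mean() - expected) < 4 * se

    def test_coverage_determinism(self, small_genome, small_truth):
        a = synthetic.simulate_coverage(small_genome, small_truth, seed=2)
        b = synthetic.simulate_coverage(small_genome, small_truth, seed=2)
        assert dataset_hash(small_genome, small_truth, a) == \
            dataset_hash(small_genome, small_truth, b)


class TestSimulateAncillary:
    def test_every_link_has_strong_spanning_interaction(self, small_genome,
                                                        small_truth):
        inter, _, _ = synthetic.simulate_ancillary(small_genome, small_truth,
                                                   seed=0)
        strong = inter[inter["score"] >= 3.0]
        enh = small_genome.truth_enhancers.set_index("enhancer_id")
        tss = small_genome.genes.tss()
        for eid, gid in small_truth.ep_links:
            t = int(tss[gid])
            mid = (int(enh.loc[eid, "start"]) + int(enh.loc[eid, "end"])) // 2
            hit = strong[(strong["bait_start"] <= t)
                         & (strong["bait_end"] > t)
                         & (strong["hit_start"] <= mid)
                         & (strong["hit_end"] > mid)]
            assert len(hit) >= 1

    def test_decoys_below_threshold(self, small_genome, small_truth):
        inter, _, _ = synthetic.simulate_ancillary(small_genome, small_truth,
                                                   seed=0)
        n_links = len(small_truth.ep_links)
        assert (inter["score"] >= 3.0).sum() == n_links
        assert (inter["score"] < 3.0).sum() == 3 * n_links

    def test_unit_enrichment_matches_background_fraction(self, small_genome,
                                                         small_truth):
        from nascenttx.enrichment import snp_enhancer_overlap

        _, snps, _ = synthetic.simulate_ancillary(
            small_genome, small_truth, seed=1, snp_enrichment=1.0,
            n_background_snps=4_000, n_trait_snps=4_000)
        enh = small_genome.truth_enhancers
        frac = {
            name: snp_enhancer_overlap(sub, enh) / len(sub)
            for name, sub in snps.groupby("set")
        }
        assert frac["trait"] == pytest.approx(frac["background"], abs=0.02)

    def test_peak_signal_tracks_activity(self, small_genome, small_truth):
        _, _, peaks = synthetic.simulate_ancillary(small_genome, small_truth,
                                                   seed=0)
        assert (peaks["signal"] > 0).all()
        mean_act = small_truth.enhancer_activity.mean(axis=1)
        r = np.corrcoef(np.log(peaks.set_index("name")["signal"]),
                        np.log(mean_act[peaks["name"]]))[0, 1]
        assert r > 0.2  # heavy tail on top of proportionality


class TestWriteDataset:
    def test_on_disk_round_trip(self, tmp_path, small_genome, small_truth,
                                clean_coverage):
        from nascenttx import genomic_io as gio

        synthetic.write_dataset(str(tmp_path), small_genome, clean_coverage)
        back = gio.read_annotation(str(tmp_path / "genes.gtf"), "gtf")
        assert len(back.genes) == len(small_genome.genes.genes)
        states = gio.read_bed(str(tmp_path / "enhancer_states.bed"))
        assert len(states) == len(small_genome.enhancer_states)
        cov = gio.read_bedgraph(str(tmp_path / "CL01_rep1.plus.bedgraph"),
                                small_genome.layout, "CL01_rep1", "+")
        np.testing.assert_array_equal(
            cov.data["chr1"], clean_coverage["CL01_rep1"]["+"].data["chr1"])
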