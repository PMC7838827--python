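import numpy as np
import pandas as pd
import pytest

from nascenttx import annotation as ann
from nascenttx.genomic_io import GenomeLayout

from conftest import single_gene_annotation


RULES = ann.ClassificationRules()


def tu(tu_id, start, end, strand, chrom="chr1", klass="unclassified",
       **extra):
    return {"tu_id": tu_id, "chrom": chrom, "start": start, "end": end,
            "strand": strand, "klass": klass, **extra}


class TestClassifyTus:
    """Gene on + strand with TSS at 10,000 (span 10,000-22,000)."""

    def setup_method(self):
        self.genes = single_gene_annotation(start=10_000, end=22_000,
                                            strand="+")

    @pytest.mark.parametrize("tss,expected", [
        (9_500, "uaRNA"),    # < 1 kbp upstream of the sense TSS
        (10_600, "conRNA"),  # < 1 kbp downstream
        (12_000, "asRNA"),   # > 1 kbp downstream, overlapping the gene
    ])
    def test_minus_strand_classes_by_tss_offset(self, tss, expected):
        tus = pd.DataFrame([tu("t0", tss - 1_500, tss, "-")])
        out = ann.classify_tus(tus, self.genes, RULES)
        assert out.iloc[0]["klass"] == expected
        assert out.iloc[0]["host_gene"] == "G0001"

    def test_mrna_requires_exon_overlap(self):
        genes = single_gene_annotation(start=10_000, end=22_000, strand="+")
        # restrict exons to the last quarter of the gene
        genes.exons = pd.DataFrame([{
            "gene_id": "G0001", "chrom": "chr1", "start": 19_000,
            "end": 22_000, "strand": "+"}])
        covering_30pct_no_exon = pd.DataFrame(
            [tu("t0", 10_000, 14_000, "+")])
        out = ann.classify_tus(covering_30pct_no_exon, genes, RULES)
        assert out.iloc[0]["klass"] != "mRNA"
        covering_with_exon = pd.DataFrame([tu("t1", 15_000, 22_000, "+")])
        out = ann.classify_tus(covering_with_exon, genes, RULES)
        assert out.iloc[0]["klass"] == "mRNA"

    def test_mrna_requires_quarter_of_gene(self):
        tus = pd.DataFrame([tu("t0", 10_000, 12_000, "+")])  # ~17%
        out = ann.classify_tus(tus, self.genes, RULES)
        assert out.iloc[0]["klass"] != "mRNA"

    def test_far_tu_is_intergenic(self):
        tus = pd.DataFrame([tu("t0", 100_000, 105_000, "+")])
        out = ann.classify_tus(tus, self.genes, RULES)
        assert out.iloc[0]["klass"] == "intergenic"

    def test_labels_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 180_000, 50)
        tus = pd.DataFrame([
            tu(f"t{i}", s, s + 2_000, rng.choice(["+", "-"]))
            for i, s in enumerate(starts)])
        out = ann.classify_tus(tus, self.genes, RULES)
        assert set(out["klass"]) <= {"mRNA", *ann.NC_CLASSES}
        assert out["klass"].notna().all()


class TestCallErnas:
    def setup_method(self):
        self.genes = single_gene_annotation(start=50_000, end=62_000,
                                            strand="+")
        self.states = pd.DataFrame([
            {"chrom": "chr1", "start": 10_000, "end": 11_000,
             "name": "state1"}])

    def _nc(self, tss, strand="+", length=1_500, klass="intergenic"):
        start = tss if strand == "+" else tss - length
        end = tss + length if strand == "+" else tss
        return pd.DataFrame([tu("t0", start, end, strand, klass=klass,
                                host_gene=None)])

    def test_tss_within_window_is_erna(self):
        # TSS 400 bp left of the state edge
        out = ann.call_ernas(self._nc(9_600), self.states, self.genes, RULES)
        assert len(out) == 1 and out.iloc[0]["erna_kind"] == "intergenic"

    def test_tss_outside_window_rejected(self):
        out = ann.call_ernas(self._nc(9_400), self.states, self.genes, RULES)
        assert out.empty

    def test_small_rna_overlap_excluded(self):
        small = pd.DataFrame([{"chrom": "chr1", "start": 9_800,
                               "end": 10_200}])
        out = ann.call_ernas(self._nc(9_600), self.states, self.genes, RULES,
                             small_rna=small)
        assert out.empty

    def test_promoter_proximal_tss_excluded(self):
        states = pd.DataFrame([{"chrom": "chr1", "start": 50_500,
                                "end": 52_000, "name": "s"}])
        out = ann.call_ernas(self._nc(50_800, klass="intergenic"),
                             states, self.genes, RULES)
        assert out.empty

    def test_long_antisense_erna_truncated_at_promoter(self):
        # host gene + strand, TSS 50,000; antisense eRNA on '-' runs from
        # 55,000 back across the promoter
        states = pd.DataFrame([{"chrom": "chr1", "start": 54_000,
                                "end": 56_000, "name": "s"}])
        nc = pd.DataFrame([tu("t0", 48_000, 55_000, "-", klass="asRNA",
                              host_gene="G0001")])
        out = ann.call_ernas(nc, states, self.genes, RULES)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 51_000  # ends 1 kbp downstream of TSS


class TestFilterAntisense:
    def _setup(self, erna_fpk, end_fpk):
        tus = pd.DataFrame([
            tu("head", 0, 20_000, "+", klass="mRNA"),
            tu("as1", 22_000, 24_000, "+", klass="asRNA"),
        ])
        ernas = pd.DataFrame([
            {**tu("as1", 22_000, 24_000, "+", klass="asRNA"),
             "erna_kind": "antisense"}])
        fpk = pd.Series({"head": 100.0, "as1": erna_fpk})
        return ernas, tus, fpk, lambda head: end_fpk

    def test_below_twofold_dropped(self):
        ernas, tus, fpk, fn = self._setup(40.0, 25.0)
        assert ann.filter_antisense(ernas, tus, fpk, fn, RULES).empty

    def test_above_twofold_kept(self):
        ernas, tus, fpk, fn = self._setup(60.0, 25.0)
        assert len(ann.filter_antisense(ernas, tus, fpk, fn, RULES)) == 1

    def test_no_upstream_chain_kept_unconditionally(self):
        ernas, tus, fpk, fn = self._setup(1.0, 1000.0)
        # push the eRNA beyond the 5-kbp chain gap
        tus.loc[1, ["start", "end"]] = [26_000, 28_000]
        ernas.loc[0, ["start", "end"]] = [26_000, 28_000]
        assert len(ann.filter_antisense(ernas, tus, fpk, fn, RULES)) == 1


class TestPairBidirectional:
    def _erna(self, start, end, strand, tid="e0"):
        return {**tu(tid, start, end, strand, klass="intergenic",
                     host_gene=None), "erna_kind": "intergenic"}

    def _partner(self, start, end, strand, tid="p0"):
        return tu(tid, start, end, strand, klass="intergenic",
                  host_gene=None)

    def test_gap_750_paired_inclusive(self):
        ernas = pd.DataFrame([self._erna(10_750, 12_000, "+")])
        nc = pd.DataFrame([self._partner(8_000, 10_000, "-"),
                           self._erna(10_750, 12_000, "+")])
        out = ann.pair_bidirectional(ernas, nc, RULES)
        assert len(out) == 1 and out.iloc[0]["gap"] == 750

    def test_gap_800_unpaired(self):
        ernas = pd.DataFrame([self._erna(10_800, 12_000, "+")])
        nc = pd.DataFrame([self._partner(8_000, 10_000, "-")])
        assert ann.pair_bidirectional(ernas, nc, RULES).empty

    def test_convergent_not_paired(self):
        # plus TU transcribing right into a downstream minus TU: TSSs at
        # the outer edges, any gap
        ernas = pd.DataFrame([self._erna(10_000, 14_000, "+")])
        nc = pd.DataFrame([self._partner(14_200, 18_000, "-")])
        assert ann.pair_bidirectional(ernas, nc, RULES).empty

    def test_overlapping_divergent_allowed(self):
        ernas = pd.DataFrame([self._erna(9_800, 12_000, "+")])
        nc = pd.DataFrame([self._partner(8_000, 10_000, "-")])
        out = ann.pair_bidirectional(ernas, nc, RULES)
        assert len(out) == 1 and out.iloc[0]["gap"] == -200

    def test_nearest_tss_wins(self):
        ernas = pd.DataFrame([self._erna(10_400, 12_000, "+")])
        nc = pd.DataFrame([self._partner(8_000, 10_000, "-", "far"),
                           self._partner(8_000, 10_200, "-", "near")])
        out = ann.pair_bidirectional(ernas, nc, RULES)
        assert out.iloc[0]["minus_id"] == "near"


class TestDefineEnhancers:
    LAYOUT = GenomeLayout((("chr1", 2_000_000),))

    def test_intergenic_region_from_divergent_tsss(self):
        pairs = pd.DataFrame([{"chrom": "chr1", "plus_id": "p", "minus_id": "m",
                               "tss_plus": 5_400, "tss_minus": 5_000,
                               "gap": 400, "erna_id": "p"}])
        out = ann.define_enhancers(pairs, pd.DataFrame(columns=["erna_kind"]),
                                   self.LAYOUT, RULES)
        r = out.iloc[0]
        assert (r["start"], r["end"]) == (4_500, 5_900)
        assert r["end"] - r["start"] == 1_400  # gap 400 + 2 x 500

    def test_intragenic_region_minus_strand(self):
        ernas = pd.DataFrame([{**tu("e0", 28_000, 30_000, "-",
                                    klass="asRNA", host_gene="G"),
                               "erna_kind": "antisense"}])
        out = ann.define_enhancers(pd.DataFrame(columns=[
            "chrom", "plus_id", "minus_id", "tss_plus", "tss_minus", "gap",
            "erna_id"]), ernas, self.LAYOUT, RULES)
        r = out.iloc[0]
        assert (r["start"], r["end"]) == (29_500, 30_750)

    def test_intragenic_width_always_1250(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            s = int(rng.integers(10_000, 1_500_000))
            strand = rng.choice(["+", "-"])
            rows.append({**tu(f"e{i}", s, s + 2_000, strand, klass="asRNA",
                              host_gene="G"), "erna_kind": "antisense"})
        out = ann.define_enhancers(pd.DataFrame(columns=[
            "chrom", "plus_id", "minus_id", "tss_plus", "tss_minus", "gap",
            "erna_id"]), pd.DataFrame(rows), self.LAYOUT, RULES)
        assert ((out["end"] - out["start"]) == 1_250).all()

    def test_out_of_bounds_region_clipped_with_warning(self):
        ernas = pd.DataFrame([{**tu("e0", 0, 300, "-", klass="asRNA",
                                    host_gene="G"),
                               "erna_kind": "antisense"}])
        with pytest.warns(UserWarning, match="clipped"):
            out = ann.define_enhancers(pd.DataFrame(columns=[
                "chrom", "plus_id", "minus_id", "tss_plus", "tss_minus",
                "gap", "erna_id"]), ernas, self.LAYOUT, RULES)
        assert out.iloc[0]["start"] == 0


class TestMergeAcrossCellLines:
    def _enh(self, start, end, kind="intergenic"):
        return pd.DataFrame([{"enhancer_id": "e", "chrom": "chr1",
                              "start": start, "end": end, "kind": kind,
                              "strand": ".", "constituents": "x"}])

    def test_identical_regions_merge_with_two_sources(self):
        out = ann.merge_across_cell_lines(
            {"A": self._enh(1_000, 2_000), "B": self._enh(1_000, 2_000)})
        assert len(out) == 1
        assert set(out.iloc[0]["sources"].split(",")) == {"A", "B"}

    def test_disjoint_regions_preserved(self):
        out = ann.merge_across_cell_lines(
            {"A": self._enh(1_000, 2_000), "B": self._enh(5_000, 6_000)})
        assert len(out) == 2

    def test_transitive_chain_merges(self):
        out = ann.merge_across_cell_lines(
            {"A": self._enh(1_000, 2_000), "B": self._enh(1_800, 2_600),
             "C": self._enh(2_500, 3_000)})
        assert len(out) == 1
        assert out.iloc[0]["end"] == 3_000


class TestQuantifyEnhancers:
    def test_effective_lengths(self):
        regions = pd.DataFrame([
            {"enhancer_id": "i1", "chrom": "chr1", "start": 0, "end": 1_250,
             "kind": "intragenic", "strand": "-"},
            {"enhancer_id": "i2", "chrom": "chr1", "start": 0, "end": 2_000,
             "kind": "intergenic", "strand": "."},
        ])
        eff = ann.effective_lengths(regions, RULES)
        assert eff["i1"] == 500 and eff["i2"] == 2_000

    def test_fpk_hand_examples(self):
        from conftest import coverage_from_arrays
        # intragenic on '-' strand: 10 antisense counts over eff. 500 bp
        minus = np.zeros(50, dtype=int)
        minus[0:6] = [2, 2, 2, 2, 1, 1]
        plus = np.zeros(50, dtype=int)
        plus[0:10] = [2, 2, 2, 1, 1, 1, 2, 1, 2, 1]  # 15 counts
        cov = {"s1": coverage_from_arrays(plus, minus)}
        regions = pd.DataFrame([
            {"enhancer_id": "i1", "chrom": "chr1", "start": 0, "end": 1_250,
             "kind": "intragenic", "strand": "-"},
            {"enhancer_id": "i2", "chrom": "chr1", "start": 0, "end": 2_000,
             "kind": "intergenic", "strand": "."},
        ])
        factors = pd.Series({"s1": 1.0})
        out = ann.quantify_enhancers(regions, cov, factors, RULES)
        # intragenic: 10 antisense counts within the first 6 bins of 1,250 bp
        assert out.loc["i1", "s1"] == pytest.approx(10 / 0.5)
        # intergenic: both strands over 2,000 bp -> (15 + 10) / 2
        assert out.loc["i2", "s1"] == pytest.approx((15 + 10) / 2.0)
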