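"""TU classification, eRNA calling, and putative enhancer construction.

Non-coding transcription units are classified by their position relative to
protein-coding genes (uaRNA / conRNA / asRNA / intergenic), intersected with
chromatin-state enhancer intervals to call eRNAs, filtered against
readthrough artifacts, and finally condensed into putative enhancer regions:
divergent intergenic eRNA pairs span the region between their TSSs extended
by 500 bp on each side, while a single antisense (intragenic) eRNA defines a
fixed 1,250-bp region from 750 bp upstream to 500 bp downstream of its TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import normalization
from .genomic_io import (BinnedCoverage, GeneAnnotation, GenomeLayout,
                         count_fragments, merge_intervals)
from .segmentation import tu_tss

NC_CLASSES = ("uaRNA", "conRNA", "asRNA", "intergenic")


@dataclass(frozen=True)
class ClassificationRules:
    """All interval constants of the TU/eRNA/enhancer classification."""

    promoter_radius: int = 1_000         # TSS exclusion zone around coding TSSs
    asrna_downstream: int = 1_000        # asRNA: TSS > this far downstream
    mrna_overlap_fraction: float = 0.25  # min fraction of gene covered for mRNA
    state_window: int = 500              # eRNA TSS +/- window vs enhancer state
    bidirectional_gap: int = 750         # max divergent TSS gap, inclusive
    antisense_merge_gap: int = 5_000     # readthrough chain gap, strict <
    antisense_fold: float = 2.0          # eRNA FPK vs upstream-end FPK
    upstream_end_window: int = 1_000     # "end" of the upstream mRNA/uaRNA
    enhancer_flank: int = 500            # extension of intergenic regions
    intragenic_upstream: int = 750       # intragenic region upstream of TSS

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"rule {name} must be positive")


def _tree(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for _, r in df.iterrows():
        trees.setdefault(r["chrom"], IntervalTree()).addi(
            int(r["start"]), int(r["end"]), r.to_dict())
    return trees


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_tus(tus: pd.DataFrame, genes: GeneAnnotation,
                 rules: ClassificationRules = ClassificationRules()) -> pd.DataFrame:
    """Label each TU as mRNA / uaRNA / conRNA / asRNA / intergenic.

    A TU is an mRNA iff it covers at least ``mrna_overlap_fraction`` of a
    same-strand protein-coding gene and touches one of its exons.  Remaining
    TUs are classified against opposite-strand protein-coding genes by the
    strand-aware offset of their TSS from the gene TSS (nearest gene wins):
    within 1 kbp upstream -> uaRNA, within 1 kbp downstream -> conRNA,
    further downstream while overlapping the gene -> asRNA; everything else
    is intergenic.  The assigned gene is recorded as ``host_gene``.
    """
    coding = genes.genes[genes.genes["biotype"] == "protein_coding"]
    gene_trees = _tree(coding)
    exon_trees = _tree(genes.exons[genes.exons["gene_id"].isin(coding["gene_id"])])
    gene_tss = genes.tss()

    out = tus.copy()
    tss = tu_tss(out)
    klasses, hosts = [], []
    for idx, r in out.iterrows():
        chrom, start, end, strand = r["chrom"], int(r["start"]), int(r["end"]), r["strand"]
        hits = gene_trees.get(chrom, IntervalTree()).overlap(start, end)
        klass, host = None, None
        # --- mRNA: same-strand gene, >= fraction covered, exon touched
        for hit in hits:
            g = hit.data
            if g["strand"] != strand:
                continue
            ov = min(end, g["end"]) - max(start, g["start"])
            if ov < rules.mrna_overlap_fraction * (g["end"] - g["start"]):
                continue
            exon_hit = any(
                e.data["gene_id"] == g["gene_id"]
                for e in exon_trees.get(chrom, IntervalTree()).overlap(start, end)
            )
            if exon_hit:
                klass, host = "mRNA", g["gene_id"]
                break
        if klass is None:
            t = int(tss[idx])
            best = None
            for hit in hits | gene_trees.get(chrom, IntervalTree()).overlap(
                    t - rules.promoter_radius, t + rules.promoter_radius):
                g = hit.data
                if g["strand"] == strand:
                    continue
                g_tss = int(gene_tss[g["gene_id"]])
                d = t - g_tss if g["strand"] == "+" else g_tss - t
                overlaps = min(end, g["end"]) > max(start, g["start"])
                if best is None or abs(d) < abs(best[0]):
                    best = (d, g["gene_id"], overlaps)
            if best is not None:
                d, gid, overlaps = best
                if -rules.promoter_radius < d < 0:
                    klass, host = "uaRNA", gid
                elif 0 <= d < rules.asrna_downstream:
                    klass, host = "conRNA", gid
                elif d >= rules.asrna_downstream and overlaps:
                    klass, host = "asRNA", gid
        klasses.append(klass or "intergenic")
        hosts.append(host)
    out["klass"] = klasses
    out["host_gene"] = hosts
    return out


# ---------------------------------------------------------------------------
# eRNA calling
# ---------------------------------------------------------------------------

def call_ernas(nc_tus: pd.DataFrame, enhancer_states: pd.DataFrame,
               genes: GeneAnnotation,
               rules: ClassificationRules = ClassificationRules(),
               small_rna: pd.DataFrame | None = None,
               lncrna_exclusion: pd.DataFrame | None = None) -> pd.DataFrame:
    """eRNAs = asRNA/intergenic TUs whose TSS +/- 500 bp hits an enhancer state.

    TUs overlapping annotated small RNAs or the functional-lncRNA exclusion
    list are dropped, as are TUs whose TSS lies within the promoter exclusion
    zone of a protein-coding TSS.  Long antisense eRNAs running across their
    host gene's promoter are truncated to end 1 kbp downstream of the coding
    TSS.  Adds an ``erna_kind`` column ('intergenic' or 'antisense').
    """
    cand = nc_tus[nc_tus["klass"].isin(["asRNA", "intergenic"])].copy()
    state_trees = _tree(enhancer_states)
    coding = genes.genes[genes.genes["biotype"] == "protein_coding"]
    coding_tss = {
        r["gene_id"]: (int(r["start"]) if r["strand"] == "+" else int(r["end"]))
        for _, r in coding.iterrows()
    }
    tss_by_chrom: dict[str, list[int]] = {}
    for _, r in coding.iterrows():
        tss_by_chrom.setdefault(r["chrom"], []).append(coding_tss[r["gene_id"]])
    exclusion_trees = {}
    for df in (small_rna, lncrna_exclusion):
        if df is not None and not df.empty:
            for chrom, tree in _tree(df).items():
                exclusion_trees.setdefault(chrom, IntervalTree()).update(tree)

    keep_rows = []
    tss = tu_tss(cand)
    for idx, r in cand.iterrows():
        chrom, t = r["chrom"], int(tss[idx])
        near_state = bool(state_trees.get(chrom, IntervalTree()).overlap(
            t - rules.state_window, t + rules.state_window + 1))
        if not near_state:
            continue
        near_promoter = any(
            abs(t - g) <= rules.promoter_radius
            for g in tss_by_chrom.get(chrom, [])
        )
        if near_promoter:
            continue
        if exclusion_trees.get(chrom, IntervalTree()).overlap(
                int(r["start"]), int(r["end"])):
            continue
        row = r.copy()
        row["erna_kind"] = "antisense" if r["klass"] == "asRNA" else "intergenic"
        # truncate antisense eRNAs that run over the host promoter
        if row["erna_kind"] == "antisense" and row["host_gene"] in coding_tss:
            g_tss = coding_tss[row["host_gene"]]
            host_strand = "+" if r["strand"] == "-" else "-"
            promoter_lo = g_tss - rules.promoter_radius
            promoter_hi = g_tss + rules.promoter_radius
            if int(r["start"]) < promoter_hi and int(r["end"]) > promoter_lo:
                if host_strand == "+":   # eRNA on '-', 3' end = start
                    row["start"] = max(int(row["start"]), g_tss + rules.promoter_radius)
                else:                     # eRNA on '+', 3' end = end
                    row["end"] = min(int(row["end"]), g_tss - rules.promoter_radius)
        keep_rows.append(row)
    cols = list(nc_tus.columns) + ["erna_kind"]
    return pd.DataFrame(keep_rows, columns=cols).reset_index(drop=True)


def filter_antisense(ernas: pd.DataFrame, tus: pd.DataFrame,
                     tu_fpk: pd.Series,
                     end_fpk_fn,
                     rules: ClassificationRules = ClassificationRules()) -> pd.DataFrame:
    """Drop antisense eRNAs that look like readthrough of an upstream TU.

    Walking each strand in the direction of transcription, non-coding TUs
    are absorbed into a chain behind the nearest upstream mRNA/uaRNA while
    successive gaps stay below ``antisense_merge_gap``.  An antisense eRNA
    inside such a chain is kept only if its FPK is at least
    ``antisense_fold`` times the FPK over the final ``upstream_end_window``
    bp of the chain's head TU.  ``tu_fpk`` maps tu_id -> FPK;
    ``end_fpk_fn(head_row)`` returns the FPK of the head TU's 3' end window.
    """
    absorbed_by: dict[str, pd.Series] = {}
    for (chrom, strand), sub in tus.groupby(["chrom", "strand"]):
        forward = strand == "+"
        sub = sub.sort_values("start", ascending=forward)
        head = None
        chain_end = None
        for _, r in sub.iterrows():
            is_head_class = r["klass"] in ("mRNA", "uaRNA")
            if is_head_class:
                head = r
                chain_end = r["end"] if forward else r["start"]
                continue
            if head is None:
                continue
            gap = (r["start"] - chain_end) if forward else (chain_end - r["end"])
            if gap < rules.antisense_merge_gap:
                absorbed_by[r["tu_id"]] = head
                chain_end = max(chain_end, r["end"]) if forward else min(chain_end, r["start"])
            else:
                head = None
    keep = []
    for _, e in ernas.iterrows():
        if e["erna_kind"] != "antisense" or e["tu_id"] not in absorbed_by:
            keep.append(True)
            continue
        head = absorbed_by[e["tu_id"]]
        upstream_end_fpk = float(end_fpk_fn(head))
        keep.append(float(tu_fpk[e["tu_id"]]) >= rules.antisense_fold * upstream_end_fpk)
    return ernas[np.array(keep, dtype=bool)].reset_index(drop=True)


def pair_bidirectional(intergenic_ernas: pd.DataFrame, nc_tus: pd.DataFrame,
                       rules: ClassificationRules = ClassificationRules()) -> pd.DataFrame:
    """Pair intergenic eRNAs with a divergent opposite-strand partner.

    The partner is any non-coding TU (not required to pass the expression
    threshold) forming a divergent configuration: the minus-strand member
    extends at least as far left and the plus-strand member at least as far
    right, with a TSS gap of at most ``bidirectional_gap`` bp (overlap
    allowed, gap counted negative).  The nearest TSS wins; ties go to the
    leftmost partner.  Returns one row per divergent pair.
    """
    partners = nc_tus[nc_tus["klass"] != "mRNA"]
    rows = []
    p_tss_all = tu_tss(partners)
    for _, e in intergenic_ernas[intergenic_ernas["erna_kind"] == "intergenic"].iterrows():
        e_tss = int(e["start"]) if e["strand"] == "+" else int(e["end"])
        cands = partners[(partners["chrom"] == e["chrom"]) &
                         (partners["strand"] != e["strand"]) &
                         (partners["tu_id"] != e["tu_id"])]
        best = None
        for pidx, p in cands.iterrows():
            if e["strand"] == "+":
                plus, minus = e, p
                plus_tss, minus_tss = e_tss, int(p_tss_all[pidx])
            else:
                plus, minus = p, e
                plus_tss, minus_tss = int(p_tss_all[pidx]), e_tss
            gap = plus_tss - minus_tss
            divergent = (
                gap <= rules.bidirectional_gap
                and int(minus["start"]) <= int(plus["start"])
                and int(plus["end"]) >= int(minus["end"])
            )
            if not divergent:
                continue
            key = (abs(gap), int(p["start"]))
            if best is None or key < best[0]:
                best = (key, plus, minus, plus_tss, minus_tss, gap)
        if best is not None:
            _, plus, minus, plus_tss, minus_tss, gap = best
            rows.append({
                "chrom": e["chrom"],
                "plus_id": plus["tu_id"], "minus_id": minus["tu_id"],
                "tss_plus": plus_tss, "tss_minus": minus_tss, "gap": gap,
                "erna_id": e["tu_id"],
            })
    df = pd.DataFrame(rows, columns=["chrom", "plus_id", "minus_id",
                                     "tss_plus", "tss_minus", "gap", "erna_id"])
    return df.drop_duplicates(subset=["plus_id", "minus_id"]).reset_index(drop=True)


def define_enhancers(pairs: pd.DataFrame, antisense_ernas: pd.DataFrame,
                     layout: GenomeLayout,
                     rules: ClassificationRules = ClassificationRules(),
                     cell_line: str = "NA") -> pd.DataFrame:
    """Construct putative enhancer regions from eRNA anchors.

    Intergenic: the span between the two divergent TSSs extended by
    ``enhancer_flank`` on both sides.  Intragenic: 750 bp upstream to 500 bp
    downstream of the antisense eRNA TSS (strand-aware), hence always
    1,250 bp wide.  Regions are clipped to chromosome bounds with a warning.
    """
    lengths = layout.lengths
    rows = []
    for _, p in pairs.iterrows():
        lo = min(p["tss_plus"], p["tss_minus"]) - rules.enhancer_flank
        hi = max(p["tss_plus"], p["tss_minus"]) + rules.enhancer_flank
        rows.append({
            "chrom": p["chrom"], "start": int(lo), "end": int(hi),
            "kind": "intergenic", "strand": ".",
            "constituents": f"{p['plus_id']},{p['minus_id']}",
        })
    for _, e in antisense_ernas[antisense_ernas["erna_kind"] == "antisense"].iterrows():
        if e["strand"] == "-":
            t = int(e["end"])
            lo, hi = t - rules.enhancer_flank, t + rules.intragenic_upstream
        else:
            t = int(e["start"])
            lo, hi = t - rules.intragenic_upstream, t + rules.enhancer_flank
        rows.append({
            "chrom": e["chrom"], "start": lo, "end": hi,
            "kind": "intragenic", "strand": e["strand"],
            "constituents": e["tu_id"],
        })
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "kind",
                                     "strand", "constituents"])
    for idx, r in df.iterrows():
        hi = lengths[r["chrom"]]
        if r["start"] < 0 or r["end"] > hi:
            warnings.warn(
                f"enhancer region clipped to chromosome bounds on {r['chrom']}",
                stacklevel=2)
            df.at[idx, "start"] = max(int(r["start"]), 0)
            df.at[idx, "end"] = min(int(r["end"]), hi)
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df.insert(0, "enhancer_id", [f"ENH_{cell_line}_{i:05d}" for i in range(len(df))])
    df["source"] = cell_line
    return df


def merge_across_cell_lines(per_line: dict[str, pd.DataFrame],
                            stranded: bool = False) -> pd.DataFrame:
    """Union annotation over cell lines: overlapping records are collapsed.

    Provenance (contributing cell lines) is kept in a ``sources`` column.
    For enhancer tables the merged ``kind`` is 'intergenic' as soon as any
    constituent was intergenic (both-strand counting then applies).
    """
    frames = []
    for line, df in per_line.items():
        d = df.copy()
        d["source"] = line
        frames.append(d)
    allrec = pd.concat(frames, ignore_index=True)
    if allrec.empty:
        out = allrec.loc[:, ["chrom", "start", "end"]].copy()
        out["sources"] = pd.Series(dtype=str)
        return out
    group_cols = ["strand"] if stranded and "strand" in allrec else []
    pieces = []
    if group_cols:
        for strand, sub in allrec.groupby("strand"):
            m = _merge_with_kind(sub)
            m["strand"] = strand
            pieces.append(m)
    else:
        pieces.append(_merge_with_kind(allrec))
    out = pd.concat(pieces, ignore_index=True).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    out.insert(0, "enhancer_id", [f"MERGED_{i:05d}" for i in range(len(out))])
    return out


def _merge_with_kind(df: pd.DataFrame) -> pd.DataFrame:
    merged = merge_intervals(df, keep_sources=True)
    if "kind" not in df.columns:
        return merged
    kinds, strands = [], []
    trees = _tree(df)
    for _, r in merged.iterrows():
        hits = trees.get(r["chrom"], IntervalTree()).overlap(r["start"], r["end"])
        hit_kinds = {h.data["kind"] for h in hits}
        hit_strands = {h.data.get("strand", ".") for h in hits}
        kinds.append("intergenic" if "intergenic" in hit_kinds else "intragenic")
        strands.append(hit_strands.pop() if len(hit_strands) == 1 else ".")
    merged["kind"] = kinds
    merged["strand"] = strands
    return merged


def effective_lengths(regions: pd.DataFrame,
                      rules: ClassificationRules = ClassificationRules()) -> pd.Series:
    """Region length, minus 750 bp for intragenic enhancer regions."""
    width = regions["end"] - regions["start"]
    eff = np.where(regions["kind"] == "intragenic",
                   width - rules.intragenic_upstream, width)
    if np.any(eff <= 0):
        raise ValueError("non-positive effective enhancer length")
    index = regions["enhancer_id"] if "enhancer_id" in regions else regions.index
    return pd.Series(eff, index=index, name="effective_length")


def quantify_enhancers(regions: pd.DataFrame,
                       coverage_by_sample: dict[str, dict[str, BinnedCoverage]],
                       factors: pd.Series,
                       rules: ClassificationRules = ClassificationRules()) -> pd.DataFrame:
    """Per-sample enhancer FPK.

    Intragenic regions count only the antisense strand of the host gene
    (i.e. the eRNA strand, carried in the region's ``strand`` column) with
    effective length width - 750 bp; intergenic regions sum both strands
    over the full width.
    """
    ids = regions["enhancer_id"]
    counts = {}
    for sample, cov in coverage_by_sample.items():
        vals = np.zeros(len(regions))
        inter = regions["kind"] == "intergenic"
        if inter.any():
            vals[inter.to_numpy()] = count_fragments(
                regions[inter], cov, strand_rule="both")
        intra = ~inter
        if intra.any():
            vals[intra.to_numpy()] = count_fragments(
                regions[intra], cov, strand_rule="sense")
        counts[sample] = vals
    count_df = pd.DataFrame(counts, index=ids)
    eff = effective_lengths(regions, rules)
    eff.index = ids
    return normalization.fpk(count_df, factors, eff)
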