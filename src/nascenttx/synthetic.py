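"""Synthetic nascent-transcription data with known ground truth.

Generates a toy genome (genes, chromatin-state enhancer intervals), a
transcription program (per-cell-line activities, planted enhancer-promoter
links), strand-specific 200-bp-binned coverage with Poisson-log-normal
noise, and ancillary data (chromatin-interaction fragments, trait/background
SNP catalogs, co-activator peak signal), so that every stage of the analysis
can be exercised and checked against the planted truth.

The emulated study design is 14 cell lines x 2 replicates.  Per-bin counts
are drawn ``Poisson(lambda * exp(sigma * Z))`` with ``Z ~ N(0, 1)``, where
``lambda`` is depth factor x local synthesis rate; gene bodies carry sense
signal, a 1-kbp window from 150 to 1,150 bp upstream of each active TSS
carries antisense (uaRNA) signal, intergenic enhancers carry divergent
signal on both strands, and intragenic enhancers carry antisense signal
inside their host gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ClassificationRules
from .genomic_io import (BinnedCoverage, GeneAnnotation, GenomeLayout,
                         bin_index_range, empty_coverage)

BIN = 200


@dataclass
class SyntheticGenome:
    """Toy genome: layout, gene models, enhancer-state intervals and the
    planted transcribed features they imply."""

    layout: GenomeLayout
    genes: GeneAnnotation
    enhancer_states: pd.DataFrame        # BED-like chrom/start/end/name
    truth_tus: pd.DataFrame              # planted transcribed intervals
    truth_enhancers: pd.DataFrame        # planted enhancer regions


@dataclass
class TruthProgram:
    """Ground-truth synthesis program across cell lines and samples."""

    gene_activity: pd.DataFrame          # genes x cell lines, >= 0
    enhancer_activity: pd.DataFrame      # enhancers x cell lines, >= 0
    ua_fraction: pd.Series               # per gene, in (0, 1]
    ep_links: set[tuple[str, str]] = field(default_factory=set)
    depth_factor: pd.Series = None       # per sample, > 0
    sample_to_line: dict[str, str] = field(default_factory=dict)
    dispersion: float = 0.3              # log-normal sigma of bin noise
    background_rate: float = 0.05        # counts per bin off features
    gene_rate: float = 10.0              # per-bin rate at activity 1
    erna_rate: float = 5.0

    def __post_init__(self):
        if (self.gene_activity < 0).any().any() or \
           (self.enhancer_activity < 0).any().any():
            raise ValueError("activities must be non-negative")
        if self.depth_factor is not None and (self.depth_factor <= 0).any():
            raise ValueError("depth factors must be positive")
        genes = set(self.gene_activity.index)
        enh = set(self.enhancer_activity.index)
        for e, g in self.ep_links:
            if e not in enh or g not in genes:
                raise ValueError(f"ep_link ({e}, {g}) references unknown ids")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.gene_activity.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.depth_factor.index)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _spread(rng: np.random.Generator, footprints: list[int], length: int,
            margin: int, what: str) -> list[int]:
    """Non-overlapping random placement of footprints along one chromosome.

    Footprints are inflated by ``margin`` on both sides, shuffled free space
    is distributed between them, and start positions (of the un-inflated
    feature) are returned bin-aligned.  Raises when the features cannot fit.
    """
    inflated = [f + 2 * margin for f in footprints]
    free = length - sum(inflated)
    if free < 0:
        raise ValueError(
            f"placement failure for {what}: total footprint "
            f"{sum(inflated):,} bp (incl. {margin} bp spacing) exceeds "
            f"chromosome length {length:,} bp")
    cuts = np.sort(rng.random(len(footprints))) * free
    gaps = np.diff(np.concatenate([[0.0], cuts]))
    starts = []
    pos = 0.0
    for f_inf, gap in zip(inflated, gaps):
        pos += gap
        start = (int(pos) + margin) // BIN * BIN
        starts.append(start)
        pos += f_inf
    return starts


def generate_genome(n_chrom: int = 1, chrom_length_bp: int = 10_000_000,
                    n_genes: int = 100, n_enhancer_states: int = 150,
                    seed: int = 0, *,
                    intragenic_fraction: float = 0.25,
                    gene_length_range: tuple[int, int] = (6_000, 14_000),
                    erna_length_range: tuple[int, int] = (1_200, 2_800),
                    margin: int = 3_000) -> SyntheticGenome:
    """Generate a toy genome with genes and enhancer-state intervals.

    Enhancer states are intergenic (hosting a divergent eRNA pair) or
    intragenic (hosting an antisense eRNA inside a gene body); every state
    keeps at least 1 kbp distance from any protein-coding TSS.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if chrom_length_bp % BIN:
        raise ValueError("chromosome length must be a multiple of the bin width")
    chroms = [(f"chr{i + 1}", chrom_length_bp) for i in range(n_chrom)]
    layout = GenomeLayout(tuple(chroms), bin_width=BIN)

    n_intra = int(round(n_enhancer_states * intragenic_fraction))
    n_inter = n_enhancer_states - n_intra

    # one joint placement list per chromosome: genes + intergenic sites
    glo, ghi = gene_length_range
    gene_lengths = (rng.integers(glo // BIN, ghi // BIN + 1, n_genes) * BIN)
    elo, ehi = erna_length_range
    rules = ClassificationRules()

    inter_specs = []
    for _ in range(n_inter):
        gap = int(rng.choice([0, 200, 400, 600]))
        lp = int(rng.integers(elo // BIN, ehi // BIN + 1) * BIN)
        lm = int(rng.integers(elo // BIN, ehi // BIN + 1) * BIN)
        inter_specs.append((gap, lp, lm))

    items = ([("gene", i, int(gene_lengths[i])) for i in range(n_genes)]
             + [("inter", j, inter_specs[j][1] + inter_specs[j][2]
                 + inter_specs[j][0] + 800) for j in range(n_inter)])
    rng.shuffle(items)
    per_chrom: dict[str, list] = {c: [] for c, _ in chroms}
    for k, item in enumerate(items):
        per_chrom[chroms[k % n_chrom][0]].append(item)

    genes_rows, exon_rows, state_rows = [], [], []
    tu_rows, enh_rows = [], []
    for chrom, length in chroms:
        chrom_items = per_chrom[chrom]
        starts = _spread(rng, [it[2] for it in chrom_items], length, margin,
                         "genes and intergenic enhancer sites")
        for (kind, idx, footprint), start in zip(chrom_items, starts):
            if kind == "gene":
                _emit_gene(rng, chrom, start, footprint, idx,
                           genes_rows, exon_rows, tu_rows)
            else:
                _emit_intergenic_site(chrom, start, inter_specs[idx], idx,
                                      rules, state_rows, tu_rows, enh_rows)

    _emit_intragenic_sites(rng, genes_rows, n_intra, n_inter, elo, ehi,
                           rules, state_rows, tu_rows, enh_rows)

    genes = GeneAnnotation(
        pd.DataFrame(genes_rows, columns=["gene_id", "chrom", "start", "end",
                                          "strand", "biotype"]),
        pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end",
                                         "strand"]),
    )
    states = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "name"])
    states["score"] = 0
    states["strand"] = "."
    truth_tus = pd.DataFrame(tu_rows, columns=["tu_id", "chrom", "start", "end",
                                               "strand", "kind", "parent"])
    truth_enh = pd.DataFrame(enh_rows, columns=["enhancer_id", "chrom", "start",
                                                "end", "kind", "strand",
                                                "constituents"])
    _check_state_distance(states, genes)
    return SyntheticGenome(layout, genes, states,
                           truth_tus.sort_values(["chrom", "start"]).reset_index(drop=True),
                           truth_enh.sort_values(["chrom", "start"]).reset_index(drop=True))


def _emit_gene(rng, chrom, start, length, idx, genes_rows, exon_rows, tu_rows):
    strand = "+" if rng.random() < 0.5 else "-"
    gid = f"G{idx:04d}"
    end = start + length
    genes_rows.append((gid, chrom, start, end, strand, "protein_coding"))
    # two exons covering the outer 40% on each side
    if strand == "+":
        exon_rows.append((gid, chrom, start, start + int(0.4 * length), strand))
        exon_rows.append((gid, chrom, end - int(0.4 * length), end, strand))
    else:
        exon_rows.append((gid, chrom, start, start + int(0.4 * length), strand))
        exon_rows.append((gid, chrom, end - int(0.4 * length), end, strand))
    tu_rows.append((f"truth_{gid}", chrom, start, end, strand, "gene", gid))
    # uaRNA window on the antisense strand upstream of the TSS
    if strand == "+":
        ua = (max(start - 1_150, 0), max(start - 150, 0), "-")
    else:
        ua = (end + 150, end + 1_150, "+")
    tu_rows.append((f"truth_ua_{gid}", chrom, ua[0], ua[1], ua[2], "uaRNA", gid))


def _emit_intergenic_site(chrom, start, spec, idx, rules, state_rows,
                          tu_rows, enh_rows):
    gap, lp, lm = spec
    minus_tss = start + lm
    plus_tss = minus_tss + gap
    eid = f"E_inter_{idx:04d}"
    tu_rows.append((f"truth_{eid}_m", chrom, start, minus_tss, "-", "erna", eid))
    tu_rows.append((f"truth_{eid}_p", chrom, plus_tss, plus_tss + lp, "+",
                    "erna", eid))
    state_rows.append((chrom, minus_tss - 400, plus_tss + 400, f"state_{eid}"))
    enh_rows.append((eid, chrom, minus_tss - rules.enhancer_flank,
                     plus_tss + rules.enhancer_flank, "intergenic", ".",
                     f"truth_{eid}_p,truth_{eid}_m"))


def _emit_intragenic_sites(rng, genes_rows, n_intra, n_inter, elo, ehi,
                           rules, state_rows, tu_rows, enh_rows):
    """Place antisense-eRNA sites inside sufficiently long gene bodies."""
    if n_intra == 0:
        return
    order = rng.permutation(len(genes_rows))
    placed = 0
    for gi in order:
        if placed == n_intra:
            break
        gid, chrom, gstart, gend, gstrand, _ = genes_rows[gi]
        length = gend - gstart
        l_erna = int(rng.integers(elo // BIN, ehi // BIN + 1) * BIN)
        # asRNA TSS must sit > 1 kbp downstream of the gene TSS with its
        # whole body clear of the promoter, and the enhancer region must
        # stay inside the gene body
        need = 1_400 + l_erna + 1_000 + rules.intragenic_upstream
        if length < need + BIN:
            continue
        lo = 1_400 + l_erna
        hi = length - 1_000 - rules.intragenic_upstream
        off = int(rng.integers(lo // BIN, hi // BIN + 1) * BIN)
        eid = f"E_intra_{n_inter + placed:04d}"
        if gstrand == "+":
            tss = gstart + off
            body = (tss - l_erna, tss, "-")
            region = (tss - rules.enhancer_flank, tss + rules.intragenic_upstream)
        else:
            tss = gend - off
            body = (tss, tss + l_erna, "+")
            region = (tss - rules.intragenic_upstream, tss + rules.enhancer_flank)
        tu_rows.append((f"truth_{eid}", chrom, body[0], body[1], body[2],
                        "erna_antisense", eid))
        state_rows.append((chrom, tss - 600, tss + 600, f"state_{eid}"))
        enh_rows.append((eid, chrom, region[0], region[1], "intragenic",
                         body[2], f"truth_{eid}"))
        placed += 1
    if placed < n_intra:
        raise ValueError(
            f"placement failure for intragenic enhancer sites: only {placed} "
            f"of {n_intra} gene bodies are long enough to host an antisense "
            "eRNA at >= 1 kbp from the TSS")


def _check_state_distance(states: pd.DataFrame, genes: GeneAnnotation,
                          min_dist: int = 1_000):
    tss = genes.tss()
    for _, s in states.iterrows():
        chrom_tss = [int(tss[g]) for g in genes.genes.loc[
            genes.genes["chrom"] == s["chrom"], "gene_id"]]
        for t in chrom_tss:
            if s["start"] - min_dist < t < s["end"] + min_dist:
                raise AssertionError(
                    f"enhancer state {s['name']} violates the 1-kbp TSS "
                    "clearance constraint")


# ---------------------------------------------------------------------------
# transcription programs
# ---------------------------------------------------------------------------

def generate_programs(genome: SyntheticGenome, n_cell_lines: int = 14,
                      frac_specific: float = 0.37, seed: int = 0, *,
                      n_replicates: int = 2, coupling: float = 0.8,
                      link_fraction: float = 0.6,
                      depth_sigma: float = 0.3,
                      dispersion: float = 0.3,
                      background_rate: float = 0.05) -> TruthProgram:
    """Draw per-cell-line activities and plant enhancer-promoter links.

    ``frac_specific`` of enhancers are active in exactly one cell line
    (one-hot activity vector); the rest are active everywhere with
    log-normal line-to-line variation.  A ``link_fraction`` of enhancers is
    linked to its nearest gene (within 500 kbp); linked genes mix the
    enhancer's activity pattern with baseline noise at weight ``coupling``.
    """
    if n_cell_lines < 2:
        raise ValueError("need at least 2 cell lines")
    if not 0.0 <= frac_specific <= 1.0:
        raise ValueError("frac_specific must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lines = [f"CL{i + 1:02d}" for i in range(n_cell_lines)]
    gene_ids = list(genome.genes.genes["gene_id"])
    enh_ids = list(genome.truth_enhancers["enhancer_id"])

    def active_level(size):
        # floor keeps planted features clearly above the FPK activity cutoff
        return np.maximum(rng.lognormal(0.5, 0.4, size), 1.2)

    n_enh = len(enh_ids)
    n_spec = int(round(frac_specific * n_enh))
    specific = set(rng.choice(n_enh, n_spec, replace=False).tolist())
    e_act = np.zeros((n_enh, n_cell_lines))
    for i in range(n_enh):
        if i in specific:
            e_act[i, rng.integers(n_cell_lines)] = active_level(1)[0]
        else:
            e_act[i] = active_level(n_cell_lines)
    enhancer_activity = pd.DataFrame(e_act, index=enh_ids, columns=lines)

    baseline = np.maximum(rng.lognormal(0.2, 0.4, (len(gene_ids), n_cell_lines)),
                          0.7)
    gene_activity = pd.DataFrame(baseline, index=gene_ids, columns=lines)

    ep_links = _plant_links(genome, enh_ids, rng, link_fraction)
    for e, g in ep_links:
        evec = enhancer_activity.loc[e].to_numpy()
        scale = 1.2 / max(evec.mean(), 1e-9)
        gene_activity.loc[g] = (coupling * scale * evec
                                + (1.0 - coupling) * gene_activity.loc[g])

    ua = pd.Series(rng.uniform(0.1, 0.5, len(gene_ids)), index=gene_ids,
                   name="ua_fraction")
    samples = [f"{ln}_rep{r + 1}" for ln in lines for r in range(n_replicates)]
    depth = pd.Series(rng.lognormal(0.0, depth_sigma, len(samples)),
                      index=samples, name="depth_factor")
    sample_to_line = {s: s.rsplit("_rep", 1)[0] for s in samples}
    return TruthProgram(
        gene_activity=gene_activity, enhancer_activity=enhancer_activity,
        ua_fraction=ua, ep_links=ep_links, depth_factor=depth,
        sample_to_line=sample_to_line, dispersion=dispersion,
        background_rate=background_rate,
    )


def _plant_links(genome: SyntheticGenome, enh_ids: list[str],
                 rng: np.random.Generator,
                 link_fraction: float) -> set[tuple[str, str]]:
    tss = genome.genes.tss()
    gene_pos = genome.genes.genes.set_index("gene_id")
    enh = genome.truth_enhancers.set_index("enhancer_id")
    links: set[tuple[str, str]] = set()
    taken: set[str] = set()  # one linked enhancer per gene: the coupled
    # pattern is then unambiguous and each link carries a clean signal
    for eid in enh_ids:
        if rng.random() >= link_fraction:
            continue
        chrom = enh.loc[eid, "chrom"]
        mid = (int(enh.loc[eid, "start"]) + int(enh.loc[eid, "end"])) // 2
        cand = gene_pos[gene_pos["chrom"] == chrom]
        cand = cand[~cand.index.isin(taken)]
        if cand.empty:
            continue
        dists = np.abs(np.array([int(tss[g]) for g in cand.index]) - mid)
        best = int(np.argmin(dists))
        if dists[best] < 500_000:
            links.add((eid, cand.index[best]))
            taken.add(cand.index[best])
    return links


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

def _rate_tracks(genome: SyntheticGenome, truth: TruthProgram,
                 line: str) -> dict[str, dict[str, np.ndarray]]:
    """Per-strand, per-chromosome expected counts per bin at depth 1."""
    layout = genome.layout
    tracks = {
        s: {c: np.full(layout.n_bins(c), truth.background_rate)
            for c, _ in layout.chromosomes}
        for s in "+-"
    }

    def add(chrom, start, end, strand, rate):
        lo, hi = bin_index_range(int(start), int(end), layout.bin_width)
        vec = tracks[strand][chrom]
        vec[lo:min(hi, len(vec))] += rate

    for _, tu in genome.truth_tus.iterrows():
        if tu["kind"] == "gene":
            act = truth.gene_activity.at[tu["parent"], line]
            rate = truth.gene_rate * act
        elif tu["kind"] == "uaRNA":
            act = truth.gene_activity.at[tu["parent"], line]
            rate = truth.gene_rate * act * truth.ua_fraction[tu["parent"]]
        else:
            act = truth.enhancer_activity.at[tu["parent"], line]
            rate = truth.erna_rate * act
        if rate > 0:
            add(tu["chrom"], tu["start"], tu["end"], tu["strand"], rate)
    return tracks


def simulate_coverage(genome: SyntheticGenome, truth: TruthProgram,
                      seed: int = 0, noise: str = "poisson-lognormal",
                      ) -> dict[str, dict[str, BinnedCoverage]]:
    """Simulate binned coverage for every sample in the truth program.

    Returns sample_id -> strand -> BinnedCoverage.  With
    ``noise='poisson-lognormal'`` counts are Poisson with a log-normally
    jittered rate; ``noise='none'`` emits the rounded expected counts (used
    for exact-recovery checks).
    """
    if noise not in ("poisson-lognormal", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, BinnedCoverage]] = {}
    line_tracks: dict[str, dict] = {}
    for sample in truth.samples:
        line = truth.sample_to_line[sample]
        if line not in line_tracks:
            line_tracks[line] = _rate_tracks(genome, truth, line)
        depth = float(truth.depth_factor[sample])
        cov = {s: empty_coverage(genome.layout, sample, s) for s in "+-"}
        for strand in "+-":
            for chrom, rate in line_tracks[line][strand].items():
                lam = depth * rate
                if noise == "none":
                    counts = np.rint(lam).astype(np.int64)
                else:
                    jitter = np.exp(truth.dispersion
                                    * rng.standard_normal(len(lam)))
                    counts = rng.poisson(lam * jitter).astype(np.int64)
                cov[strand].data[chrom] = counts
        out[sample] = cov
    return out


# ---------------------------------------------------------------------------
# ancillary data
# ---------------------------------------------------------------------------

def simulate_ancillary(genome: SyntheticGenome, truth: TruthProgram,
                       seed: int = 0, *,
                       fragment_size: int = 4_000,
                       n_decoys_per_link: int = 3,
                       n_background_snps: int = 5_000,
                       n_trait_snps: int = 500,
                       snp_enrichment: float = 3.0,
                       peak_signal_scale: float = 100.0,
                       heavy_tail: float = 1.2,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate interaction, SNP, and peak-signal tables.

    * interactions: a >= 3.0-scoring bait/hit fragment pair spanning every
      planted E-P link, plus random sub-3.0 decoys;
    * SNPs: background catalog uniform over the genome with matching
      covariates (maf, gene density, distance to nearest gene) and a trait
      set whose in-enhancer probability is ``snp_enrichment`` times the
      background enhancer fraction;
    * peaks: one peak per planted enhancer with signal proportional to mean
      activity times a Pareto-tailed boost (drives super-enhancer calling).
    """
    rng = np.random.default_rng(seed)
    layout = genome.layout
    lengths = layout.lengths
    enh = genome.truth_enhancers
    tss = genome.genes.tss()
    gene_pos = genome.genes.genes.set_index("gene_id")

    def tile(pos: int) -> tuple[int, int]:
        lo = (pos // fragment_size) * fragment_size
        return lo, lo + fragment_size

    inter_rows = []
    for eid, gid in sorted(truth.ep_links):
        chrom = enh.set_index("enhancer_id").loc[eid, "chrom"]
        b_lo, b_hi = tile(int(tss[gid]))
        e = enh.set_index("enhancer_id").loc[eid]
        h_lo, h_hi = tile((int(e["start"]) + int(e["end"])) // 2)
        inter_rows.append((chrom, b_lo, b_hi, chrom, h_lo, h_hi,
                           float(rng.uniform(3.0, 10.0))))
        for _ in range(n_decoys_per_link):
            p1 = int(rng.integers(0, lengths[chrom]))
            p2 = int(rng.integers(0, lengths[chrom]))
            d_lo, d_hi = tile(p1)
            d2_lo, d2_hi = tile(p2)
            inter_rows.append((chrom, d_lo, d_hi, chrom, d2_lo, d2_hi,
                               float(rng.uniform(0.3, 2.99))))
    interactions = pd.DataFrame(
        inter_rows, columns=["bait_chrom", "bait_start", "bait_end",
                             "hit_chrom", "hit_start", "hit_end", "score"])

    snps = _simulate_snps(rng, layout, enh, gene_pos, tss,
                          n_background_snps, n_trait_snps, snp_enrichment)

    mean_act = truth.enhancer_activity.mean(axis=1).reindex(enh["enhancer_id"])
    boost = 1.0 + rng.pareto(heavy_tail, len(enh))
    peaks = pd.DataFrame({
        "chrom": enh["chrom"].to_numpy(),
        "start": enh["start"].to_numpy(),
        "end": enh["end"].to_numpy(),
        "name": enh["enhancer_id"].to_numpy(),
        "signal": peak_signal_scale * mean_act.to_numpy() * boost,
    })
    return interactions, snps, peaks


def _simulate_snps(rng, layout, enhancers, gene_pos, tss,
                   n_background, n_trait, enrichment):
    lengths = layout.lengths
    chroms = list(lengths)
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    enh_bp = float((enhancers["end"] - enhancers["start"]).sum())
    p_bg = enh_bp / sizes.sum()
    p_trait = min(enrichment * p_bg, 0.95)

    tss_by_chrom = {
        c: np.sort([int(tss[g]) for g in gene_pos[gene_pos["chrom"] == c].index])
        for c in chroms
    }
    # truth enhancer regions never overlap, so sorted-edge search suffices
    enh_sorted = {
        c: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for c, sub in ((c, enhancers[enhancers["chrom"] == c]
                        .sort_values("start")) for c in chroms)
    }

    def in_enhancer(chrom, pos):
        starts, ends = enh_sorted[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        return np.where(i >= 0, pos < ends[np.maximum(i, 0)], False)

    def draw_uniform(n):
        ci = rng.choice(len(chroms), n, p=sizes / sizes.sum())
        pos = (rng.random(n) * sizes[ci]).astype(np.int64)
        return ci, pos

    def draw_outside_enhancer(n):
        out_c = np.empty(n, dtype=int)
        out_p = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:  # rejection: enhancers cover a few % of the genome
            ci, pos = draw_uniform(2 * (n - filled) + 8)
            keep = ~np.array([in_enhancer(chroms[c], p)
                              for c, p in zip(ci, pos)], dtype=bool)
            take = min(int(keep.sum()), n - filled)
            out_c[filled:filled + take] = ci[keep][:take]
            out_p[filled:filled + take] = pos[keep][:take]
            filled += take
        return out_c, out_p

    def draw_in_enhancer(n):
        widths = (enhancers["end"] - enhancers["start"]).to_numpy(dtype=float)
        ei = rng.choice(len(enhancers), n, p=widths / widths.sum())
        sub = enhancers.iloc[ei]
        pos = (sub["start"].to_numpy()
               + (rng.random(n) * widths[ei]).astype(np.int64))
        ci = np.array([chroms.index(c) for c in sub["chrom"]])
        return ci, pos

    frames = []
    for setname, n, p_in in (("background", n_background, None),
                             ("trait", n_trait, p_trait)):
        if p_in is None:
            ci, pos = draw_uniform(n)
        else:
            inside = rng.random(n) < p_in
            ci = np.empty(n, dtype=int)
            pos = np.empty(n, dtype=np.int64)
            n_in = int(inside.sum())
            if n_in:
                ci[inside], pos[inside] = draw_in_enhancer(n_in)
            if n - n_in:
                ci[~inside], pos[~inside] = draw_outside_enhancer(n - n_in)
        chrom_names = np.array(chroms)[ci]
        dens = np.empty(n, dtype=int)
        dist = np.empty(n, dtype=float)
        for k, (c, p) in enumerate(zip(chrom_names, pos)):
            ts = tss_by_chrom[c]
            if len(ts) == 0:
                dens[k], dist[k] = 0, float(lengths[c])
            else:
                d = np.abs(ts - p)
                dens[k] = int((d <= 500_000).sum())
                dist[k] = float(d.min())
        frames.append(pd.DataFrame({
            "chrom": chrom_names, "pos": pos, "set": setname,
            "maf": rng.uniform(0.05, 0.5, n),
            "gene_density": dens, "dist_nearest_gene": dist,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_dataset(outdir: str, genome: SyntheticGenome,
                  coverage: dict[str, dict[str, BinnedCoverage]] | None = None,
                  interactions: pd.DataFrame | None = None,
                  snps: pd.DataFrame | None = None,
                  peaks: pd.DataFrame | None = None):
    """Write the synthetic dataset in its on-disk formats (GTF, BED,
    bedGraph per sample/strand, TSV tables)."""
    import os

    from .genomic_io import write_bed, write_bedgraph, write_gtf

    os.makedirs(outdir, exist_ok=True)
    write_gtf(genome.genes, os.path.join(outdir, "genes.gtf"))
    write_bed(genome.enhancer_states, os.path.join(outdir, "enhancer_states.bed"))
    if coverage:
        for sample, strands in coverage.items():
            for strand, cov in strands.items():
                suffix = "plus" if strand == "+" else "minus"
                write_bedgraph(cov, os.path.join(outdir, f"{sample}.{suffix}.bedgraph"))
    if interactions is not None:
        interactions.to_csv(os.path.join(outdir, "interactions.tsv"),
                            sep="\t", index=False)
    if snps is not None:
        snps.to_csv(os.path.join(outdir, "snps.tsv"), sep="\t", index=False)
    if peaks is not None:
        write_bed(peaks.assign(score=0, strand="."),
                  os.path.join(outdir, "peaks.bed"), extra=["signal"])
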