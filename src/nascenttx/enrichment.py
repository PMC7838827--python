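"""Super-enhancer calling and matched-null enrichment statistics.

Super-enhancers follow the stitched-peak recipe: co-activator peaks closer
than 12.5 kbp are chained, chains are ranked by total signal, both axes are
min-max rescaled, and the cutoff sits where the discrete slope of the
signal-vs-rank curve first exceeds 1 — everything ranked above it is a
super-enhancer.

Empirical enrichment uses matched resampling: null feature sets are drawn
from a background to preserve the observed covariate distribution (decile
bins per covariate, joint-bin sampling with nearest-bin fallback), and the
empirical p-value applies the plus-one rule
``p = (1 + #{null >= observed}) / (1 + n_resamples)`` so it is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .genomic_io import GenomeLayout


@dataclass
class NullEnsemble:
    """An observed statistic against matched-resample null statistics."""

    observed: float
    null_values: np.ndarray
    greater_is_enriched: bool = True

    def __post_init__(self):
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) == 0:
            raise ValueError("need at least one null resample")

    @property
    def n_resamples(self) -> int:
        return len(self.null_values)

    @property
    def p_value(self) -> float:
        if self.greater_is_enriched:
            extreme = int(np.sum(self.null_values >= self.observed))
        else:
            extreme = int(np.sum(self.null_values <= self.observed))
        return (1 + extreme) / (1 + self.n_resamples)

    def summary(self) -> dict:
        return {
            "observed": float(self.observed),
            "null_median": float(np.median(self.null_values)),
            "n_resamples": self.n_resamples,
            "p_value": float(self.p_value),
        }


# ---------------------------------------------------------------------------
# super-enhancers
# ---------------------------------------------------------------------------

def call_super_enhancers(peaks: pd.DataFrame,
                         stitch_gap: int = 12_500) -> pd.DataFrame:
    """Stitch peaks and flag super-enhancers above the slope-1 inflection.

    ``peaks`` needs chrom/start/end/signal (and optionally name).  Peaks on
    the same chromosome separated by less than ``stitch_gap`` are stitched;
    stitched regions are ranked by total constituent signal.  On the
    min-max-rescaled rank/signal curve, the first rank where the central-
    difference slope exceeds 1 sets the cutoff; regions ranked strictly
    above it are super-enhancers.  With fewer than 3 stitched regions the
    inflection is undefined and everything is flagged typical.
    """
    if "name" not in peaks:
        peaks = peaks.assign(name=[f"peak_{i}" for i in range(len(peaks))])
    regions = []
    for chrom, sub in peaks.sort_values(["chrom", "start"]).groupby("chrom"):
        cur = None
        for _, r in sub.iterrows():
            if cur is None or r["start"] - cur["end"] >= stitch_gap:
                if cur is not None:
                    regions.append(cur)
                cur = {"chrom": chrom, "start": int(r["start"]),
                       "end": int(r["end"]), "signal": float(r["signal"]),
                       "constituents": [str(r["name"])]}
            else:
                cur["end"] = max(cur["end"], int(r["end"]))
                cur["signal"] += float(r["signal"])
                cur["constituents"].append(str(r["name"]))
        if cur is not None:
            regions.append(cur)
    df = pd.DataFrame(regions)
    if df.empty:
        df["rank"] = df["is_super"] = pd.Series(dtype=int)
        return df
    df["constituents"] = df["constituents"].str.join(",")
    df = df.sort_values("signal", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(len(df))
    n = len(df)
    if n < 3 or df["signal"].nunique() == 1:
        if n < 3:
            warnings.warn("fewer than 3 stitched regions; inflection undefined",
                          stacklevel=2)
        df["is_super"] = False
        return df
    x = df["rank"].to_numpy(dtype=float) / (n - 1)
    sig = df["signal"].to_numpy(dtype=float)
    y = (sig - sig.min()) / (sig.max() - sig.min())
    slope = np.gradient(y, x)
    above = np.flatnonzero(slope > 1.0)
    if len(above) == 0:
        df["is_super"] = False
    else:
        df["is_super"] = df["rank"] > above[0]
    return df


# ---------------------------------------------------------------------------
# CHi-C support
# ---------------------------------------------------------------------------

class InteractionIndex:
    """Bait-fragment interval index over score-filtered interactions.

    Built once and reused across matched-null resamples.
    """

    def __init__(self, interactions: pd.DataFrame, min_score: float = 3.0):
        strong = interactions[interactions["score"] >= min_score]
        self._trees: dict[str, IntervalTree] = {}
        self._hits = {
            i: (r["hit_chrom"], int(r["hit_start"]), int(r["hit_end"]))
            for i, r in strong.iterrows()
        }
        for i, r in strong.iterrows():
            self._trees.setdefault(r["bait_chrom"], IntervalTree()).addi(
                int(r["bait_start"]), int(r["bait_end"]), i)

    def supports(self, chrom: str, tss: int, e_start: int, e_end: int) -> bool:
        for hit in self._trees.get(chrom, IntervalTree()).at(int(tss)):
            h_chrom, h_start, h_end = self._hits[hit.data]
            if h_chrom == chrom and h_start < e_end and h_end > e_start:
                return True
        return False


def chic_support(pairs: pd.DataFrame, interactions: pd.DataFrame,
                 promoters: pd.DataFrame, enhancers: pd.DataFrame,
                 min_score: float = 3.0, min_distance: int = 10_000,
                 index: InteractionIndex | None = None,
                 ) -> tuple[pd.DataFrame, float]:
    """Flag E-P pairs supported by a chromatin interaction.

    A pair is supported iff some interaction with score >= ``min_score``
    has its bait fragment covering the promoter TSS and its hit fragment
    overlapping the enhancer region.  Pairs at distance <= ``min_distance``
    are excluded from the analysis (short-range contacts are unreliable).
    Returns (pair table with ``supported``, supported fraction).
    """
    if index is None:
        index = InteractionIndex(interactions, min_score)
    tss = promoters.set_index("gene_id")["tss"]
    enh = enhancers.set_index("enhancer_id")
    considered = pairs[pairs["distance"] > min_distance].copy()
    flags = [
        index.supports(enh.loc[p["enhancer_id"], "chrom"],
                       int(tss[p["gene_id"]]),
                       int(enh.loc[p["enhancer_id"], "start"]),
                       int(enh.loc[p["enhancer_id"], "end"]))
        for _, p in considered.iterrows()
    ]
    considered["supported"] = flags
    frac = float(np.mean(flags)) if flags else float("nan")
    return considered, frac


# ---------------------------------------------------------------------------
# matched resampling
# ---------------------------------------------------------------------------

def _decile_bins(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Bin assignment by deciles of the reference distribution."""
    edges = np.quantile(reference, np.linspace(0, 1, 11)[1:-1])
    return np.searchsorted(edges, values, side="right")


class MatchedSampler:
    """Decile-bin matched resampler over a fixed background.

    Decile bins are computed on the background per covariate; draws are per
    joint bin with replacement, falling back to the nearest nonempty bin
    (L1 distance on bin coordinates) with a warning.  Precomputes the bin
    index once so repeated null draws are cheap.
    """

    def __init__(self, background: pd.DataFrame, covariates: list[str]):
        self.background = background
        self.covariates = list(covariates)
        self._ref = {c: background[c].to_numpy(dtype=float)
                     for c in self.covariates}
        bg_bins = np.stack([
            _decile_bins(self._ref[c], self._ref[c])
            for c in self.covariates], axis=1)
        self._index_by_key: dict[tuple, np.ndarray] = {}
        for i, key in enumerate(map(tuple, bg_bins)):
            self._index_by_key.setdefault(key, []).append(i)
        self._index_by_key = {k: np.asarray(v)
                              for k, v in self._index_by_key.items()}
        self._keys_arr = {k: np.array(k) for k in self._index_by_key}
        self._warned = False

    def bin_assignments(self, observed: pd.DataFrame) -> np.ndarray:
        return np.stack([
            _decile_bins(observed[c].to_numpy(dtype=float), self._ref[c])
            for c in self.covariates], axis=1)

    def draw_positions(self, obs_bins: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
        picks = np.empty(len(obs_bins), dtype=int)
        for j, row in enumerate(obs_bins):
            key = tuple(row)
            if key not in self._index_by_key:
                if not self._warned:
                    warnings.warn(
                        "empty matching bin; using nearest nonempty bin",
                        stacklevel=3)
                    self._warned = True
                key = min(self._index_by_key,
                          key=lambda k: np.abs(self._keys_arr[k] - row).sum())
            idx = self._index_by_key[key]
            picks[j] = idx[rng.integers(len(idx))]
        return picks

    def draw(self, observed: pd.DataFrame,
             rng: np.random.Generator) -> pd.DataFrame:
        return self.background.iloc[
            self.draw_positions(self.bin_assignments(observed), rng)]


def matched_sample(observed: pd.DataFrame, background: pd.DataFrame,
                   covariates: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Draw |observed| rows from background matching covariate deciles.

    One-shot convenience over :class:`MatchedSampler`.  Draws are with
    replacement, so the background may be smaller than the observed set
    (callers that require a larger background enforce that themselves).
    """
    return MatchedSampler(background, covariates).draw(observed, rng)


def _interval_trees(regions: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for _, r in regions.iterrows():
        trees.setdefault(r["chrom"], IntervalTree()).addi(
            int(r["start"]), int(r["end"]))
    return trees


def sample_noncoding_regions(n: int, widths: np.ndarray, layout: GenomeLayout,
                             genes: pd.DataFrame,
                             rng: np.random.Generator,
                             max_tries: int = 200) -> pd.DataFrame:
    """Random gene-free regions with the given widths."""
    gene_trees = _interval_trees(genes)
    chroms = [c for c, _ in layout.chromosomes]
    lengths = layout.lengths
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    rows = []
    for w in widths[:n]:
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            if lengths[chrom] <= w:
                continue
            start = int(rng.integers(0, lengths[chrom] - int(w)))
            if not gene_trees.get(chrom, IntervalTree()).overlap(start, start + int(w)):
                rows.append({"chrom": chrom, "start": start,
                             "end": start + int(w)})
                break
        else:
            raise RuntimeError("could not place a gene-free region; "
                               "genome too crowded")
    return pd.DataFrame(rows)


def sample_matched_ep_nulls(pairs: pd.DataFrame, promoters: pd.DataFrame,
                            promoter_covariates: pd.DataFrame,
                            interactions: pd.DataFrame,
                            enhancers: pd.DataFrame,
                            layout: GenomeLayout, genes: pd.DataFrame,
                            n_sets: int = 100, seed: int = 0,
                            min_score: float = 3.0,
                            min_distance: int = 10_000) -> NullEnsemble:
    """Empirical null for the CHi-C-supported fraction of E-P pairs.

    Each null set redraws promoters matching the observed joint decile
    distribution of activity and overall specificity
    (``promoter_covariates`` columns: activity, specificity), then pairs
    each with a random gene-free region matching the observed enhancer
    widths and E-P distances, and recomputes the supported fraction.
    """
    if n_sets <= 0:
        raise ValueError("n_sets must be positive")
    rng = np.random.default_rng(seed)
    index = InteractionIndex(interactions, min_score)
    observed_pairs, obs_frac = chic_support(
        pairs, interactions, promoters, enhancers, min_score, min_distance,
        index=index)
    if observed_pairs.empty:
        raise ValueError("no E-P pairs beyond the minimum distance")

    enh = enhancers.set_index("enhancer_id")
    widths = (enh["end"] - enh["start"]).reindex(
        observed_pairs["enhancer_id"]).to_numpy()
    distances = observed_pairs["distance"].to_numpy()
    obs_cov = promoter_covariates.reindex(observed_pairs["gene_id"])
    bg_cov = promoter_covariates.dropna()
    sampler = MatchedSampler(bg_cov, list(promoter_covariates.columns))
    obs_bins = sampler.bin_assignments(obs_cov)
    tss = promoters.set_index("gene_id")["tss"]
    chrom_of = promoters.set_index("gene_id")["chrom"]
    lengths = layout.lengths

    nulls = []
    for _ in range(n_sets):
        drawn = bg_cov.iloc[sampler.draw_positions(obs_bins, rng)]
        null_pairs, null_enh_rows = [], []
        for j, gid in enumerate(drawn.index):
            if gid not in tss.index:
                continue
            chrom = chrom_of[gid]
            t = int(tss[gid])
            w = int(widths[j])
            d = int(distances[j])
            side = rng.choice([-1, 1])
            mid = t + side * d
            start = mid - w // 2
            if start < 0 or start + w > lengths[chrom]:
                mid = t - side * d
                start = mid - w // 2
                if start < 0 or start + w > lengths[chrom]:
                    continue
            eid = f"null_{j}"
            null_enh_rows.append({"enhancer_id": eid, "chrom": chrom,
                                  "start": start, "end": start + w})
            null_pairs.append({"enhancer_id": eid, "gene_id": gid,
                               "method": "null", "distance": d,
                               "r": np.nan, "skip": False})
        null_pair_df = pd.DataFrame(null_pairs)
        null_enh_df = pd.DataFrame(null_enh_rows)
        if null_pair_df.empty:
            nulls.append(0.0)
            continue
        _, frac = chic_support(null_pair_df, interactions, promoters,
                               null_enh_df, min_score, min_distance,
                               index=index)
        nulls.append(frac if np.isfinite(frac) else 0.0)
    return NullEnsemble(obs_frac, np.array(nulls))


def snp_hit_mask(snps: pd.DataFrame, enhancers: pd.DataFrame) -> np.ndarray:
    """Boolean per SNP: does it fall inside any enhancer region?"""
    trees = _interval_trees(enhancers)
    return np.array([
        bool(trees.get(chrom, IntervalTree()).at(int(pos)))
        for chrom, pos in zip(snps["chrom"], snps["pos"])
    ])


def snp_enhancer_overlap(snps: pd.DataFrame, enhancers: pd.DataFrame) -> int:
    """Number of SNPs falling inside any enhancer region."""
    return int(snp_hit_mask(snps, enhancers).sum())


def sample_matched_snp_nulls(trait_snps: pd.DataFrame,
                             background_snps: pd.DataFrame,
                             enhancers: pd.DataFrame,
                             n_sets: int = 1_000, seed: int = 0,
                             covariates: tuple[str, ...] = (
                                 "maf", "gene_density", "dist_nearest_gene"),
                             ) -> NullEnsemble:
    """Empirical null for trait-SNP overlap with enhancer regions.

    Each null set draws |trait| background SNPs matched on the covariate
    deciles; the statistic is the count of SNPs inside any enhancer.
    """
    if len(trait_snps) == 0:
        raise ValueError("trait SNP set is empty")
    if len(background_snps) < len(trait_snps):
        raise ValueError("background catalog smaller than the trait set")
    if n_sets <= 0:
        raise ValueError("n_sets must be positive")
    rng = np.random.default_rng(seed)
    observed = snp_enhancer_overlap(trait_snps, enhancers)
    # precompute per-SNP overlap and the matching bins once
    bg_hits = snp_hit_mask(background_snps, enhancers).astype(int)
    cov_list = [c for c in covariates if c in background_snps.columns]
    sampler = MatchedSampler(background_snps, cov_list)
    obs_bins = sampler.bin_assignments(trait_snps)
    nulls = np.empty(n_sets)
    for i in range(n_sets):
        nulls[i] = bg_hits[sampler.draw_positions(obs_bins, rng)].sum()
    return NullEnsemble(float(observed), nulls)


# ---------------------------------------------------------------------------
# classical tests and generic overlap machinery
# ---------------------------------------------------------------------------

def fisher_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for the 2x2 table
    [[a, b], [c, d]]; OR = (a*d)/(b*c) with OR = inf when b*c == 0 and
    a*d > 0."""
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("contingency cells must be non-negative")
    if sum(cells) == 0:
        raise ValueError("empty contingency table")
    if b * c == 0:
        odds = np.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def region_overlap_enrichment(query: pd.DataFrame, reference: pd.DataFrame,
                              layout: GenomeLayout, genes: pd.DataFrame,
                              n_sets: int = 20, seed: int = 0) -> NullEnsemble:
    """Fraction of query regions hitting the reference vs matched nulls.

    Null sets are random gene-free regions with the observed query widths.
    """
    rng = np.random.default_rng(seed)
    ref_trees = _interval_trees(reference)

    def frac(regions: pd.DataFrame) -> float:
        hits = [
            bool(ref_trees.get(r["chrom"], IntervalTree()).overlap(
                int(r["start"]), int(r["end"])))
            for _, r in regions.iterrows()
        ]
        return float(np.mean(hits)) if hits else float("nan")

    widths = (query["end"] - query["start"]).to_numpy()
    nulls = []
    for _ in range(n_sets):
        rand = sample_noncoding_regions(len(query), widths, layout, genes, rng)
        nulls.append(frac(rand))
    return NullEnsemble(frac(query), np.array(nulls))
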