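"""Transcription directionality and cell-type-specificity scores.

Two specificity scores over a feature's activity vector x across n cell
lines are provided:

* entropy score ``1 - H(p) / log2(n)`` with ``p_i = x_i / sum(x)`` — 0 for a
  uniform pattern, 1 for activity confined to a single cell line;
* Jensen-Shannon score ``1 - sqrt(JS(t, t_c))`` against the one-hot
  indicator pattern ``t_c`` of cell line c, with JS in bits, so a pattern
  identical to the indicator scores 1.

Directionality scores are plain ratios of normalized counts: mRNA vs uaRNA
windows at promoters, plus vs minus strand at intergenic enhancers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genomic_io import BinnedCoverage, GeneAnnotation, count_fragments


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------

def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropy_specificity(x) -> float:
    """Entropy-based overall cell type specificity of an activity vector.

    Returns NaN when the vector sums to zero (score undefined).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector over >= 2 cell lines")
    if np.any(x < 0):
        raise ValueError("activities must be non-negative")
    total = x.sum()
    if total == 0:
        return float("nan")
    p = x / total
    score = 1.0 - _entropy_bits(p) / np.log2(len(x))
    return float(np.clip(score, 0.0, 1.0))  # guard log round-off


def js_divergence(p1, p2) -> float:
    """Jensen-Shannon divergence of two probability vectors, in bits."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    m = (p1 + p2) / 2.0
    return _entropy_bits(m) - (_entropy_bits(p1) + _entropy_bits(p2)) / 2.0


def js_specificity(t, c: int) -> float:
    """JS-based specificity of pattern ``t`` with respect to cell line ``c``.

    ``t`` is normalized to a probability vector and compared with the
    indicator pattern of cell line ``c``; the score is 1 minus the JS
    distance (square root of the JS divergence).  NaN when sum(t) == 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("activities must be non-negative")
    if not 0 <= c < len(t):
        raise ValueError("cell-line index out of range")
    total = t.sum()
    if total == 0:
        return float("nan")
    p = t / total
    tc = np.zeros(len(t))
    tc[c] = 1.0
    js = max(js_divergence(p, tc), 0.0)  # clip tiny negative round-off
    return float(np.clip(1.0 - np.sqrt(js), 0.0, 1.0))


def specificity_table(activity: pd.DataFrame) -> pd.DataFrame:
    """Entropy score plus per-line JS scores for every row of an
    (features x cell lines) activity matrix."""
    lines = list(activity.columns)
    rows = {}
    for fid, x in activity.iterrows():
        vec = x.to_numpy(dtype=float)
        rec = {"entropy_specificity": entropy_specificity(vec)}
        for i, line in enumerate(lines):
            rec[f"js_{line}"] = (js_specificity(vec, i)
                                 if vec.sum() > 0 else float("nan"))
        rows[fid] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# directionality
# ---------------------------------------------------------------------------

def promoter_windows(genes: GeneAnnotation,
                     sense_bp: int = 1_000,
                     antisense_lo: int = 150,
                     antisense_hi: int = 1_150) -> pd.DataFrame:
    """Sense (TSS..TSS+1000) and upstream-antisense (TSS-1150..TSS-150)
    quantification windows, strand-mirrored for minus-strand genes."""
    g = genes.genes
    tss = genes.tss().to_numpy()
    plus = g["strand"].to_numpy() == "+"
    sense_start = np.where(plus, tss, tss - sense_bp)
    sense_end = np.where(plus, tss + sense_bp, tss)
    anti_start = np.where(plus, tss - antisense_hi, tss + antisense_lo)
    anti_end = np.where(plus, tss - antisense_lo, tss + antisense_hi)
    return pd.DataFrame({
        "gene_id": g["gene_id"].to_numpy(), "chrom": g["chrom"].to_numpy(),
        "strand": g["strand"].to_numpy(),
        "sense_start": np.maximum(sense_start, 0), "sense_end": sense_end,
        "anti_start": np.maximum(anti_start, 0), "anti_end": anti_end,
    })


def eligible_promoters(genes: GeneAnnotation, radius: int = 5_000) -> pd.Series:
    """Genes with no opposite-strand protein-coding gene within +/- radius
    of the sense TSS (boolean per gene, indexed by gene_id)."""
    g = genes.genes[genes.genes["biotype"] == "protein_coding"]
    tss = genes.tss()
    ok = {}
    for _, r in g.iterrows():
        t = int(tss[r["gene_id"]])
        others = g[(g["chrom"] == r["chrom"]) & (g["strand"] != r["strand"])]
        # clash iff any part of an opposite-strand gene lies within the radius
        clash = (others["start"] <= t + radius) & (others["end"] >= t - radius)
        ok[r["gene_id"]] = not bool(clash.any())
    return pd.Series(ok, name="eligible")


def promoter_directionality(genes: GeneAnnotation,
                            coverage: dict[str, BinnedCoverage],
                            size_factor: float = 1.0,
                            min_counts: float = 10.0) -> pd.DataFrame:
    """Per-promoter sense/antisense counts, bidirectionality and ratio.

    Only genes without an opposite-strand protein-coding neighbor within
    +/- 5 kbp of the TSS are scored.  A promoter is bidirectional iff both
    windows reach ``min_counts`` normalized counts; the directionality score
    (sense / antisense ratio) is defined only for bidirectional promoters.
    """
    win = promoter_windows(genes)
    keep = eligible_promoters(genes)
    win = win[win["gene_id"].map(keep).fillna(False)]
    sense_iv = win.rename(columns={"sense_start": "start", "sense_end": "end"})
    anti_iv = win.rename(columns={"anti_start": "start", "anti_end": "end"})
    sense = count_fragments(sense_iv, coverage, "sense") / size_factor
    anti = count_fragments(anti_iv, coverage, "antisense") / size_factor
    out = pd.DataFrame({
        "gene_id": win["gene_id"].to_numpy(),
        "sense": sense, "antisense": anti,
    })
    out["bidirectional"] = (out["sense"] >= min_counts) & (out["antisense"] >= min_counts)
    out["ratio"] = np.where(out["bidirectional"],
                            out["sense"] / out["antisense"], np.nan)
    return out.set_index("gene_id")


def enhancer_directionality(regions: pd.DataFrame,
                            coverage: dict[str, BinnedCoverage],
                            size_factor: float = 1.0,
                            max_width: int = 3_000,
                            min_counts: float = 10.0,
                            cutoff: float = 3.0) -> pd.DataFrame:
    """Plus/minus strand ratio at bidirectional intergenic enhancers.

    Only intergenic regions strictly narrower than ``max_width`` enter the
    analysis; an enhancer is 'preferred' when the ratio is >= cutoff or
    <= 1/cutoff, otherwise 'balanced'.
    """
    sel = regions[(regions["kind"] == "intergenic") &
                  (regions["end"] - regions["start"] < max_width)].copy()
    sel["strand"] = "+"
    plus = count_fragments(sel, coverage, "sense") / size_factor
    minus = count_fragments(sel, coverage, "antisense") / size_factor
    out = pd.DataFrame({
        "enhancer_id": sel["enhancer_id"].to_numpy(),
        "plus": plus, "minus": minus,
    }).set_index("enhancer_id")
    out["bidirectional"] = (out["plus"] >= min_counts) & (out["minus"] >= min_counts)
    out["ratio"] = np.where(out["bidirectional"], out["plus"] / out["minus"], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        preferred = (out["ratio"] >= cutoff) | (out["ratio"] <= 1.0 / cutoff)
    out["category"] = np.where(out["bidirectional"],
                               np.where(preferred, "preferred", "balanced"), "na")
    return out


def cross_line_correlation(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                           min_lines: int = 5, min_cv: float = 0.5,
                           min_counts: float = 10.0) -> pd.Series:
    """Pearson r of log2 counts between two matched activity matrices.

    A cell line is valid for a feature when both matrices reach
    ``min_counts`` there (the bidirectionality rule).  Features with fewer
    than ``min_lines`` valid lines, with a coefficient of variation of
    total activity <= ``min_cv`` over the valid lines, or with a
    zero-variance log vector are excluded.
    """
    if not matrix_a.index.equals(matrix_b.index):
        raise ValueError("matrices must share features")
    out = {}
    a = matrix_a.to_numpy(dtype=float)
    b = matrix_b.to_numpy(dtype=float)
    for i, fid in enumerate(matrix_a.index):
        valid = (a[i] >= min_counts) & (b[i] >= min_counts)
        if valid.sum() < min_lines:
            continue
        total = a[i][valid] + b[i][valid]
        if total.mean() <= 0 or total.std(ddof=0) / total.mean() <= min_cv:
            continue
        la, lb = np.log2(a[i][valid]), np.log2(b[i][valid])
        if la.std() == 0 or lb.std() == 0:
            continue
        out[fid] = float(np.corrcoef(la, lb)[0, 1])
    return pd.Series(out, name="r", dtype=float)


def log_activity(activity: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(FPK + pseudocount), the transform used for pairing correlations."""
    return np.log2(activity + pseudocount)
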