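"""Enhancer-promoter pairing by proximity and activity correlation.

Three strategies link an enhancer (anchored at its region midpoint) to gene
promoters (anchored at the 5'-most annotated TSS):

* N  — nearest active promoter within 500 kbp, no correlation filter;
* CN — the nearest active promoter on each side, kept when the Pearson
  correlation of log2(FPK + 1) across cell lines exceeds 0.6;
* CW — every active promoter within +/- 500 kbp, same r > 0.6 filter, with
  a flag marking pairs that skip over a closer transcribed promoter.

Active promoters are genes with normalized FPK >= 30 in at least one cell
line; a pair is attributed to a cell line when both partners are active
there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MAX_DISTANCE = 500_000
R_CUTOFF = 0.6
PROMOTER_FPK = 30.0


def promoter_anchors(genes, activity: pd.DataFrame,
                     fpk_threshold: float = PROMOTER_FPK) -> pd.DataFrame:
    """Active-promoter table: gene_id, chrom, tss for genes with FPK >=
    threshold in at least one cell line."""
    g = genes.genes[genes.genes["biotype"] == "protein_coding"]
    tss = genes.tss()
    act = activity.reindex(g["gene_id"]).fillna(0.0)
    keep = (act >= fpk_threshold).any(axis=1)
    sub = g[g["gene_id"].map(keep).fillna(False)]
    return pd.DataFrame({
        "gene_id": sub["gene_id"].to_numpy(),
        "chrom": sub["chrom"].to_numpy(),
        "tss": [int(tss[gid]) for gid in sub["gene_id"]],
        "strand": sub["strand"].to_numpy(),
    })


def _midpoints(enhancers: pd.DataFrame) -> np.ndarray:
    return ((enhancers["start"] + enhancers["end"]) // 2).to_numpy()


def _pearson_log(a: np.ndarray, b: np.ndarray) -> float:
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if la.std() == 0 or lb.std() == 0:
        return np.nan
    return float(np.corrcoef(la, lb)[0, 1])


def pair_nearest(enhancers: pd.DataFrame, promoters: pd.DataFrame,
                 max_distance: int = MAX_DISTANCE) -> pd.DataFrame:
    """Each enhancer paired to its nearest active promoter (< 500 kbp).

    Equidistant promoters are broken toward the leftmost TSS.
    """
    rows = []
    mids = _midpoints(enhancers)
    for (_, e), mid in zip(enhancers.iterrows(), mids):
        cand = promoters[promoters["chrom"] == e["chrom"]]
        if cand.empty:
            continue
        dist = np.abs(cand["tss"].to_numpy() - mid)
        order = np.lexsort((cand["tss"].to_numpy(), dist))
        best = order[0]
        if dist[best] < max_distance:
            rows.append({
                "enhancer_id": e["enhancer_id"],
                "gene_id": cand.iloc[best]["gene_id"],
                "method": "N", "distance": int(dist[best]),
                "r": np.nan, "skip": False,
            })
    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "method",
                                       "distance", "r", "skip"])


def pair_correlated_neighboring(enhancers: pd.DataFrame, promoters: pd.DataFrame,
                                enhancer_activity: pd.DataFrame,
                                promoter_activity: pd.DataFrame,
                                r_cutoff: float = R_CUTOFF,
                                max_distance: int = MAX_DISTANCE) -> pd.DataFrame:
    """Nearest active promoter on each side, kept when r > cutoff."""
    rows = []
    mids = _midpoints(enhancers)
    for (_, e), mid in zip(enhancers.iterrows(), mids):
        cand = promoters[promoters["chrom"] == e["chrom"]]
        if cand.empty:
            continue
        tss = cand["tss"].to_numpy()
        left, right = cand[tss <= mid], cand[tss > mid]
        up = left.loc[[left["tss"].idxmax()]] if not left.empty else None
        down = right.loc[[right["tss"].idxmin()]] if not right.empty else None
        for side in (up, down):
            if side is None:
                continue
            p = side.iloc[0]
            dist = abs(int(p["tss"]) - int(mid))
            if dist >= max_distance:
                continue
            r = _pearson_log(
                enhancer_activity.loc[e["enhancer_id"]].to_numpy(dtype=float),
                promoter_activity.loc[p["gene_id"]].to_numpy(dtype=float))
            if np.isfinite(r) and r > r_cutoff:
                rows.append({
                    "enhancer_id": e["enhancer_id"], "gene_id": p["gene_id"],
                    "method": "CN", "distance": dist, "r": r, "skip": False,
                })
    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "method",
                                       "distance", "r", "skip"])


def pair_correlated_window(enhancers: pd.DataFrame, promoters: pd.DataFrame,
                           enhancer_activity: pd.DataFrame,
                           promoter_activity: pd.DataFrame,
                           window: int = MAX_DISTANCE,
                           r_cutoff: float = R_CUTOFF,
                           keep_all_candidates: bool = False) -> pd.DataFrame:
    """All active promoters within +/- window, kept when r > cutoff.

    Each kept pair carries a ``skip`` flag: True when at least one other
    active promoter lies strictly between the enhancer midpoint and the
    target TSS.  With ``keep_all_candidates`` the unfiltered candidate table
    (every in-window pair with its distance and r) is returned instead.
    """
    rows = []
    mids = _midpoints(enhancers)
    for (_, e), mid in zip(enhancers.iterrows(), mids):
        cand = promoters[promoters["chrom"] == e["chrom"]]
        tss = cand["tss"].to_numpy()
        in_window = np.abs(tss - mid) < window
        sub = cand[in_window]
        for _, p in sub.iterrows():
            t = int(p["tss"])
            lo, hi = min(mid, t), max(mid, t)
            between = ((tss > lo) & (tss < hi)
                       & (cand["gene_id"] != p["gene_id"]).to_numpy())
            r = _pearson_log(
                enhancer_activity.loc[e["enhancer_id"]].to_numpy(dtype=float),
                promoter_activity.loc[p["gene_id"]].to_numpy(dtype=float))
            passed = np.isfinite(r) and r > r_cutoff
            if keep_all_candidates or passed:
                rows.append({
                    "enhancer_id": e["enhancer_id"], "gene_id": p["gene_id"],
                    "method": "CW", "distance": abs(t - int(mid)), "r": r,
                    "skip": bool(between.any()),
                    "passed": passed,
                })
    df = pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "method",
                                     "distance", "r", "skip", "passed"])
    if not keep_all_candidates:
        df = df.drop(columns="passed")
    return df


def attribute_cell_lines(pairs: pd.DataFrame,
                         enhancer_active: pd.DataFrame,
                         promoter_active: pd.DataFrame) -> pd.DataFrame:
    """Add per-pair cell-line provenance.

    A pair exists in cell line c iff the enhancer and the promoter are both
    active there (boolean matrices, features x cell lines).
    """
    out = pairs.copy()
    lines = list(enhancer_active.columns)
    provenance = []
    for _, p in out.iterrows():
        e_act = enhancer_active.loc[p["enhancer_id"]] \
            if p["enhancer_id"] in enhancer_active.index else None
        g_act = promoter_active.loc[p["gene_id"]] \
            if p["gene_id"] in promoter_active.index else None
        if e_act is None or g_act is None:
            provenance.append("")
            continue
        both = [ln for ln in lines if bool(e_act[ln]) and bool(g_act[ln])]
        provenance.append(",".join(both))
    out["cell_lines"] = provenance
    return out


def pairing_summaries(pairs: pd.DataFrame) -> dict:
    """Per-promoter enhancer counts (per cell line and union) and the
    neighbor-only / skipped-only / both fractions of paired enhancers."""
    if pairs.empty:
        return {"per_line_mean_enhancers_per_promoter": {},
                "union_mean_enhancers_per_promoter": float("nan"),
                "fraction_neighbor_only": float("nan"),
                "fraction_skipped_only": float("nan"),
                "fraction_both": float("nan")}
    per_line: dict[str, float] = {}
    if "cell_lines" in pairs:
        lines = sorted({ln for s in pairs["cell_lines"] for ln in s.split(",") if ln})
        for ln in lines:
            sub = pairs[pairs["cell_lines"].str.split(",").map(lambda x: ln in x)]
            if not sub.empty:
                per_line[ln] = float(
                    sub.groupby("gene_id")["enhancer_id"].nunique().mean())
    union_mean = float(pairs.groupby("gene_id")["enhancer_id"].nunique().mean())
    by_enh = pairs.groupby("enhancer_id")["skip"].agg(["any", "all"])
    neighbor_only = float((~by_enh["any"]).mean())
    skipped_only = float(by_enh["all"].mean())
    both = 1.0 - neighbor_only - skipped_only
    return {
        "per_line_mean_enhancers_per_promoter": per_line,
        "union_mean_enhancers_per_promoter": union_mean,
        "fraction_neighbor_only": neighbor_only,
        "fraction_skipped_only": skipped_only,
        "fraction_both": both,
    }


def audit_pairs(pairs: pd.DataFrame, max_distance: int = MAX_DISTANCE,
                r_cutoff: float = R_CUTOFF):
    """Post-hoc contract check: raises on any distance/correlation violation."""
    if pairs.empty:
        return
    if (pairs["distance"] >= max_distance).any():
        raise AssertionError("pair exceeds the distance limit")
    corr = pairs[pairs["method"].isin(["CN", "CW"])]
    if (corr["r"] <= r_cutoff).any():
        raise AssertionError("CN/CW pair at or below the correlation cutoff")
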