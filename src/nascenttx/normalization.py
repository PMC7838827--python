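"""Between-sample normalization and length-normalized activity (FPK).

Samples are made comparable with the median-of-ratios size-factor estimator:
``s_j = median_i k_ij / (prod_j k_ij)^(1/m)`` over features with a nonzero
count in every sample.  Counts divided by ``s_j`` are "normalized counts";
dividing further by feature length in kb gives normalized FPK (fragments per
kilobase), the activity unit used throughout the pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Features with a zero count in any sample are excluded from the median;
    at least one all-sample-nonzero feature is required.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    keep = np.all(mat > 0, axis=1)
    if not keep.any():
        raise ValueError("no feature has nonzero counts in all samples")
    sub = mat[keep]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    s = pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")
    gm = float(np.exp(np.mean(np.log(s))))
    if not 0.5 < gm < 2.0:
        warnings.warn(
            f"geometric mean of size factors is {gm:.3g}; "
            "samples may be poorly comparable", stacklevel=2,
        )
    return s


def fpk(counts: pd.DataFrame, factors: pd.Series,
        effective_lengths: pd.Series) -> pd.DataFrame:
    """Normalized fragments per kilobase: (k_ij / s_j) / (L_i / 1000)."""
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing effective length for some features")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    norm = counts.div(factors.reindex(counts.columns), axis=1)
    return norm.div(lengths / 1000.0, axis=0)


def replicate_average(per_sample: pd.DataFrame,
                      sample_to_line: dict[str, str]) -> pd.DataFrame:
    """Arithmetic mean over replicate columns, one column per cell line."""
    groups = pd.Series(sample_to_line).reindex(per_sample.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a cell-line assignment")
    return per_sample.T.groupby(groups).mean().T


def classify_active(per_sample_fpk: pd.DataFrame,
                    sample_to_line: dict[str, str],
                    threshold_mean: float = 20.0,
                    threshold_per_replicate: float = 15.0) -> pd.DataFrame:
    """Active calls per feature per cell line.

    A feature is active in a cell line iff its replicate-averaged FPK is at
    least ``threshold_mean`` and every single replicate reaches
    ``threshold_per_replicate``.
    """
    groups = pd.Series(sample_to_line).reindex(per_sample_fpk.columns)
    mean_ok = per_sample_fpk.T.groupby(groups).mean().T >= threshold_mean
    min_ok = per_sample_fpk.T.groupby(groups).min().T >= threshold_per_replicate
    return mean_ok & min_ok


def density_valley_cutoff(log2_fpk: np.ndarray,
                          grid: int = 512) -> float | None:
    """Optional diagnostic: valley of a bimodal log2(FPK) density.

    Returns the FPK value at the deepest local minimum of a Gaussian
    kernel-density estimate between the two largest modes, or None when the
    density has fewer than two modes.
    """
    from scipy.stats import gaussian_kde

    vals = np.asarray(log2_fpk, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 10:
        return None
    kde = gaussian_kde(vals)
    xs = np.linspace(vals.min(), vals.max(), grid)
    dens = kde(xs)
    d = np.diff(dens)
    maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    if len(maxima) < 2:
        return None
    top2 = sorted(sorted(maxima, key=lambda i: -dens[i])[:2])
    valley = top2[0] + int(np.argmin(dens[top2[0]:top2[1] + 1]))
    return float(2 ** xs[valley])
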