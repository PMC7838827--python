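"""Two-state genome segmentation from binned nascent-transcription coverage.

A hidden Markov model with a Poisson-log-normal emission separates
"transcribed" from "untranscribed" bins: the count in a bin is Poisson with
rate ``exp(mu_s + sigma_s * Z)``, ``Z ~ N(0, 1)``, so the log-normal mixing
absorbs the strong overdispersion of nascent-RNA coverage.  The marginal
emission likelihood is integrated by Gauss-Hermite quadrature.  Maximal runs
of the transcribed state become transcription units (TUs), whose boundaries
can then be refined by a two-segment piecewise-constant fit around each
bin-resolution edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from ._hmm_kernels import forward_backward, viterbi
from .genomic_io import BinnedCoverage

SIGMA_FLOOR = 1e-3
SIGMA_CAP = 5.0          # an all-zero state is otherwise unidentifiable
MU_FLOOR = np.log(1e-6)  # rate floor so the quiet state can emit zeros


@dataclass
class HmmModel:
    """Fitted two-state Poisson-log-normal HMM.

    State 0 is "untranscribed", state 1 "transcribed" (mu[1] > mu[0] by
    construction; states are re-ordered after fitting).
    """

    mu: np.ndarray                 # log-mean of the Poisson rate, per state
    sigma: np.ndarray              # log-sd of the Poisson rate, per state
    transmat: np.ndarray           # (2, 2) row-stochastic
    startprob: np.ndarray
    n_nodes: int = 20
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.clip(np.asarray(self.sigma, dtype=float),
                             SIGMA_FLOOR, SIGMA_CAP)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")

    def emission_logprob(self, counts: np.ndarray) -> np.ndarray:
        """(T, 2) log-likelihood of each count under each state."""
        uniq, inv = np.unique(counts, return_inverse=True)
        table = np.stack(
            [_pln_logpmf(uniq, self.mu[s], self.sigma[s], self.n_nodes)
             for s in range(2)], axis=1,
        )
        return table[inv]

    def to_yaml(self, path: str):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "mu": self.mu.tolist(),
                    "sigma": self.sigma.tolist(),
                    "transmat": self.transmat.tolist(),
                    "startprob": self.startprob.tolist(),
                    "n_nodes": self.n_nodes,
                    "loglik_trace": [float(x) for x in self.loglik_trace],
                }, fh,
            )

    @classmethod
    def from_yaml(cls, path: str) -> "HmmModel":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            mu=np.array(d["mu"]), sigma=np.array(d["sigma"]),
            transmat=np.array(d["transmat"]), startprob=np.array(d["startprob"]),
            n_nodes=d["n_nodes"], loglik_trace=d.get("loglik_trace", []),
        )


def _pln_logpmf(k: np.ndarray, mu: float, sigma: float, n_nodes: int) -> np.ndarray:
    """Poisson-log-normal log pmf via Gauss-Hermite quadrature.

    P(k) = int Pois(k; exp(mu + sigma z)) phi(z) dz with phi the standard
    normal density, approximated at ``n_nodes`` Hermite nodes.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    log_rate = np.clip(mu + sigma * np.sqrt(2.0) * nodes, None, 300.0)
    k = np.asarray(k, dtype=float)
    # (len(k), n): k*log(rate) - rate, gammaln added once below
    terms = k[:, None] * log_rate[None, :] - np.exp(log_rate)[None, :]
    logw = np.log(weights) - 0.5 * np.log(np.pi)
    return logsumexp(terms + logw[None, :], axis=1) - gammaln(k + 1.0)


def _as_sequences(coverage) -> list[np.ndarray]:
    if isinstance(coverage, BinnedCoverage):
        return [coverage.data[c] for c in sorted(coverage.data)]
    if isinstance(coverage, dict):
        seqs = []
        for strand in sorted(coverage):
            seqs.extend(_as_sequences(coverage[strand]))
        return seqs
    if isinstance(coverage, np.ndarray):
        return [coverage]
    return [np.asarray(s) for s in coverage]


def fit_hmm(coverage, max_iter: int = 100, tol: float = 1e-3,
            seed: int = 0, n_nodes: int = 20) -> HmmModel:
    """Fit the two-state Poisson-log-normal HMM by Baum-Welch EM.

    ``coverage`` may be a :class:`BinnedCoverage`, a dict of them (e.g. one
    per strand), an array, or a list of arrays; sequences are modelled as
    independent chains sharing parameters.  The returned model carries a
    non-decreasing log-likelihood trace (up to numerical tolerance).  EM
    stops when the gain drops below ``tol`` or after ``max_iter`` iterations.
    """
    seqs = [np.asarray(s, dtype=np.int64) for s in _as_sequences(coverage)]
    total_bins = sum(len(s) for s in seqs)
    if total_bins < 100:
        raise ValueError("need at least 100 bins to fit the segmentation HMM")
    concat = np.concatenate(seqs)
    if concat.max() == 0:
        raise ValueError(
            "all-zero coverage: nothing to segment, skip segmentation for "
            "this sample"
        )

    model = _init_model(concat, seed=seed, n_nodes=n_nodes)
    prev_ll = -np.inf
    for it in range(max_iter):
        stats, ll = _e_step(model, seqs)
        model.loglik_trace.append(ll)
        if np.isinf(tol):
            break  # any gain counts as converged: return the initialization
        if it > 0 and ll - prev_ll < tol:
            break
        prev_ll = ll
        _m_step(model, stats)
    _order_states(model)
    return model


def _init_model(concat: np.ndarray, seed: int, n_nodes: int) -> HmmModel:
    """Seed state means by 2-means on log1p(counts)."""
    from sklearn.cluster import KMeans

    x = np.log1p(concat.astype(float))
    rng = np.random.default_rng(seed)
    sample = x if len(x) <= 50_000 else rng.choice(x, 50_000, replace=False)
    km = KMeans(n_clusters=2, n_init=1, random_state=seed).fit(sample[:, None])
    centers = np.sort(km.cluster_centers_.ravel())
    sigma0 = 0.5
    mu = np.maximum(np.log(np.maximum(np.expm1(centers), 1e-6)) - sigma0 ** 2 / 2,
                    MU_FLOOR)
    if mu[1] - mu[0] < 0.1:  # degenerate clustering; force separation
        mu[1] = mu[0] + 1.0
    return HmmModel(
        mu=mu, sigma=np.array([sigma0, sigma0]),
        transmat=np.array([[0.99, 0.01], [0.01, 0.99]]),
        startprob=np.array([0.5, 0.5]), n_nodes=n_nodes,
    )


def _e_step(model: HmmModel, seqs: list[np.ndarray]):
    xi_total = np.zeros((2, 2))
    start_total = np.zeros(2)
    ll_total = 0.0
    # per-state weights per unique count, accumulated across sequences
    weight_maps: list[dict[int, float]] = [dict(), dict()]
    for seq in seqs:
        logb = model.emission_logprob(seq)
        offset = logb.max(axis=1)
        b = np.exp(logb - offset[:, None])
        gamma, xi, ll = forward_backward(b, model.transmat, model.startprob)
        ll_total += ll + offset.sum()
        xi_total += xi
        start_total += gamma[0]
        uniq, inv = np.unique(seq, return_inverse=True)
        for s in range(2):
            w = np.zeros(len(uniq))
            np.add.at(w, inv, gamma[:, s])
            for u, wu in zip(uniq, w):
                weight_maps[s][int(u)] = weight_maps[s].get(int(u), 0.0) + wu
    return (weight_maps, xi_total, start_total, len(seqs)), ll_total


def _m_step(model: HmmModel, stats):
    weight_maps, xi_total, start_total, n_seq = stats
    trans = xi_total / np.maximum(xi_total.sum(axis=1, keepdims=True), 1e-300)
    model.transmat = np.clip(trans, 1e-12, None)
    model.transmat /= model.transmat.sum(axis=1, keepdims=True)
    model.startprob = np.clip(start_total / n_seq, 1e-12, None)
    model.startprob /= model.startprob.sum()

    for s in range(2):
        ks = np.array(sorted(weight_maps[s]))
        ws = np.array([weight_maps[s][int(k)] for k in ks])
        keep = ws > 1e-12
        ks, ws = ks[keep], ws[keep]
        if len(ks) == 0:
            continue

        def nll(theta, ks=ks, ws=ws):
            mu, log_sigma = theta
            sigma = min(max(np.exp(log_sigma), SIGMA_FLOOR), SIGMA_CAP)
            return -np.sum(ws * _pln_logpmf(ks, mu, sigma, model.n_nodes))

        x0 = np.array([model.mu[s], np.log(model.sigma[s])])
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-6})
        # generalized EM: only accept parameters that improve the Q-term
        if res.fun < nll(x0):
            model.mu[s] = max(res.x[0], MU_FLOOR)
            model.sigma[s] = min(max(np.exp(res.x[1]), SIGMA_FLOOR), SIGMA_CAP)


def _order_states(model: HmmModel):
    """Ensure state 1 is the transcribed (higher-rate) state."""
    if model.mu[0] > model.mu[1]:
        perm = [1, 0]
        model.mu = model.mu[perm]
        model.sigma = model.sigma[perm]
        model.startprob = model.startprob[perm]
        model.transmat = model.transmat[np.ix_(perm, perm)]


# ---------------------------------------------------------------------------
# decoding and TU post-processing
# ---------------------------------------------------------------------------

def decode_states(counts: np.ndarray, model: HmmModel) -> np.ndarray:
    """Viterbi state path for one bin-count vector (0/1 per bin)."""
    logb = model.emission_logprob(np.asarray(counts, dtype=np.int64))
    return viterbi(logb, np.log(model.transmat), np.log(model.startprob))


def decode_tus(coverage: dict[str, BinnedCoverage], model: HmmModel,
               prefix: str = "TU") -> pd.DataFrame:
    """Call transcription units as maximal runs of the transcribed state.

    ``coverage`` maps strand -> BinnedCoverage.  Returns a TU table with
    bin-resolution boundaries and class label 'unclassified'.
    """
    rows = []
    for strand in sorted(coverage):
        cov = coverage[strand]
        bw = cov.bin_width
        for chrom in sorted(cov.data):
            path = decode_states(cov.data[chrom], model)
            edges = np.flatnonzero(np.diff(np.concatenate([[0], path, [0]])))
            for s_bin, e_bin in zip(edges[::2], edges[1::2]):
                rows.append((chrom, int(s_bin) * bw, int(e_bin) * bw, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df = df.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)
    df["tu_id"] = [f"{prefix}_{i:06d}" for i in range(len(df))]
    df["klass"] = "unclassified"
    return df[["tu_id", "chrom", "start", "end", "strand", "klass"]]


def tu_tss(tus: pd.DataFrame) -> pd.Series:
    """Strand-aware 5' end of each TU."""
    return pd.Series(
        np.where(tus["strand"] == "+", tus["start"], tus["end"]),
        index=tus.index, name="tss",
    )


def merge_gaps(tus: pd.DataFrame, max_gap_bp: int = 200,
               merge_classes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Merge same-strand TUs separated by at most ``max_gap_bp``.

    Only rows whose class is in ``merge_classes`` participate (default: every
    class except mRNA, i.e. the non-coding TUs); other rows pass through.
    """
    if tus.empty:
        return tus.copy()
    if merge_classes is None:
        mergeable = tus["klass"] != "mRNA"
    else:
        mergeable = tus["klass"].isin(merge_classes)
    keep = tus[~mergeable]
    rows = []
    for (chrom, strand), sub in tus[mergeable].groupby(["chrom", "strand"]):
        sub = sub.sort_values("start")
        cur = None
        for _, r in sub.iterrows():
            if cur is None or r["start"] - cur["end"] > max_gap_bp:
                if cur is not None:
                    rows.append(cur)
                cur = r.copy()
            else:
                cur["end"] = max(cur["end"], r["end"])
        rows.append(cur)
    out = pd.concat([keep, pd.DataFrame(rows)], ignore_index=True)
    return out.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


def best_changepoint(y: np.ndarray) -> int | None:
    """Exhaustive two-segment constant fit; index of the best split.

    Returns the split ``i`` (segments y[:i], y[i:]) minimizing the residual
    sum of squares, or None when no split improves on a single segment.
    Ties go to the smallest index.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        return None
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csq = np.concatenate([[0.0], np.cumsum(y * y)])

    def rss(a, b):  # RSS of y[a:b] around its mean
        m = b - a
        s = csum[b] - csum[a]
        return (csq[b] - csq[a]) - s * s / m

    single = rss(0, n)
    splits = np.array([rss(0, i) + rss(i, n) for i in range(1, n)])
    best = int(np.argmin(splits)) + 1
    if splits[best - 1] >= single - 1e-12:
        return None
    return best


def refine_boundaries(tus: pd.DataFrame, profile_fn,
                      window_bp: int = 200) -> pd.DataFrame:
    """Snap TU boundaries to change-points of the local coverage profile.

    For each boundary, the two bins around it (``[b - window_bp, b +
    window_bp)``) are scanned for the split minimizing the two-segment
    constant-fit RSS.  ``profile_fn(chrom, start, end, strand)`` must return
    per-bp coverage for the window; when only bin-level data exist, the
    caller expands bins to bp and refinement snaps to the best bin edge.
    Boundaries never move by more than ``2 * window_bp``.
    """
    out = tus.copy()
    for idx, r in tus.iterrows():
        for which in ("start", "end"):
            b = int(r[which])
            lo = max(b - window_bp, 0)
            y = np.asarray(profile_fn(r["chrom"], lo, b + window_bp, r["strand"]),
                           dtype=float)
            if len(y) < 2:
                continue
            cp = best_changepoint(y)
            if cp is not None:
                new = lo + cp
                if which == "start" and new < int(out.at[idx, "end"]):
                    out.at[idx, "start"] = new
                elif which == "end" and new > int(out.at[idx, "start"]):
                    out.at[idx, "end"] = new
    return out
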