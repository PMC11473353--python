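"""Information dynamics of spike trains and continuous series.

Estimators used to quantify motor autonomy and dyadic causal
influence:

* Shannon entropy of a symbol table.
* Approximate entropy (ApEn) — the count-ratio approximation of the
  entropy rate: for templates of length m and m+1 under Chebyshev
  distance with tolerance r, the mean log ratio of m-template to
  (m+1)-template match counts.  On a K-symbol alphabet the entropy
  rate lives in (0, log_base K); a binary spike train therefore maps
  onto an autonomy scale from fully deterministic (0) to fully random
  (1 bit).
* Average mutual information (AMI) across lags; the first local
  minimum gives the embedding delay, the time scale at which the
  dynamics decorrelate.
* Transfer entropy (TE), the plug-in estimate of
  E[log p(x_{n+1} | x-history, y-history) - log p(x_{n+1} | x-history)],
  its per-transition local values, and its decomposition
  TE = h_X - h_{X,Y}: the target's conditional entropy rate minus the
  source-conditioned (generalized) entropy rate.

All plug-in quantities are computed over empirical word counts after
integer-encoding histories, so the identities mean(local TE) == TE and
TE == h_X - h_{X,Y} hold to floating-point rounding by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, InputError

logger = logging.getLogger(__name__)


@dataclass
class ApEnEstimate:
    value: float
    m: int
    r: float
    N: int
    base: float


@dataclass
class TEEstimate:
    value: float
    k: int
    l: int
    n_eff: int
    base: float
    estimator: str = "plugin"
    h_x: float = float("nan")
    h_xy: float = float("nan")


@dataclass
class EmbeddingDelay:
    delay: int
    ami_curve: np.ndarray  # AMI at lags 1..max_lag, in log_base units
    fallback: bool = False


def shannon_entropy(counts, base: float = 2.0) -> float:
    """Shannon entropy -sum p log_base p of a frequency table.

    ``counts`` may be a mapping symbol -> count or an array of
    non-negative counts.
    """
    if hasattr(counts, "values") and not isinstance(counts, np.ndarray):
        c = np.asarray(list(counts.values()), dtype=float)
    else:
        c = np.asarray(counts, dtype=float).ravel()
    if np.any(c < 0):
        raise InputError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise InputError("all-zero counts: entropy undefined")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def _exact_counts(codes: np.ndarray, n_symbols: int, m_len: int, n_t: int) -> np.ndarray:
    """Multiplicity of each of the first ``n_t`` length-``m_len`` words."""
    words = np.zeros(n_t, dtype=np.int64)
    mult = 1
    for j in range(m_len - 1, -1, -1):
        words += codes[j:j + n_t].astype(np.int64) * mult
        mult *= n_symbols
    _, inv, cnt = np.unique(words, return_inverse=True, return_counts=True)
    return cnt[inv]


def _chebyshev_counts(x: np.ndarray, m_len: int, r: float, n_t: int) -> np.ndarray:
    """Match counts under Chebyshev distance < r for the first n_t templates."""
    emb = np.lib.stride_tricks.sliding_window_view(x, m_len)[:n_t]
    counts = np.zeros(n_t, dtype=np.int64)
    chunk = max(1, int(4e7) // max(n_t * m_len, 1))
    for lo in range(0, n_t, chunk):
        hi = min(lo + chunk, n_t)
        d = np.abs(emb[lo:hi, None, :] - emb[None, :, :]).max(axis=2)
        counts[lo:hi] = (d < r).sum(axis=1)
    return counts


def approximate_entropy(x, m: int, r: float, base: float = 2.0) -> ApEnEstimate:
    """Approximate entropy ApEn(m, r, N) as an entropy-rate estimate.

    The mean over the first N-m template positions i of log_base of
    C_m(i) / C_{m+1}(i), where C_m(i) counts templates within
    Chebyshev distance r of template i (both sums run over the same
    N-m positions, self-match included, so every ratio is well
    defined).  A constant series gives exactly 0.  When all distinct
    sample values differ by at least r, matching reduces to exact
    symbol equality and an O(N) word-count path is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    N = len(x)
    if r <= 0:
        raise InputError("tolerance r must be positive")
    if m < 1:
        raise InputError("template length m must be >= 1")
    if N <= m + 1:
        raise InputError(f"need N > m+1 samples (N={N}, m={m})")

    n_t = N - m  # both template lengths evaluated at positions 0..n_t-1
    uniq = np.unique(x)
    exact = len(uniq) == 1 or np.diff(uniq).min() >= r
    if exact:
        codes = np.searchsorted(uniq, x)
        c_m = _exact_counts(codes, len(uniq), m, n_t)
        c_m1 = _exact_counts(codes, len(uniq), m + 1, n_t)
    else:
        c_m = _chebyshev_counts(x, m, r, n_t)
        c_m1 = _chebyshev_counts(x, m + 1, r, n_t)
    value = float(np.mean(np.log(c_m / c_m1)) / np.log(base))
    return ApEnEstimate(value=value, m=m, r=r, N=N, base=base)


def average_mutual_information(x, max_lag: int = 64, n_bins: int = 16,
                               base: float = 2.0) -> EmbeddingDelay:
    """AMI across lags 1..max_lag; embedding delay at its first local minimum.

    AMI(tau) = I(x_t ; x_{t+tau}) from an equal-width histogram
    estimator (exact symbols when the series takes <= n_bins distinct
    values).  The delay is the first lag that is a local minimum of
    the AMI curve, treating the lag-0 AMI (= H(x), the maximum) as the
    left boundary; if no local minimum exists up to max_lag the argmin
    is returned with ``fallback=True`` and a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) == 0 or np.ptp(x) == 0:
        raise DegenerateDataError("constant series: AMI undefined")
    if len(x) <= 2 * max_lag:
        raise InputError(f"series length {len(x)} too short for max_lag={max_lag}")
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        codes = np.searchsorted(uniq, x)
        nb = len(uniq)
    else:
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
        codes = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
        nb = n_bins
    logb = np.log(base)

    def mi(a, b):
        joint = np.bincount(a * nb + b, minlength=nb * nb).astype(float)
        joint /= joint.sum()
        pab = joint.reshape(nb, nb)
        pa = pab.sum(axis=1)
        pb = pab.sum(axis=0)
        nzm = pab > 0
        denom = np.outer(pa, pb)
        return float((pab[nzm] * np.log(pab[nzm] / denom[nzm])).sum() / logb)

    ami0 = mi(codes, codes)
    ami = np.array([mi(codes[:-tau], codes[tau:]) for tau in range(1, max_lag + 1)])
    curve = np.concatenate(([ami0], ami))
    delay, fallback = None, False
    for tau in range(1, max_lag):
        if curve[tau] < curve[tau - 1] and curve[tau] <= curve[tau + 1]:
            delay = tau
            break
    if delay is None:
        delay = int(np.argmin(ami)) + 1
        fallback = True
        logger.warning("no local AMI minimum up to lag %d; using argmin %d",
                       max_lag, delay)
    return EmbeddingDelay(delay=delay, ami_curve=ami, fallback=fallback)


def _te_transition_table(pairs, k: int, l: int):
    """Integer-coded (x_next, x-history, y-history) rows pooled over segments.

    ``pairs`` is a list of (x_target, y_source) array pairs; rows are
    pooled across segments without crossing their boundaries.  Series
    symbols are mapped to a common 0..K-1 alphabet first.
    """
    xs, ys = [], []
    for x, y in pairs:
        xa = np.asarray(x).ravel()
        ya = np.asarray(y).ravel()
        if len(xa) != len(ya):
            raise InputError("target and source must have equal length")
        xs.append(xa)
        ys.append(ya)
    symbols = np.unique(np.concatenate(xs + ys))
    ns = max(len(symbols), 2)
    rows_x1, rows_xk, rows_yl = [], [], []
    for xa, ya in zip(xs, ys):
        xc = np.searchsorted(symbols, xa).astype(np.int64)
        yc = np.searchsorted(symbols, ya).astype(np.int64)
        N = len(xc)
        m0 = max(k, l)
        if N <= m0 + 1:
            continue
        # wx[i] encodes x[i:i+k]; history ending at n-1 is wx[n-k]
        wx = np.zeros(N - k + 1, dtype=np.int64)
        mult = 1
        for j in range(k - 1, -1, -1):
            wx += xc[j:j + N - k + 1] * mult
            mult *= ns
        wy = np.zeros(N - l + 1, dtype=np.int64)
        mult = 1
        for j in range(l - 1, -1, -1):
            wy += yc[j:j + N - l + 1] * mult
            mult *= ns
        n_idx = np.arange(m0, N)
        rows_x1.append(xc[n_idx])
        rows_xk.append(wx[n_idx - k])
        rows_yl.append(wy[n_idx - l])
    if not rows_x1:
        raise InputError("no segment long enough for the requested histories "
                         f"(k={k}, l={l})")
    return (np.concatenate(rows_x1), np.concatenate(rows_xk),
            np.concatenate(rows_yl), ns)


def _group_counts(*key_parts) -> np.ndarray:
    """For each row of the stacked key columns, its multiplicity."""
    if len(key_parts) == 1:
        keys = key_parts[0]
        _, inv, cnt = np.unique(keys, return_inverse=True, return_counts=True)
        return cnt[inv]
    stacked = np.stack(key_parts)
    _, inv, cnt = np.unique(stacked, axis=1, return_inverse=True,
                            return_counts=True)
    return cnt[np.asarray(inv).ravel()]


def _te_count_tables(x1, xk, yl, ns, k, l):
    """(c_xk, c_x1xk, c_xkyl, c_all) multiplicities per transition row."""
    # pack into a single int64 key when the alphabet allows it
    if np.log2(ns) * (k + l + 1) < 62:
        span_k = ns ** k
        key_x1xk = x1 + xk * ns
        key_xkyl = xk + yl * span_k
        key_all = x1 + xk * ns + yl * (span_k * ns)
        return (_group_counts(xk), _group_counts(key_x1xk),
                _group_counts(key_xkyl), _group_counts(key_all))
    return (_group_counts(xk), _group_counts(x1, xk),
            _group_counts(xk, yl), _group_counts(x1, xk, yl))


def local_transfer_entropy(x_target, y_source, k: int = 20, l: int | None = None,
                           base: float = 2.0, pairs=None) -> np.ndarray:
    """Per-transition local TE values t_{Y->X}(n+1, k, l).

    Each value is log_base p(x_{n+1}|x_k, y_l) - log_base p(x_{n+1}|x_k)
    under the pooled empirical distribution; individual values may be
    negative although their mean (the average TE) cannot.
    """
    if l is None:
        l = k
    if pairs is None:
        pairs = [(x_target, y_source)]
    x1, xk, yl, ns = _te_transition_table(pairs, k, l)
    c_xk, c_x1xk, c_xkyl, c_all = _te_count_tables(x1, xk, yl, ns, k, l)
    return (np.log(c_all / c_xkyl) - np.log(c_x1xk / c_xk)) / np.log(base)


def entropy_rate_decomposition(x_target, y_source, k: int = 20, l: int | None = None,
                               base: float = 2.0, pairs=None):
    """(h_X, h_{X,Y}, TE) with TE = h_X - h_{X,Y} by construction.

    h_X is the plug-in conditional entropy rate of the target given
    its own k-history; h_{X,Y} additionally conditions on the
    source's l-history (the generalized entropy rate).  Their
    difference is the transfer entropy.
    """
    if l is None:
        l = k
    if pairs is None:
        pairs = [(x_target, y_source)]
    x1, xk, yl, ns = _te_transition_table(pairs, k, l)
    c_xk, c_x1xk, c_xkyl, c_all = _te_count_tables(x1, xk, yl, ns, k, l)
    logb = np.log(base)
    h_x = float(-np.mean(np.log(c_x1xk / c_xk)) / logb)
    h_xy = float(-np.mean(np.log(c_all / c_xkyl)) / logb)
    te = TEEstimate(value=h_x - h_xy, k=k, l=l,
                    n_eff=len(x1), base=base, h_x=h_x, h_xy=h_xy)
    return h_x, h_xy, te


def transfer_entropy(x_target, y_source, k: int = 20, l: int | None = None,
                     base: float = 2.0, pairs=None,
                     shuffle_correct: bool = False, n_shuffle: int = 20,
                     seed: int = 0) -> TEEstimate:
    """Plug-in transfer entropy T_{Y->X}(k, l) in units of log_base.

    The expectation of the local TE values; non-negative up to
    floating error because it is the empirical conditional mutual
    information I(x_{n+1}; y-history | x-history).  ``pairs`` pools
    word counts across multiple segments (e.g. the windows of a
    session) without crossing segment boundaries.  With
    ``shuffle_correct`` the mean TE of ``n_shuffle`` seeded
    source-shuffled surrogates is subtracted and the result clipped
    at zero.
    """
    if l is None:
        l = k
    _, _, te = entropy_rate_decomposition(x_target, y_source, k=k, l=l,
                                          base=base, pairs=pairs)
    if not shuffle_correct:
        return te
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = [(x_target, y_source)]
    null = []
    for _ in range(n_shuffle):
        shuf = [(x, rng.permutation(np.asarray(y).ravel())) for x, y in pairs]
        _, _, te_s = entropy_rate_decomposition(None, None, k=k, l=l,
                                                base=base, pairs=shuf)
        null.append(te_s.value)
    corrected = max(0.0, te.value - float(np.mean(null)))
    return TEEstimate(value=corrected, k=k, l=l, n_eff=te.n_eff, base=base,
                      estimator="plugin_shuffle_corrected",
                      h_x=te.h_x, h_xy=te.h_xy)


def auto_template_length(bits: np.ndarray, cap: int = 10) -> int:
    """Template length = rounded mean inter-spike interval, capped.

    Chosen so that an embedded template typically spans both quiet
    samples and a spike; the cap guards against degenerate
    undersampling when spikes are very sparse (hitting it is logged).
    """
    idx = np.flatnonzero(np.asarray(bits).ravel())
    if len(idx) < 2:
        logger.info("fewer than 2 spikes; template length defaults to 1")
        return 1
    m = int(round(float(np.mean(np.diff(idx)))))
    m = max(m, 1)
    if m > cap:
        logger.info("auto template length %d capped at %d", m, cap)
        m = cap
    return m
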