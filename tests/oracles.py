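"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles (definition sums,
exhaustive enumeration) without touching the package's implementation paths.
"""

from itertools import combinations, product

import numpy as np
import scipy.stats as st


def dft_oracle(x, fs=8.0):
    """O(n^2) DFT-by-definition recomputation of all ten spectral descriptors."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = np.arange(n // 2 + 1)
    F = np.array([np.sum(x * np.exp(-2j * np.pi * kk * np.arange(n) / n)) for kk in k])
    mag = np.abs(F)
    P = mag**2

    def entropy(shares):
        shares = shares[shares > 0]
        return float(-(shares * np.log(shares)).sum()) if shares.size else 0.0

    tp, tm = P.sum(), mag.sum()
    p_share = P / tp if tp > 0 else np.zeros_like(P)
    m_share = mag / tm if tm > 0 else np.zeros_like(mag)
    freqs = k * fs / n
    nondc = P[1:]
    peak_freq = float(freqs[1:][np.argmax(nondc)]) if nondc.max() > 0 else 0.0
    return {
        "fft_energy": float(P.sum()),
        "fft_mean_energy": float(P.mean()),
        "fft_std_energy": float(P.std(ddof=1)),
        "peak_power": float(p_share.max()) if tp > 0 else 0.0,
        "peak_dft_bin": float(np.argmax(mag)),
        "spectral_entropy": entropy(p_share),
        "peak_magnitude": float(mag.max()),
        "entropy": entropy(m_share),
        "peak_frequency": peak_freq,
        "peak_energy": float(P.max()),
    }


def brute_force_wilcoxon_p(d):
    """Two-sided exact p by enumerating every sign pattern of the ranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = st.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    total = ranks.sum()
    t_obs = min(observed, total - observed)
    n = len(ranks)
    hits = 0
    for signs in product([0, 1], repeat=n):
        t = sum(r for r, s in zip(ranks, signs) if s)
        if min(t, total - t) <= t_obs + 1e-9:
            hits += 1
    return hits / 2**n


def signed_rank_distribution_p(d):
    """Exact two-sided p via an independent convolution of rank distributions.

    Builds the null distribution of the positive-rank sum by convolving the
    two-point distributions {0, r_i} one rank at a time with numpy's
    ``convolve`` — a different mechanism from any cumulative-array DP.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = st.rankdata(np.abs(d))
    w = np.rint(2 * ranks).astype(int)
    dist = np.array([1.0])
    for wi in w:
        term = np.zeros(wi + 1)
        term[0] = term[wi] = 0.5
        dist = np.convolve(dist, term)
    t2 = int(np.rint(2 * ranks[d > 0].sum()))
    total = len(dist) - 1
    lo = min(t2, total - t2)
    p = dist[: lo + 1].sum() + dist[total - lo :].sum()
    if lo == total - lo:
        p -= dist[lo]
    return min(float(p), 1.0)


def brute_force_minimal_removal(df, cutoff):
    """Smallest removal set leaving all surviving pairs below the cutoff."""
    names = list(df.columns)
    corr = np.abs(np.corrcoef(df.to_numpy(), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    for k in range(len(names) + 1):
        for removed in combinations(range(len(names)), k):
            keep = [i for i in range(len(names)) if i not in removed]
            if len(keep) < 2 or corr[np.ix_(keep, keep)].max() < cutoff:
                return k
    return len(names)
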