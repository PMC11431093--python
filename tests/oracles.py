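"""Independent brute-force reference implementations.

Deliberately naive (explicit loops, Counter-based tallies, no shared code
with the package) so they can serve as oracles for the vectorized
estimators. Complexity is O(P^2) or worse; use only on tiny inputs.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def ordinal_pattern_bf(vector) -> tuple[int, ...]:
    """Ascending rank pattern, ties broken by earlier original position."""
    order = sorted(range(len(vector)), key=lambda i: (vector[i], i))
    return tuple(j + 1 for j in order)


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def mv_perm_entropy_bf(X, m: int, tau: int = 1) -> float:
    """Pooled ordinal-pattern Shannon entropy over ln(m!)."""
    X = _as_matrix(X)
    N, g = X.shape
    counts: Counter = Counter()
    for b in range(g):
        for i in range(N - (m - 1) * tau):
            window = [X[i + k * tau, b] for k in range(m)]
            counts[ordinal_pattern_bf(window)] += 1
    total = sum(counts.values())
    H = -sum((c / total) * math.log(c / total) for c in counts.values())
    return H / math.log(math.factorial(m))


def chebyshev_bf(a, b) -> float:
    return max(abs(x - y) for x, y in zip(a, b))


def mv_samp_entropy_bf(X, m: int, tau: int, r: float, standardize: bool = False) -> float:
    """Composite-vector sample entropy via explicit double loops.

    Extends each variate's dimension m -> m+1 in turn and averages the g
    match fractions, matching the estimator's stated convention. NaN when
    either match probability is zero.
    """
    X = _as_matrix(X)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    N, g = X.shape
    P = N - m * tau

    def composite(i, dims):
        out = []
        for b in range(g):
            for k in range(dims[b]):
                out.append(X[i + k * tau, b])
        return out

    def phi(dims):
        fractions = []
        for i in range(P):
            hits = 0
            for j in range(P):
                if j == i:
                    continue
                if chebyshev_bf(composite(i, dims), composite(j, dims)) <= r:
                    hits += 1
            fractions.append(hits / (P - 1))
        return sum(fractions) / P

    phi_m = phi([m] * g)
    extended = []
    for b in range(g):
        dims = [m] * g
        dims[b] = m + 1
        extended.append(phi(dims))
    phi_m1 = sum(extended) / g
    if phi_m == 0.0 or phi_m1 == 0.0:
        return float("nan")
    return -math.log(phi_m1 / phi_m)


def univariate_samp_entropy_bf(x, m: int, tau: int, r: float) -> float:
    """Classic univariate sample entropy: template pair counting."""
    x = np.asarray(x, dtype=float)
    P = len(x) - m * tau
    B = A = 0
    for i in range(P):
        for j in range(i + 1, P):
            if max(abs(x[i + k * tau] - x[j + k * tau]) for k in range(m)) <= r:
                B += 1
                if abs(x[i + m * tau] - x[j + m * tau]) <= r:
                    A += 1
    if B == 0 or A == 0:
        return float("nan")
    return -math.log(A / B)


def m_fre_en_bf(X, m: int, tau: int = 1):
    """Cross-band distance rank-pattern entropy via explicit pair loops.

    Returns (value, pattern_counts).
    """
    X = _as_matrix(X)
    N, g = X.shape
    P = N - (m - 1) * tau
    counts: Counter = Counter()
    n_pairs = 0
    for i in range(P):
        for j in range(i + 1, P):
            tup = tuple(
                max(abs(X[i + k * tau, b] - X[j + k * tau, b]) for k in range(m))
                for b in range(g)
            )
            counts[ordinal_pattern_bf(tup)] += 1
            n_pairs += 1
    H = -sum((c / n_pairs) * math.log(c / n_pairs) for c in counts.values())
    return H / math.log(math.factorial(g)), dict(counts)


def periodogram_loglog_slope(x, fs: float = 1.0) -> float:
    """Least-squares slope of log power vs log frequency (DC excluded)."""
    x = np.asarray(x, dtype=float)
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    keep = (freqs > 0) & (spectrum > 0)
    logf, logp = np.log(freqs[keep]), np.log(spectrum[keep])
    return float(np.polyfit(logf, logp, 1)[0])
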