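"""Multivariate entropy estimators for band-decomposed signals.

Three estimators operate on an ``N x g`` matrix of synchronized time series
(one column per frequency band or channel):

* :func:`mv_perm_entropy` — multivariate permutation entropy: Shannon entropy
  of ordinal (rank) patterns of delay-embedded vectors, pooled across the
  ``g`` variates and normalized by ``ln(m!)``.
* :func:`mv_samp_entropy` — multivariate sample entropy: negative log ratio of
  template-match probabilities at embedding dimensions ``m+1`` vs ``m`` under
  a Chebyshev-distance tolerance ``r``.
* :func:`m_fre_en` — multi-frequency entropy: Shannon entropy of the
  rank-orderings of per-band Chebyshev distances between pairs of
  time-frequency embedding blocks, normalized by ``ln(g!)``.

All three use uniform delay embedding (same ``m`` and ``tau`` for every
variate). Estimators are deterministic; no randomness is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MultibandSeries",
    "EmbeddingConfig",
    "EmbeddedTrajectory",
    "PatternDistribution",
    "SampEnCounts",
    "EntropyResult",
    "embed_uniform",
    "ordinal_pattern",
    "mv_perm_entropy",
    "chebyshev_distance",
    "mv_samp_entropy",
    "pairwise_band_distances",
    "distance_rank_pattern",
    "m_fre_en",
    "compute_entropy",
]


@dataclass(frozen=True)
class MultibandSeries:
    """An ``N x g`` matrix of synchronized band (or channel) time series.

    Parameters
    ----------
    values : ndarray, shape (N, g)
        One column per variate; rows are time samples. All entries finite.
    band_labels : sequence of str, optional
        Unique identifiers per column (e.g. ``["theta", "alpha", "beta"]``).
        Generated as ``b1..bg`` when omitted.
    sample_rate_hz : float, optional
        Informational sampling rate; not used by the estimators.
    """

    values: np.ndarray
    band_labels: tuple[str, ...] = ()
    sample_rate_hz: float | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.ndim != 2:
            raise ValueError("values must be a 1-D or 2-D array")
        if values.shape[0] < 2:
            raise ValueError("need at least 2 time samples")
        if values.shape[1] < 1:
            raise ValueError("need at least 1 variate")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, column {bad[1]}"
            )
        labels = tuple(self.band_labels)
        if not labels:
            labels = tuple(f"b{i + 1}" for i in range(values.shape[1]))
        if len(labels) != values.shape[1]:
            raise ValueError(
                f"{len(labels)} band labels for {values.shape[1]} columns"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("band labels must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "band_labels", labels)
        if self.sample_rate_hz is not None and self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding parameters shared by the estimators.

    ``m`` is the embedding dimension, ``tau`` the time delay. ``r`` is the
    similarity tolerance used only by multivariate sample entropy; when left
    unset each variate is scaled to unit standard deviation and
    ``r = r_factor`` (default 0.15).
    """

    m: int = 4
    tau: int = 1
    r: float | None = None
    r_factor: float = 0.15

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.tau < 1:
            raise ValueError("time delay tau must be >= 1")
        if self.r is not None and self.r < 0:
            raise ValueError("tolerance r must be nonnegative")
        if self.r_factor < 0:
            raise ValueError("r_factor must be nonnegative")


@dataclass(frozen=True)
class EmbeddedTrajectory:
    """Delay-embedded vectors in one of three layouts.

    ``per-variate``   — array (g, P, m): m-dimensional windows per variate.
    ``concatenated``  — array (P, g*m): composite vectors (sample entropy).
    ``time-frequency``— array (P, m, g): m x g blocks whose columns are the
    per-band delay windows (multi-frequency entropy).
    """

    vectors: np.ndarray
    m: int
    tau: int
    layout: str

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1] if self.layout == "per-variate" else self.vectors.shape[0]


@dataclass(frozen=True)
class PatternDistribution:
    """Counts and relative frequencies of rank patterns of order K."""

    pattern_counts: dict[tuple[int, ...], int]
    total: int
    K: int
    probabilities: dict[tuple[int, ...], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("total must be positive")
        if sum(self.pattern_counts.values()) != self.total:
            raise ValueError("pattern counts must sum to total")
        if len(self.pattern_counts) > math.factorial(self.K):
            raise ValueError("more distinct patterns than K! permutations")
        if not self.probabilities:
            probs = {
                pat: cnt / self.total for pat, cnt in self.pattern_counts.items()
            }
            object.__setattr__(self, "probabilities", probs)

    def shannon_entropy(self) -> float:
        """``-sum p ln p`` over observed patterns (0 ln 0 := 0)."""
        p = np.array(list(self.probabilities.values()))
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))


@dataclass(frozen=True)
class SampEnCounts:
    """Template-match probabilities underlying a sample-entropy value."""

    phi_m: float
    phi_m_plus_1: float
    match_count_m: int
    match_count_m_plus_1: int


@dataclass(frozen=True)
class EntropyResult:
    """A single entropy value with its provenance.

    ``value`` is NaN (and ``defined`` False) when sample entropy has no
    template matches at dimension ``m`` or ``m+1``.
    """

    algorithm: str
    value: float
    normalized: bool
    config: EmbeddingConfig
    n_samples: int
    n_bands: int
    defined: bool = True
    diagnostic: str = ""


_LAYOUTS = ("per-variate", "concatenated", "time-frequency")


def _as_series(series) -> MultibandSeries:
    if isinstance(series, MultibandSeries):
        return series
    return MultibandSeries(np.asarray(series, dtype=float))


def _check_length(n: int, m: int, tau: int) -> int:
    """Number of embedding windows; raises if there is none."""
    count = n - (m - 1) * tau
    if count < 1:
        raise ValueError(
            f"series of length {n} too short for m={m}, tau={tau}; "
            f"need at least N = {(m - 1) * tau + 1}"
        )
    return count


def embed_uniform(series, config: EmbeddingConfig, layout: str = "per-variate") -> EmbeddedTrajectory:
    """Uniform delay embedding of a multiband series.

    Produces the windows ``(u[g,i], u[g,i+tau], ..., u[g,i+(m-1)tau])`` for
    ``i = 0 .. N-(m-1)tau - 1`` arranged per the requested layout (see
    :class:`EmbeddedTrajectory`).
    """
    series = _as_series(series)
    if layout not in _LAYOUTS:
        raise ValueError(f"layout must be one of {_LAYOUTS}")
    m, tau = config.m, config.tau
    count = _check_length(series.n_samples, m, tau)
    x = series.values  # (N, g)
    # windows[i, k, b] = x[i + k*tau, b]
    idx = np.arange(count)[:, None] + tau * np.arange(m)[None, :]
    windows = x[idx, :]  # (P, m, g)
    if layout == "time-frequency":
        vectors = windows
    elif layout == "per-variate":
        vectors = np.transpose(windows, (2, 0, 1))  # (g, P, m)
    else:  # concatenated: variate 1's m lags, then variate 2's, ...
        vectors = np.transpose(windows, (0, 2, 1)).reshape(count, -1)
    return EmbeddedTrajectory(vectors=vectors, m=m, tau=tau, layout=layout)


def ordinal_pattern(vector: Sequence[float], tau: int = 1) -> tuple[int, ...]:
    """Rank pattern of an embedded vector: the permutation (1-based) that
    sorts it ascending, ties broken by original position (earlier first)."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("vector must be 1-D with at least 2 entries")
    order = np.argsort(v, kind="stable")
    return tuple(int(j) + 1 for j in order)


def _ordinal_codes(windows: np.ndarray) -> np.ndarray:
    """Encode each row's stable-ascending argsort as an integer < m!."""
    order = np.argsort(windows, axis=-1, kind="stable")
    m = windows.shape[-1]
    # Lehmer-style mixed-radix code of the permutation; bijective onto 0..m!-1.
    codes = np.zeros(order.shape[:-1], dtype=np.int64)
    for pos in range(m):
        smaller = np.sum(order[..., pos + 1:] < order[..., pos:pos + 1], axis=-1)
        codes = codes * (m - pos) + smaller
    return codes


def _decode_pattern(code: int, m: int) -> tuple[int, ...]:
    """Inverse of :func:`_ordinal_codes` for a single code."""
    digits = []
    for pos in range(m):
        radix = m - pos
        digits.append(code // math.factorial(radix - 1) % radix)
    remaining = list(range(1, m + 1))
    perm = []
    for d in digits:
        perm.append(remaining.pop(d))
    return tuple(perm)


def _distribution_from_codes(codes: np.ndarray, K: int) -> PatternDistribution:
    uniq, counts = np.unique(codes, return_counts=True)
    pattern_counts = {
        _decode_pattern(int(c), K): int(n) for c, n in zip(uniq, counts)
    }
    return PatternDistribution(
        pattern_counts=pattern_counts, total=int(codes.size), K=K
    )


def mv_perm_entropy(series, config: EmbeddingConfig | None = None) -> EntropyResult:
    """Multivariate permutation entropy, normalized to [0, 1].

    Ordinal patterns of the m-dimensional delay windows are computed per
    variate and pooled across all g variates into a single distribution of
    ``g * (N - (m-1)tau)`` patterns; the Shannon entropy of that distribution
    is divided by ``ln(m!)``.
    """
    series = _as_series(series)
    config = config or EmbeddingConfig()
    traj = embed_uniform(series, config, layout="per-variate")
    codes = _ordinal_codes(traj.vectors)  # (g, P)
    dist = _distribution_from_codes(codes.ravel(), config.m)
    value = dist.shannon_entropy() / math.log(math.factorial(config.m))
    return EntropyResult(
        algorithm="mvPerEn",
        value=value,
        normalized=True,
        config=config,
        n_samples=series.n_samples,
        n_bands=series.n_bands,
    )


def chebyshev_distance(a, b) -> float:
    """Maximum absolute componentwise difference between two vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.max(np.abs(a - b))) if a.size else 0.0


def _chebyshev_matrix(vectors: np.ndarray) -> np.ndarray:
    """All-pairs Chebyshev distances, accumulated one component at a time so
    memory stays at O(P^2) regardless of dimension."""
    P, d = vectors.shape
    if P < 2:
        raise ValueError("need at least 2 composite vectors")
    dist = np.zeros((P, P))
    for c in range(d):
        col = vectors[:, c]
        np.maximum(dist, np.abs(col[:, None] - col[None, :]), out=dist)
    return dist


def _match_fraction_from(dist: np.ndarray, r: float) -> tuple[float, int]:
    """Mean over i of the fraction of j != i with distance <= r."""
    P = dist.shape[0]
    matches = (dist <= r).sum() - P  # drop self-matches on the diagonal
    return matches / (P * (P - 1)), int(matches)


def _sampen_phis(x: np.ndarray, m: int, tau: int, r: float):
    """phi at dimension m and the g dimension-(m+1) extensions.

    ``x`` is the (N, g) data; composite vectors concatenate each variate's m
    delay lags, indexed 0 .. N - m*tau - 1. The base distance matrix is
    reused when each variate in turn gains its lag-m*tau component.
    """
    N, g = x.shape
    n = m * tau
    P = N - n
    idx = np.arange(P)[:, None] + tau * np.arange(m)[None, :]
    vec_m = np.concatenate([x[idx, b] for b in range(g)], axis=1)
    dist_m = _chebyshev_matrix(vec_m)
    phi_m, count_m = _match_fraction_from(dist_m, r)
    phis, count_m1 = [], 0
    tail = np.arange(P) + n
    for b in range(g):
        col = x[tail, b]
        dist_b = np.maximum(dist_m, np.abs(col[:, None] - col[None, :]))
        phi_b, cnt = _match_fraction_from(dist_b, r)
        phis.append(phi_b)
        count_m1 += cnt
    return phi_m, count_m, phis, count_m1


def mv_samp_entropy(series, config: EmbeddingConfig | None = None) -> EntropyResult:
    """Multivariate sample entropy ``-ln(phi^{m+1} / phi^m)``.

    Composite vectors concatenate the m-dimensional delay windows of all g
    variates; ``N - m*tau`` of them are formed so the same index range
    supports the dimension-(m+1) extension. ``phi^m`` is the average over
    vectors of the fraction of other vectors within Chebyshev distance ``r``
    (self-matches excluded). The embedding is then extended to m+1 in each of
    the g variates in turn and the g match fractions are averaged.

    When ``config.r`` is unset, each variate is first scaled to unit standard
    deviation and ``r = r_factor`` (zero-variance variates are left as-is).
    If either phi is zero the result is flagged undefined (value NaN).
    """
    series = _as_series(series)
    config = config or EmbeddingConfig()
    m, tau = config.m, config.tau
    x = series.values
    N, g = x.shape
    n = m * tau  # max{M} * max{tau} once extended; fixes the index range
    P = N - n
    if P < 2:
        raise ValueError(
            f"series of length {N} too short for m={m}, tau={tau}; "
            f"need at least N = {n + 2}"
        )
    if config.r is None:
        sd = x.std(axis=0, ddof=0)
        scale = np.where(sd > 0, sd, 1.0)
        x = x / scale
        r = config.r_factor
    else:
        r = config.r
    if r <= 0:
        raise ValueError("similarity tolerance r must be > 0")

    phi_m, count_m, phis, count_m1 = _sampen_phis(x, m, tau, r)
    phi_m1 = float(np.mean(phis))

    if phi_m == 0.0 or phi_m1 == 0.0:
        which = "m" if phi_m == 0.0 else "m+1"
        return EntropyResult(
            algorithm="mvSampEn",
            value=float("nan"),
            normalized=False,
            config=config,
            n_samples=N,
            n_bands=g,
            defined=False,
            diagnostic=f"no template matches at dimension {which} "
            f"(r={r:g}, {P} composite vectors)",
        )
    return EntropyResult(
        algorithm="mvSampEn",
        value=float(-np.log(phi_m1 / phi_m)),
        normalized=False,
        config=config,
        n_samples=N,
        n_bands=g,
    )


def samp_en_counts(series, config: EmbeddingConfig) -> SampEnCounts:
    """Match probabilities behind :func:`mv_samp_entropy` (diagnostic)."""
    series = _as_series(series)
    m, tau = config.m, config.tau
    x = series.values
    if config.r is None:
        sd = x.std(axis=0, ddof=0)
        x = x / np.where(sd > 0, sd, 1.0)
        r = config.r_factor
    else:
        r = config.r
    phi_m, cm, phis, cm1 = _sampen_phis(x, m, tau, r)
    return SampEnCounts(
        phi_m=phi_m,
        phi_m_plus_1=float(np.mean(phis)),
        match_count_m=cm,
        match_count_m_plus_1=cm1,
    )


def pairwise_band_distances(traj: EmbeddedTrajectory) -> np.ndarray:
    """Per-band Chebyshev distances for every unordered block pair.

    For time-frequency blocks ``Y_m(i)`` of shape (m, g), returns an array of
    shape (C(P, 2), g): row (i, j), i < j, holds for each band the maximum
    over the m lags of the absolute difference between the two blocks'
    columns. Pairs are ordered (0,1), (0,2), ..., (P-2, P-1).
    """
    if traj.layout != "time-frequency":
        raise ValueError("pairwise_band_distances requires time-frequency layout")
    blocks = traj.vectors  # (P, m, g)
    P = blocks.shape[0]
    if P < 2:
        raise ValueError("need at least 2 embedding blocks")
    iu, ju = np.triu_indices(P, k=1)
    g = blocks.shape[2]
    out = np.zeros((iu.size, g))
    # one (P, P) matrix per band per lag keeps memory at O(P^2)
    for b in range(g):
        dist = np.zeros((P, P))
        for k in range(blocks.shape[1]):
            col = blocks[:, k, b]
            np.maximum(dist, np.abs(col[:, None] - col[None, :]), out=dist)
        out[:, b] = dist[iu, ju]
    return out


def distance_rank_pattern(dist_tuple: Sequence[float]) -> tuple[int, ...]:
    """Permutation of band indices (1-based) sorting a distance tuple
    ascending; ties broken by band column order."""
    v = np.asarray(dist_tuple, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 bands")
    return tuple(int(j) + 1 for j in np.argsort(v, kind="stable"))


def m_fre_en(series, config: EmbeddingConfig | None = None) -> EntropyResult:
    """Multi-frequency entropy of a band-decomposed signal, in [0, 1].

    The g band columns are expected to be the band-filtered, per-band
    standardized series of one channel (standardization is applied by
    :func:`mfreen.preprocess.band_decompose`; the estimator itself does not
    rescale). Time-frequency blocks ``Y_m(i)`` (m lags x g bands) are formed;
    for every unordered block pair the g-tuple of per-band Chebyshev
    distances is ranked ascending, and the Shannon entropy of the resulting
    rank-pattern distribution over the g! patterns — with probabilities
    count / number-of-pairs — is normalized by ``ln(g!)``.
    """
    series = _as_series(series)
    config = config or EmbeddingConfig()
    if series.n_bands < 2:
        raise ValueError("m_fre_en needs at least 2 bands (g >= 2)")
    traj = embed_uniform(series, config, layout="time-frequency")
    dists = pairwise_band_distances(traj)
    codes = _ordinal_codes(dists)
    dist = _distribution_from_codes(codes, series.n_bands)
    value = dist.shannon_entropy() / math.log(math.factorial(series.n_bands))
    return EntropyResult(
        algorithm="mFreEn",
        value=value,
        normalized=True,
        config=config,
        n_samples=series.n_samples,
        n_bands=series.n_bands,
    )


_ALGORITHMS = {
    "mvperen": mv_perm_entropy,
    "mvsampen": mv_samp_entropy,
    "mfreen": m_fre_en,
}


def compute_entropy(series, algorithm: str, config: EmbeddingConfig | None = None) -> EntropyResult:
    """Dispatch to one of the three estimators by (case-insensitive) name."""
    key = algorithm.lower().replace("_", "")
    if key not in _ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose from mvPerEn, mvSampEn, mFreEn"
        )
    return _ALGORITHMS[key](series, config)
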