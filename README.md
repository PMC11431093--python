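# mfreen — multi-frequency entropy for band-decomposed signals

Neural oscillations in different frequency bands (theta 4–8 Hz, alpha
8–13 Hz, beta 13–30 Hz, …) interact, and the complexity of those
interactions is informative about brain state. Classic multivariate entropy
estimators treat EEG *channels* as the variates; `mfreen` instead treats the
*frequency bands of a single channel* as the variates, quantifying
cross-frequency complexity. The package provides:

- **mFreEn** (multi-frequency entropy) — the cross-band rank-pattern
  estimator at the core of the package;
- **mvPerEn** (multivariate permutation entropy) and **mvSampEn**
  (multivariate sample entropy) — the standard baselines, under the same
  uniform-embedding conventions, for comparison;
- band decomposition (zero-phase FIR), per-band or per-channel
  standardization, and windowing;
- synthetic-signal generators (MIX model, white Gaussian noise, 1/f noise,
  SNR-controlled noise injection) and a seeded study harness for
  sensitivity, noise-robustness, and data-length benchmarks.

## The estimators

Let `U` be an `N × g` matrix whose columns are synchronized band series
`u_g(l)`. With embedding dimension `m` and delay `τ` (uniform embedding):

**mvPerEn** — for each variate, every delay window
`(u(i), u(i+τ), …, u(i+(m−1)τ))` is mapped to its ordinal pattern (the
permutation sorting it ascending; ties keep original position order).
Counts are pooled across all `g` variates into one distribution `p_r` over
the `m!` patterns, and

    mvPerEn = −Σ_r p_r ln p_r / ln(m!)  ∈ [0, 1].

**mvSampEn** — composite vectors concatenate all `g` delay windows
(dimension `g·m`); `φ^m(r)` is the mean fraction of other vectors within
Chebyshev distance `r` (self-matches excluded). The embedding is extended
to `m+1` in each variate in turn and the `g` match fractions averaged to
give `φ^{m+1}(r)`; then

    mvSampEn = −ln( φ^{m+1}(r) / φ^m(r) )  ≥ 0.

By default each variate is scaled to unit SD and `r = 0.15`. If either φ
is zero the value is flagged undefined (never ±∞).

**mFreEn** — time-frequency blocks `Y_m(i)` (the `m × g` matrix of all
bands' windows at time `i`) are compared pairwise: for every unordered pair
`(i, j)` the `g`-tuple of per-band Chebyshev distances
`D^m_{ij}(band) = max_k |u_band(i+kτ) − u_band(j+kτ)|` is ranked ascending,
giving one of `g!` rank patterns. With `p_t` the relative frequencies over
all pairs,

    mFreEn = −Σ_t p_t ln p_t / ln(g!)  ∈ [0, 1].

The rank pattern records *which band changed most* between two moments, so
mFreEn is sensitive to the relative dynamics of the rhythms — information
the per-band ordinal and template statistics discard.

## Worked example

```python
from mfreen import EmbeddingConfig, band_decompose, compute_entropy, mix_composite

signal = mix_composite(p=0.2, n_samples=1500, seed=42)   # 3 s at 500 Hz
series = band_decompose(signal, sample_rate_hz=500.0)    # theta/alpha/beta, z-scored
cfg = EmbeddingConfig(m=4, tau=1)

for algo in ("mvPerEn", "mvSampEn", "mFreEn"):
    res = compute_entropy(series, algo, cfg)
    print(f"{res.algorithm:>8}: {res.value:.4f}  (normalized={res.normalized})")
```

prints

```
 mvPerEn: 0.3597  (normalized=True)
mvSampEn: 0.1312  (normalized=False)
  mFreEn: 0.9741  (normalized=True)
```

The input is a MIX(0.2) composite — three sinusoidal carriers (6, 10,
20 Hz) with 20% of samples replaced by uniform noise — filtered into the
three EEG bands. The oversampled narrowband bands are smooth, so the
ordinal patterns concentrate on monotone shapes (mvPerEn ≈ 0.36) and
templates repeat often (mvSampEn ≈ 0.13), while the *relative* band
dynamics stay rich (mFreEn ≈ 0.97). All three are deterministic given the
simulation seed.

The same computation from the shell:

```sh
mfreen simulate --model mix --p 0.2 --fs 500 --t 3 --freq 10 --amp 2 --seed 7 --out sig.csv
mfreen compute --input sig.csv --algo mvperen --m 4
mfreen experiment --study length --seed 1 --out results/length/
mfreen fixtures --seed 3 --out fixtures/
```

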