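# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `mfreen`. The package computes three multivariate
entropy statistics on an `N × g` matrix of synchronized band (or channel)
time series, plus the simulation and study machinery used to benchmark
them. Nothing here is fitted; every estimator is a deterministic function
of its input and parameters, and every simulation is a pure function of its
parameters and seed.

## Estimators and conventions

All three estimators use uniform delay embedding: the same dimension `m`
and delay `τ` for every variate. Defaults are `m = 4`, `τ = 1`; sweeps in
the study harness cover `m = 2…7`. `m` below ~4 gives too few states to
discriminate; above ~4 the pattern/template statistics get undersampled at
typical record lengths and noise robustness degrades, which is why 4 is the
working default.

**Multivariate permutation entropy (mvPerEn).** Ordinal patterns are
computed per variate over the `N − (m−1)τ` delay windows and pooled across
all `g` variates into a single distribution (total `g·(N−(m−1)τ)`
patterns), rather than averaging per-variate entropies; this keeps one
probability distribution per series and matches the standard multivariate
construction. The Shannon sum is normalized by `ln(m!)`. Tied window values
are ranked by original position (stable ascending sort) — the common
permutation-entropy convention — so the map from windows to patterns is
total and deterministic.

**Multivariate sample entropy (mvSampEn).** Composite vectors concatenate
each variate's `m` delay lags. `N − mτ` of them are formed (one fewer lag
range than the embedding strictly needs) so the *same* index range supports
the dimension-`(m+1)` extension. `φ^m` averages, over vectors, the fraction
of other vectors within Chebyshev distance `r`, excluding self-matches and
dividing by `N − mτ − 1`. The extension to `m+1` is done `g` ways (each
variate gains its lag-`mτ` component in turn), the match fraction is
computed *within* each extended family, and the `g` fractions are averaged.
The pooled alternative — one family of `g·(N−mτ)` extended vectors with
cross-family matching — was evaluated and rejected: on band-decomposed
composites its estimate is still drifting at `N = 2000` and can go negative
at small `N` (cross-family matches inflate `φ^{m+1}` above `φ^m`).

The tolerance convention: the phrase "0.15 × the standard deviation" is
only well-defined once the scale is fixed, so when `r` is not given
explicitly each variate is scaled to unit SD and `r = r_factor = 0.15`.
This makes mvSampEn invariant to per-variate rescaling. Zero-variance
variates are left unscaled (a constant column matches everywhere
regardless). If either match probability is zero the result is flagged
undefined (`value = NaN`, `defined = False`) with a diagnostic — never
±∞; the study harness drops and counts such replicates and aborts if more
than 25% of any cell is lost.

**Multi-frequency entropy (mFreEn).** Time-frequency blocks `Y_m(i)`
(`m` lags × `g` bands) are compared over all `C(P, 2)` unordered pairs,
`P = N − (m−1)τ`. Each pair yields the `g`-tuple of per-band Chebyshev
distances; the tuple's ascending rank pattern (ties broken by band column
order) is one of `g!` symbols. Pattern probabilities are counts divided by
the number of *pairs* — the only denominator under which they sum to one —
and the entropy is normalized by `ln(g!)`. Zero-probability patterns
contribute zero (`0·ln 0 := 0`).

Consequences worth knowing:

- mvPerEn and mFreEn lie in [0, 1]; 0 iff a single pattern occurs, 1 iff
  the pattern distribution is uniform.
- Both are invariant under a strictly positive affine rescaling applied to
  *all* bands at once. mFreEn is **not** invariant under per-band
  rescaling — relative band scale is exactly what its distance ranks
  measure — which is why normalization policy (below) matters.
- Permuting band columns permutes mFreEn's pattern labels but not their
  multiset, leaving the value unchanged — *except* in the measure-zero
  event of tied distance tuples, where the positional tie-break is
  column-order-dependent.
- At `g = 1`, mvSampEn reduces exactly to univariate sample entropy with
  the same template count at both dimensions.
- mFreEn uses ~`N²/2` pairs where mvPerEn uses ~`g·N` patterns, so its
  pattern distribution is far better sampled at short record lengths.

## Preprocessing

Band decomposition uses a windowed-sinc (Hamming) FIR applied forward and
backward (`filtfilt`), i.e. zero-phase, with passband gain ≈ 1. The filter
order follows the 3-cycles-of-the-low-edge convention, `3·fs/low`. Within
`band_decompose` one order — set by the lowest band edge in the bank
(374 taps + 1 for theta at fs = 500) — is used for *every* band: per-band
orders would give the wide beta band a ~14 Hz transition skirt while theta
gets a sharp one, and a method that compares patterns across bands should
not inherit band-dependent leakage. For records shorter than three filter
lengths, the backward-pass edge padding is clamped to `N − 1` rather than
shortening the filter, so every record length sees the same filter; short
records consequently carry larger edge transients (flagged below as a
limitation). Filtered series are used full-length (no trimming), keeping
the sample count stated by a study design.

Two standardization scopes are offered after filtering:

- `scope="band"` (default): each band column is z-scored to mean 0, SD 1.
  No band can then dominate the cross-band distances by sheer amplitude —
  the appropriate choice when band amplitudes differ for uninteresting
  reasons (electrode gain, 1/f background) and only the *dynamics* should
  count.
- `scope="channel"`: the channel is z-scored once before filtering and the
  bands keep that common scale, preserving the relative power of the
  rhythms. This is the scope the study harness uses: distinguishing, e.g.,
  flat-spectrum from 1/f noise, or amplitude assignments of band carriers,
  is *only* possible when relative band power survives preprocessing —
  under per-band z-scoring those signal classes become statistically
  near-identical and no estimator can separate them.

Windowing (`segment`) cuts a series into length-`window_len` windows at
offsets `0, step, 2·step, …`, dropping the last partial window: 200/200
(non-overlapping) for resting-state-style analysis, 200/1 (sliding) for
task-locked analysis.

## Synthetic signals

**MIX(p)**: a sinusoid `A sin(2π f n / fs)` in which exactly
`round(N·p)` positions — sampled uniformly without replacement — are
replaced by i.i.d. Uniform(−3, 3) draws (the ±3 range mirrors the 3σ span
of a standard normal). Complexity rises with `p`. The generator takes the
oscillation frequency `f` explicitly (6/10/20 Hz emulate the theta, alpha
and beta rhythms).

**mix_composite**: the sum of one MIX(p) signal per carrier, default
carriers (6, 10, 20) Hz with amplitudes (2, 2√2, 3√2) — three levels whose
3! assignments to the carriers form the amplitude-sensitivity conditions.
Each carrier draws its own child seed.

**Noise**: white Gaussian noise is i.i.d. standard normal; 1/f (pink)
noise is white noise shaped in the frequency domain by `1/√f` (DC zeroed),
inverse-transformed and standardized to unit SD. Spectral slopes are
verified by periodogram regression (0 ± 0.1 and −1 ± 0.15 at `N = 2^16`).
`add_noise_snr` rescales a white-noise realization so the *realized*
`10·log10(P_signal/P_noise)` equals the requested SNR exactly.

All generators, and every study, are bit-reproducible: the harness derives
per-replicate seeds from the master seed and the replicate's coordinates
via `SeedSequence`, keeping them below 2^31.

## Study harness and problem sizes

Each study produces a tidy raw table (algorithm, condition, swept
parameter, replicate, entropy, defined-flag) and mean/SD/`n_valid`
summaries. For cross-estimator display and the stabilization criterion,
raw values are min-max normalized per algorithm *over the full sweep* and
then averaged — normalize-then-average, so the normalized means share the
affine scale of the replicates and the span reflects replicate spread.

Standard study conditions (chosen once, as the conditions the benchmarks
describe): 20 replicates, `N = 1500` (3 s at 500 Hz), `m = 2…7`,
`p ∈ {0.2, 0.4, 0.6, 0.8}`, SNR ∈ {5, 10, 15, 20, 25} dB at `p = 0.2`,
beta carrier ∈ {15, 20, 25, 30} Hz with theta/alpha fixed at 6/10 Hz. The
data-length study uses `p = 0.2`, the default carriers/amplitudes, `m = 4`,
and the grid `N = 100…2000` step 100; with these sizes it completes in
about two minutes on one CPU (mvSampEn at `N = 2000` dominates, all-pairs
distance matrices being O(N²) — computed one component at a time so memory
stays at O(N²) floats).

**Stabilization length**: the benchmark never defines "stabilized", so the
package does — the smallest grid `N` such that for every `N' ≥ N` the
normalized mean at `N'` stays within `rel_tol · |mean(N_max)|` of the
`N_max` mean, `rel_tol = 0.05` by default and exposed as a parameter.

Measured behavior under these conditions (what `scripts/acceptance.py`
recomputes): mvPerEn stabilizes at the grid floor (100–200) — ordinal
patterns of heavily oversampled narrowband signals converge almost
immediately; mFreEn at ~500; mvSampEn last (≳1500), its match-probability
ratio still drifting at `N = 2000` because the commensurate carriers share
a 250-sample period and near-exact template repeats keep accumulating.
The qualitative conclusion that the pattern-based estimators need far less
data than the template-matching baseline is robust across seeds; the exact
stabilization lengths are not finer than the grid and depend on the
replicate noise entering the min-max span.

## What the synthetic benchmarks do and do not show

The generators emulate narrowband oscillations with controlled complexity
(MIX), controlled spectra (WGN vs 1/f), and controlled SNR. They do not
emulate nonstationarity, artifacts (eye movement, muscle), volume
conduction, cross-frequency *coupling* (phase-amplitude relations), or
between-subject variability. Passing the suite therefore demonstrates
correctness of the estimators and the stated sensitivities on stationary
band-limited signals — not clinical performance on real EEG, which
additionally depends on preprocessing choices out of scope here (artifact
removal, re-referencing, epoching).

## Known limitations

- Filtering short records with a full-length FIR leaves most of the record
  edge-affected below `N ≈ 700` at fs = 500; the data-length study
  deliberately accepts this rather than varying the filter with `N`.
- Bandpass filtering before cross-band analysis cannot detect
  cross-coupling interference within a band; alternative decompositions
  (e.g. STFT) are not implemented.
- Uniform embedding only; nonuniform/variational embedding and multiscale
  extensions are out of scope.
- mvSampEn on strongly periodic inputs converges slowly and its value
  depends on the record length; compare values only at matched `N`.
- The mFreEn tie-break makes the estimator column-order-dependent on data
  with exactly tied cross-band distances (integer-valued inputs); real
  filtered signals are tie-free almost surely.
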