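# Methods

## Statistical model

All estimators assume the two-frame model: registered frames
t₁ = s + n₁, t₂ = s + n₂ with a shared, wide-sense-stationary signal s
and zero-mean noise n₁, n₂ that is independent between frames and of s.
Then E{Cov(t₁,t₂)} = Var(s), and the amplitude SNR is estimated as

    S_σ = √(max(Cov_s, 0)),  N_σ = √(max(√(Var₁·Var₂) − Cov_s, 0)),  SNR = S_σ/N_σ.

Conventions and edge cases:

* All sample statistics use the unbiased n−1 divisor.
* A negative sample covariance is clamped: status `zero_signal`,
  SNR = 0 (a negative amplitude ratio is physically meaningless and
  destabilises downstream graphs).
* A vanishing noise term (e.g. t₁ ≡ t₂) yields status `zero_noise` and
  SNR = ∞ — a sentinel, never a finite fake. Such samples are excluded
  from smoothing and peak detection.
* A constant pair (both variances zero) raises: the SNR is undefined.
* Pixels are converted to float64 and never renormalised; the estimator
  is exactly invariant under common affine maps g·x + b, g > 0.
* Registration is a contract. No drift correction is applied; drift
  converts signal variance into apparent noise and biases SNR low
  (known limitation).

## Stability index

For Gaussian frames the sample covariance over M pixels has

    E{Cov_s}²/Var(Cov_s) = (M−1)·SNR⁴ / (2·SNR⁴ + 2·SNR² + 1),

derived from Var(Cov_s) = (σ₁²σ₂² + σ₁₂²)/(M−1). The implemented index
uses the low-SNR form M·SNR⁴/(2·SNR²+1); the two agree to ~1% at
SNR ≤ 0.3 and diverge to ~40% as SNR → 1 (the brute-force replicate
oracle in the tests pins the closed form at SNR 0.1 and 0.3, within 3
Monte-Carlo standard errors). The index is used comparatively — to rank
reduction levels and candidate fields — so the low-SNR approximation is
harmless at higher SNR as long as it remains monotone, which it is.

One 2×2 block-averaging step on oversampled texture doubles SNR and
quarters M, multiplying the index by 4·(2s²+1)/(8s²+1) ≈ 4 at low SNR.

## SNR-priority reduction

`block_average` averages disjoint 2×2 blocks and decimates; a trailing
odd row/column is discarded (padding would bias block means). Both
frames of a pair are always reduced in lockstep so the covariance model
holds at every level. The sweep records (SNR, M, index) for levels
0..r_max (default 5, i.e. 640×480 → 20×15) and selects the global index
maximum, ties broken toward the smaller level to preserve resolution.
Reduction is expressed only as repetitions of the 2×2 step — not as a
general low-pass filter — because the index explicitly trades the
resulting M against the resulting SNR.

## Temporal chain

* **Frame integration** (default 4): pixelwise mean. Metric samples pair
  two *disjoint* n-frame block means (frames k−2n+1..k−n vs k−n+1..k).
  Overlapping sliding windows would share noise between the pair members
  and inflate the covariance; disjoint blocks keep the estimator
  unbiased at the cost of starting the graph at tick 2n−1.
* **Moving average** (default 4 points): causal mean of the last
  min(window, k+1) values; NaN sentinels are skipped.
* Both defaults follow the experimentally selected operating point for a
  TV-scan instrument; both are configurable, and the combined group
  delay is (2n−1)/2 + (window−1)/2 ticks.
* `FocusGraph.focus_estimate` removes that known causal lag when
  converting a detected peak tick into a control estimate (the graph
  itself stays strictly causal; only the *labelling* of the peak looks
  back).
* A covariance-graph mode (`metric="cov"`) is provided for cost-sensitive
  use; the SNR mode is the default because of its display invariance.

## Just-focus detection

The detector accepts the global maximum of the smoothed graph only if
its rise and fall each exceed a prominence threshold. The default
threshold estimates the raw-series noise sd σ̂ robustly from second
differences (median absolute deviation scaled by 1.4826/√6 — second
differences cancel smooth trend curvature) and sets

    threshold = 4·σ̂·√(2·ln N) / √window.

The √(2·ln N) factor tracks the expected extreme range of N noise
samples, so an information-free graph reports "no peak" regardless of
length, while any peak standing clear of the noise envelope is kept. A
fixed threshold can be passed to override the default. (A plain
"k × sd of first differences" rule was rejected: the expected extreme
range of a smoothed noise series exceeds it for realistic N, so pure
noise would trigger detections.)

## Sufficiency and field search

`assess_sufficiency` compares the chosen level's index against a
user threshold; an insufficient field triggers the beam-shift search.
Candidates (default: centre + 8 shifts on a ring; pattern and radius
user-set, as the near-region extent is instrument-specific) are rendered
at one shared optics state, evaluated at the already-selected reduction
level, and ranked by index, descending; ties keep scan order. Ranking is
invariant under global affine intensity changes and degrades gracefully
under defocus, since blur attenuates all candidates alike.

## Virtual SEM

The generator emulates exactly the statistical model above, so estimator
tests are well-posed:

* **Specimen**: seeded Gaussian white noise smoothed to a correlation
  length `feature_scale` (wrap-around boundary), normalised to
  `texture_sd` around `mean_level` (defaults 1.0 and 100.0 — weak
  contrast on a bright background). `block_size > 1` generates at
  reduced resolution and replicates pixels, giving texture exactly
  constant on b×b blocks (the idealised oversampled regime).
  Gaussian-profile strength patches plant stronger/weaker fields for
  search scenarios.
* **Optics**: elliptical Gaussian PSF with principal sigmas
  σ_u = σ₀·|Δf + a|, σ_v = σ₀·|Δf − a|, a = hypot(astig_x, astig_y),
  axis angle atan2(astig_y, astig_x)/2 — the two-line-foci stigmator
  parameterisation (at Δf = ±a one direction reaches a line focus; at
  Δf = 0 astigmatism blurs isotropically, the circle of least
  confusion). σ₀ (`psf_scale`) defaults to 1.5 px per focal unit. The
  Gaussian PSF is a deliberate simplification: the method responds to
  blur-induced loss of signal variance, not to the beam profile's shape.
* **Magnification** scales the crop (>1 = oversampling) by bilinear
  resampling of the specimen map; magnification 1 with integer shifts
  uses an exact slice so block-constant textures stay exact.
* **Noise**: per-frame independent Gaussian with
  sd = dwell_scale/√(current·dwell). The default dwell_scale (3.4) puts
  a 26 pA, 25 frames/s TV scan near SNR 0.3 for unit texture sd —
  physical instrument constants are unknowable here, so scenarios are
  pinned by ground-truth SNR via `calibrate_dwell_scale` instead.
  Slow-scan acquisition multiplies the dwell (e.g. ×2000 for 80 s vs
  0.04 s), raising SNR by the square root of the ratio. A Poisson mode
  is provided for realism; its noise is signal-dependent, so the
  covariance model then holds only approximately.
* **Reproducibility**: textures are seeded; per-frame noise is keyed on
  (seed, tick), making streams byte-identical across reruns and
  regenerable frame by frame.

What the generator does *not* emulate: scan distortion and drift
(pairs are perfectly registered), detector nonlinearity and afterglow,
electron-optical aberrations beyond defocus/astigmatism, and non-
stationary specimen contrast mechanisms. Passing tests therefore
demonstrate correctness of the estimators and the chain under the
stated model, not robustness to registration error.

## Problem sizes and scenario choices

* Stream scenarios for end-to-end validation use 192×144 frames, 81
  control steps at 2 frames per step, features of 4 px correlation, and
  generator SNR 0.1 at focus — frames small enough to iterate quickly
  while leaving the raw (unprocessed) chain genuinely unusable, which is
  the regime the chain exists for. Control ramps span ±6 focal units so
  maximum blur (9 px sigma) comfortably destroys the 4 px texture and
  the graph has real contrast.
* Recovery tolerance for sweep scenarios is 15% of the swept control
  range; this absorbs the deliberate causal group delay plus peak jitter
  on the gentle SNR plateau around focus.
* The replicate oracle uses 10⁴ pairs at M ∈ {256, 1024}; the
  delta-method standard error of E²/Var accounts for the 3rd and 4th
  moments of the replicate covariances.
* Field-search scenarios separate patch centres by ≥220 px with 60 px
  patch radius so planted strengths do not overlap (Gaussian tails
  < 0.2% at neighbouring centres).

## Known limitations

* The stability index is a low-SNR approximation (see above); absolute
  index values above SNR ≈ 1 overestimate the true covariance
  steadiness.
* Auto reduction-level selection from a stream head uses a few noisy
  pairs; on very weak texture it may pick a neighbouring level of the
  optimum. The chain is insensitive to ±1 level.
* No registration/drift handling; no hardware control — the package
  emits guidance (chosen level, peak tick, recommended shift), it does
  not drive an instrument.
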