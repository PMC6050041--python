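# Methods

This note documents the models, conventions, and numerical choices behind
`scmotion`: what the synthetic generator emulates, how the analysis stages
are defined, where the design was genuinely open, and what the tests do and
do not establish about real data.

## Stimulus model

Stimuli are represented by condition labels only; no grating movies are
rendered. The direction-contrast set crosses 8 motion directions (0–315° in
45° steps) plus a blank for both center and surround: 81 unique conditions,
including the center-alone row, the surround-alone column, and one all-gray
condition. Feature-contrast sets pair the 8 center directions with an
anti-phase surround (8 conditions), a 1 Hz or 4 Hz surround against the 2 Hz
center (16), or cross static orientations {0, 45, 90, 135°} plus blank for
center and surround (25). Gratings last 2 s with a 5 s gray interval; the
RF-mapping stimulus flashes a 5° square over a 6×6 grid (30°×30°), 1 s on /
3 s off. Every set is presented ≥4 times with conditions permuted within
each repeat block ("pseudo-random" block design). The direction difference
Δθ is always the folded difference min(|θc−θs|, 360−|θc−θs|) ∈ [0, 180];
clockwise and counterclockwise offsets are treated alike (the analysis
averages the two off-diagonals at Δθ = 45/90/135).

## Generative model of a neuron

Each simulated cell carries:

- **Direction tuning**: von Mises on direction (period 360°),
  `R_C(θ) = peak · exp(κ(cos(θ−pref) − 1))`, κ = 0 meaning untuned. The
  parametric form is a package choice; only one concentration parameter
  controls sharpness. gDSI of the noiseless curve is I₁(κ)/I₀(κ).
- **Surround modulation law**: `R_CS = a(Δθ)·R_C + b(Δθ)`. Excitatory
  defaults anchor (a, b) at (0.50, 0.48), (1.17, 2.54), (1.63, 1.55) %ΔF/F₀
  for Δθ = 0/90/180, with both a and b linearly interpolated at 45/135
  (the intermediate-Δθ law is not separately constrained; interpolation is
  the assumption). Inhibitory defaults are suppressive everywhere
  (a = 0.75/0.55/0.35, b ≈ 0.3 %) with the opposite surround most
  suppressive. Per-cell slopes jitter around the anchors (SD 0.08) and are
  coupled to the cell's standardized log κ (excitatory +0.22 on a(180);
  inhibitory −0.10 on a(180), +0.08 on a(0)); the couplings are zero-mean so
  class-average laws stay at the anchors, and they produce the
  selectivity–modulation correlations and the inhibitory gDSI-split
  contrast.
- **Center-silent cells** (23.6% of excitatory, 13% of inhibitory cells)
  have zero center-alone and surround-alone response and an emergent C-S
  response with an intercept-only law, b(Δθ) rising monotonically
  (0.05→1.0 of a per-cell amplitude, median 40 %ΔF/F₀ for excitatory). The
  emergent amplitude is direction-tuned around an assigned preferred center
  direction and normalized so its mean over center directions equals b(Δθ);
  a fully direction-untuned intercept would make the preferred-center
  assignment rule for these cells noise-driven.
- **Surround-alone responses**: 53.8% of center-responsive inhibitory cells
  (3% of excitatory) respond to the surround alone, at half the center gain
  with the same tuning.
- **Feature-contrast factors**: multiplicative gains on the center response
  (excitatory: anti-phase 0.95, TF 0.90, static iso/mid/cross
  0.55/0.65/0.75 on a half-gain static response; inhibitory: 0.80, 0.75,
  0.65/0.72/0.80). These sit between the same-direction suppression and the
  opposite-direction effect, so phase/TF/orientation contrasts attenuate
  suppression without reproducing the direction-contrast potentiation.
- **Receptive field**: 2D Gaussian (σ = 4°) centered per cell; centroids
  scatter around the patch center with SD 3° (excitatory) or 4.5°
  (inhibitory), which is what makes inhibitory per-field-of-view centroid
  dispersion larger. 19.4% of center-silent/silent cells lack a mappable RF.
- **Amplitudes and noise**: peak center responses are log-normal
  (median 60 %ΔF/F₀ excitatory, 50% inhibitory, σ_log = 0.5) — the scale of
  real recordings where example traces span ~100 %ΔF/F₀. Trace noise is
  additive i.i.d. Gaussian per frame in ΔF/F₀ units (SD 0.10); trial-to-trial
  gain variability is not modeled.
- **Depth**: the default cohort is superficial (10–45 µm, fast indicator);
  the `depth_survey` preset spans 10–205 µm with the slow nuclear indicator
  and linear declines of κ (0.4%/µm) and of the excitatory opposite-surround
  slope (0.0065/µm), so potentiation turns into suppression at depth. The
  gradients are config values that reproduce the qualitative depth profile,
  not measured quantities.

## Trace synthesis

A trial contributes `A · (H(t−t₀) − H(t−t₀−D))` to the cell's ΔF/F₀ time
course, the boxcar of the stimulus convolved with a causal double-exponential
kernel (fast dye: 50 ms rise / 600 ms decay; slow nuclear indicator: 400 ms /
3 s — free choices consistent with "significantly slower" nuclear kinetics;
the slow response peaks ~0.3 s later than the fast one). The kernel is
normalized so the mean of the noiseless response over the indicator's
standard analysis window equals the nominal amplitude, making
generator → pipeline a round trip. The trace is
`baseline_F · (1 + ΔF/F₀(t) + noise(t))`. Stimulus onsets follow duration +
ITI and are not frame-aligned, so quadrature phases vary across trials as in
a real acquisition (8.079 Hz default).

Round-trip accuracy: with noise off, per-condition means reproduce the
generative law to within 2% of each cell's response range at 4 repeats
(measured worst case 1.4%). The error is normalized to the cell's maximum
response rather than each condition's own value because conditions span
zero (gray, weak flanks) and because inter-trial kernel tails — decay into
the next trial's baseline and response windows, a real feature of 5 s ITI
recordings — contribute absolute offsets up to ~0.6 %ΔF/F₀ that scale with
the *preceding* trial's amplitude. A fast path (`simulate_trial_table`)
draws trial values directly from the expected-response law with
variance-matched noise for population-scale studies where trace extraction
itself is not under test.

## Analysis conventions

- **Windows**: gratings/fast — baseline 1.25 s pre-onset, response
  [onset+0.25 s, offset+0.75 s); gratings/slow — the response window shifted
  +0.375 s; flashing squares/fast — baseline 0.75 s, response
  [onset+0.25 s, offset+0.35 s). A frame belongs to a window if its
  acquisition midpoint falls in the half-open interval (unambiguous when
  windows are not frame-aligned). The flash/slow combination is undefined
  and rejected.
- **Responsiveness**: mean ΔF/F₀ > 2 × baseline SD expressed in ΔF/F₀ units
  (SD(F_baseline)/F₀, pooled as the RMS across that cell's trials) for at
  least one condition. Pooling across trials (rather than per-trial SDs) is
  a package choice flagged here. Negative ΔF/F₀ values are retained through
  averaging; clipping happens only inside the modulation index.
- **gDSI**: negative tuning-curve entries are rectified to zero first
  (keeps gDSI in [0, 1]; configurable). All-zero rectified curves yield NaN
  and are excluded from selectivity analyses.
- **Preferred direction**: argmax of the center-alone row for
  center-responsive cells; for center-silent cells, the center direction of
  the peak C-S combination. Ties break toward the lowest direction label.
  The opposite surround is preferred + 180°; the same surround is the
  preferred direction itself.
- **Modulation index**: clipped to [−1, 1]; a zero denominator maps to the
  sign of the numerator (0 if both responses are 0).
- **Bootstrap**: 10,000 resamples; each draws 2n values with replacement
  from the pooled 2n and splits them 4/4 by an explicit random permutation
  (the with-replacement sample is already exchangeable, so this matches
  taking the first four; the permutation is kept for fidelity to the
  procedure). Interval bounds use empirical quantiles with linear
  interpolation. Measured null calibration: ~94% non-modulated at the
  nominal 95%, i.e. mildly anti-conservative at n = 4, as expected for
  pooled resampling.
- **Category taxonomy**: cells responsive to no condition involving the
  center stimulus — including surround-alone-only responders — are
  non-responsive; others carry their opposite-surround bootstrap class.
- **Matrix alignment**: both direction axes are circularly shifted so the
  preferred center lands at relative 0; the blank row/column stays fixed;
  the entry multiset is conserved and alignment is idempotent.
- **Modulation fits**: ordinary least squares of the with-surround curve on
  the center-alone curve over the 8 direction points (the blank-center
  point is excluded), in raw response units; slope CIs are t-based on 6
  degrees of freedom. Fits on per-cell curves apply an R² ≥ 0.5 quality
  filter. Normalizing responses per cell before averaging is available but
  off by default.
- **RF conventions**: per-location responsiveness reuses the 2-SD
  criterion; RF "size" is n_responsive × 25 deg² (a labeled convention);
  centroid dispersion is the RMS distance from the mean centroid (a single
  rotation-invariant scalar — the "2D standard deviation" has no standard
  formula); patch coverage is inclusive at exactly the 10° radius.
- **Depth bins**: [0, 50), [50, 90), [90, 150), [150, ∞) µm, labeled
  superficial/60 µm/120 µm/180 µm; edges are configurable since bin
  membership has no canonical definition.
- Two-sample distribution comparisons use scipy's Kolmogorov–Smirnov and
  Mann–Whitney U routines; only the pooled-resampling bootstrap is bespoke.

## Problem sizes

Test and acceptance runs use populations of 300–500 cells (the scale of the
per-class samples in comparable experiments), 4 repeats, and 2000 null pairs
× 10,000 resamples for bootstrap calibration; the full suite and the
acceptance script each run in a few minutes on one CPU.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes —
affine surround modulation, class- and depth-specific laws, indicator
kinetics, Gaussian trace noise. Passing tests show the pipeline correctly
recovers parameters from data with that structure, with calibrated error
rates. They do not show that real SGS data satisfy the structure: real
recordings add neuropil contamination, motion artifacts, correlated and
non-Gaussian noise, eye movements, and anesthesia-state effects, none of
which are modeled. Real-data population statistics (KS statistics,
suppressed/potentiated percentages, correlation magnitudes) depend on the
recorded population and are used here only to calibrate generator defaults,
never as expected test outcomes.

## Known limitations

- No pixel-level stimulus rendering, spiking model, eye-position or
  running-state modeling; condition labels map directly to expected
  responses.
- The slow-indicator path inherits heavy inter-trial tails (3 s decay vs
  5 s ITI), producing negative ΔF/F₀ at some conditions — realistic, but it
  means noiseless round-trip identities are only guaranteed for the fast
  indicator.
- Intermediate-Δθ intercepts and the center-silent amplitude scale are
  interpolations/choices, not measured quantities.
- The surround-alone response model (half-gain, same tuning) is the
  simplest that produces the inhibitory control analyses; its gain is a
  config value.
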