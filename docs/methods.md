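# Methods

## The question and the designs

A neuron with orientation tuning measured at two lateral tilts can keep its
tuning fixed on the earth-fixed screen (gravitational anchoring) or fixed on
the retina (retinal anchoring). `gravframe` quantifies which, per neuron and
per population, for two designs:

- **Body tilt.** The observer is tilted by each of two angles (default ±25°)
  about the line of sight. The eyes counter-roll toward upright by a fixed
  `counterroll_deg` (default 6°), so the retinal image rotates by
  tilt − sign(tilt)·counter-roll = ±19°. Screen orientation *is*
  gravitational orientation; retinal orientation is screen − eye orientation.
- **Horizon tilt (cue conflict).** The observer stays upright while the
  depicted ground/horizon tilts by ±25° on the screen. The eyes never move
  (retinal = screen), and "gravitational" orientation is taken relative to
  the depicted ground: screen − tilt. Counter-roll is identically zero here.

All angles are degrees, counterclockwise positive in the subject's view.
Tested ranges are ≤200°, so orientation is treated as a linear axis with no
wrapping. Every frame transformation is a per-condition translation of the
orientation axis.

**Comparison orientations.** Correlating tuning across conditions in a frame
requires orientations at which both conditions have data after the frame
transformation. Candidates are the multiples of the grid spacing; a
candidate qualifies if it lies in the closed transformed tested interval of
both conditions. The default 9-point, −50°…+50° grid yields 5 retinal and 9
gravitational comparison points under body tilt, and 5 gravitational and 9
retinal points under horizon tilt. `balanced=True` restricts both frames to
their common grid indices so each frame uses equally many points;
`trim_leftmost` reproduces the display convention of dropping leftmost grid
points to equate counts without interpolating.

## Synthetic populations

The generator stands in for recorded data and defines the conditions under
which the pipeline is validated. Expected rate at screen orientation `s`
under tilt `T`:

    rate(s, T) = baseline + amplitude · [ λ·g(θ_grav) + (1−λ)·g(θ_ret) ]
    g(θ) = exp( κ · (cos(θ − θ_pref) − 1) )          (angles in degrees)

- λ = 1 gravitational, λ = 0 retinal, λ ∈ (0, 1) mixed. The mixture combines
  *responses*, not coordinates, so mixed neurons genuinely carry both
  signals — the premise of the decoding analysis.
- Defaults: 2 conditions × 9 orientations × 5 repetitions, 750 ms response
  windows. θ_pref ~ U(−20°, 20°): the probe stimulus is chosen to drive the
  neuron strongly at the center of the tested range, so preferred
  orientations cluster near 0°. κ ~ U(2, 6) gives half-widths of roughly
  30–50°, appropriate for well-tuned anterior ventral-stream neurons;
  amplitude U(20, 60) spk/s over baseline U(2, 10) spk/s. Class mix 35%
  gravitational / 15% retinal / 35% mixed (λ ~ U(0.3, 0.7)) / 15% untuned
  (κ = 0), a composition in which clear gravitational anchoring dominates
  clear retinal anchoring but a large fraction of neurons commit to neither.
- Noise: Poisson spike counts over the window (the physiological default),
  or zero-clipped Gaussian rate noise with per-neuron σ. Validation suites
  use Gaussian σ = amplitude/10 where a controlled signal-to-noise ratio is
  needed.

What the generator does *not* emulate: trial-order effects (adaptation,
drift), correlated noise across neurons, non-unimodal or asymmetric tuning,
eye-position scatter, and stimulus-specific response structure. Passing
recovery tests therefore shows the estimator chain is unbiased and
calibrated for smooth unimodal tuning with independent trial noise — not
that every recorded neuron is of that kind.

## Tuning curves, smoothing, interpolation

Tuning functions are repetition means at each tested orientation, smoothed
with a width-3 boxcar before any correlation. Cross-condition values at
non-tested screen coordinates (retinal comparisons under body tilt sit ±19°
off the grid) are read with a uniform Catmull-Rom spline through the
smoothed values — an interpolating cubic, exact at control points, with
phantom endpoints linearly reflected (`p[-1] = 2p[0] − p[1]`) to preserve
the end slope. Frame transformation is applied to the *query* point; whole
curves are never resampled, so grid-aligned comparisons are exact table
lookups.

**Boxcar edge rule.** Interior points average their full window. Endpoints
are *copied unsmoothed* (`edge="copy"`, default). The alternative
shrink-to-valid rule (endpoint = mean of itself and its one neighbor) was
found to displace the effective endpoint sample by half a grid step; because
the two conditions' retinal queries approach opposite curve ends, that phase
error biases the counter-roll sweep by a systematic −1° and depresses
retinal correlations of centrally-tuned neurons. Copying preserves sample
phase and fabricates nothing beyond the tested range; `edge="shrink"`
remains available.

Both smoothing and spline readout are linear maps of the tuning values. The
composite read-out matrix (spline ∘ boxcar) is precomputed per frame, which
makes each permutation draw a single matrix product.

## Randomization tests

- **Per neuron.** Observed statistic: Pearson r between the two conditions'
  comparison values, monotonically equivalent to t = r√(n−2)/√(1−r²). Null:
  each condition's *raw* per-orientation means are independently permuted
  across tested orientations and pushed through the identical
  smoothing-and-readout chain. Re-applying smoothing is essential: permuting
  already-smoothed values breaks exchangeability (smoothed neighbors are
  serially correlated) and measured type-I error then inflates to 11–16% at
  nominal 5%, while the full-recomputation scheme is calibrated (5.0–5.5%
  measured on 400 untuned neurons). One-tailed, add-one estimator
  p = (1 + #{t_null ≥ t_obs})/(1 + n_perm); p is never 0 and its floor is
  1/(n_perm + 1). Default n_perm = 10,000.
- **Classification.** gravitational / retinal / both / neither by which
  one-tailed p-values fall below α = 0.05; zero-variance curves give an
  undefined r and the neuron is excluded (counted, never silently dropped).
- **Population.** Center of mass = arithmetic mean of per-neuron
  correlations on an axis; two-tailed permutation p with every neuron's
  values reshuffled per draw.
- **Counter-roll sweep.** For each candidate compensation angle, the
  geometry is rebuilt, retinal correlations of the selected
  (retina-classified) neurons recomputed, and the mean taken. Candidates
  whose comparison set shrinks below 3 points are invalid. The sweep is
  flagged uninformative when the curve range is below 0.05 or the maximum
  sits at the upper end of the swept range (a gravity-aligned selection
  rises monotonically toward full compensation and localizes nothing); a
  maximum at 0° is genuine because the decline away from it is observed.

## Decoding

Match pairs are cross-condition tested-orientation pairs whose coordinates
agree in the tested frame; a 1° tolerance absorbs the 0.5° residual left
because the 6° counter-roll is not a grid multiple (gravitational matches
are exact). Non-match pairs differ by >25° (cross- and within-condition,
canonical order so no pair is another's negation). Counts are equalized
across frames: 5 matches (one per balanced comparison orientation, the
candidate with the nearest frame midpoint) and 20 seeded-subsampled
non-matches. Each pseudo-trial draws one repetition per neuron per side
independently; the default feature is the per-neuron **absolute** response
difference |A − B|, which makes the task linearly separable (match features
concentrate at the origin, non-match features lie in the positive orthant).
Signed-difference and concatenation features are available; signed
differences cap noise-free LDA accuracy below 1 because non-match
difference vectors span opposing directions. Classifier: LDA with pooled
within-class covariance, diagonal shrinkage 0.1 (scale-invariant under
common feature scaling), stratified 10-fold CV, accuracy = 1 −
misclassification rate. Class imbalance (5:20 pair types) is retained, so
"chance" is the majority-class proportion, 0.8 by default.

## Validation problem sizes

The test suite validates calibration and recovery at sizes chosen to give
tight binomial intervals while keeping the default run quick: parameter
recovery on 200 neurons (half λ=1, half λ=0, amplitude/σ = 10) with 2,000
reshuffles; type-I calibration on 1,000 untuned neurons × 2,000 reshuffles
per frame; counter-roll localization on 60 retina-anchored neurons over
candidates 0–12°; decoder calibration on 40–89-neuron populations. The
analysis default of 10,000 reshuffles only lowers the attainable p-value
floor; calibration and recovery are insensitive to it.

## Known limitations

- Comparison points are snapped to grid multiples; alternative published
  display conventions (e.g. seven-point sets) are reproduced via
  `trim_leftmost`, not inferred.
- Counter-roll is modeled as a fixed angle opposing tilt, not a gain;
  a single magnitude is assumed for both tilt directions.
- Orientation is linear, not circular; designs spanning >200° would need
  wraparound handling throughout.
- The per-neuron test's power depends on tuning sharpness and peak position;
  broad or edge-peaked tuning in a 5-point comparison window is weakly
  identifiable at α = 0.05 regardless of noise level.
- LDA with shrinkage is one fixed decoder; accuracies are not tuned per
  population and should be read as lower bounds on linearly decodable
  information.
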