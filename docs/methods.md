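# Methods

This note documents the models, conventions and numerical choices
behind `rppgbp`, what the synthetic generators do and do not emulate,
and the known limitations.

## Signal model

The pulse pressure wave is modelled as a truncated harmonic series: a
DC term plus one fundamental,

    p(t) = a0 + e^(−z/c) · (Q·cos ωt + R·sin ωt),

where ω is the fundamental angular frequency (default 2π·1.2 rad/s,
i.e. 72 beats/min — a resting adult heart rate), z the subject-to-lens
distance in cm and c the wave velocity in cm/s, so the first harmonic
is attenuated by e^(−z/c) with distance. Higher harmonics of the real
arterial waveform are deliberately omitted: the zeroth and first orders
dominate the optically measured signal, and every downstream stage
(extrema, averages) is insensitive to the fine shape between extrema.

Observed channel means follow the linear instantaneous mixing model
X = A·S + ε with a full-column-rank mixing matrix A and i.i.d. Gaussian
sensor noise ε. The Gaussian choice is ours; nothing downstream depends
on the noise family, only on its scale. The artifact sources bundled
for fixtures (sawtooth drift, broadband noise) are generic stand-ins
chosen for the non-Gaussianity that blind separation requires — real
ambient-light flicker and motion artifacts are richer than this.

## Separation

The chain is classical fixed-point ICA. Channels are centered, then
whitened by V = D^(−1/2)E′ from the eigendecomposition of the channel
covariance (rank deficiency raises a degenerate-input error naming the
independent channel count). Unmixing rows are estimated with the
Newton-type update w ← E[z·g(wᵀz)] − E[g′(wᵀz)]·w, renormalised each
iteration. Defaults: the log-cosh contrast (g = tanh; robust for
sub- and super-Gaussian sources alike), with the cubic (kurtosis)
contrast as an option; deflation (row-by-row Gram–Schmidt) as the
decorrelation scheme, with symmetric decorrelation as an option;
convergence when |1 − |⟨w_new, w_old⟩|| < 1e−6, iteration cap 200,
`converged` reporting which branch stopped the loop. The number of
components defaults to the channel count (3 for RGB).

When the mixing matrix is approximately known (a semi-blind setting),
`ICAConfig.init_mixing` initialises W from the pseudo-inverse of the
whitened mixing matrix instead of randomly; the update loop is
identical. Separated components are defined only up to sign, scale and
permutation, so the pulse is then chosen as the component maximising
the fraction of (non-DC, un-detrended) periodogram power inside the
heart-rate band, default 0.7–3 Hz (42–180 bpm), clipped to Nyquist.
Polarity is standardised peaks-up (the excursion above the mean must
exceed the one below, else the sign is flipped) and the component is
rescaled to unit variance. That rescale is this package's normalisation
convention; the absolute scale of a camera-derived pulse is arbitrary,
and calibration and estimation are consistent as long as both use
features from the same extraction path.

## Features

Peaks and valleys are strict 3-point extrema; a flat run counts once,
at its first sample. The plausibility filter encodes that at 120
beats/min a peak and its neighbouring valley are 0.25 s apart: any
adjacent peak–valley pair (either order) closer than 0.25 s is a
disturbance, and the **later** member of the pair is discarded, the
rule re-applied until no violation remains. Exactly 0.25 s survives
(strict comparison). Discarding the later member is a convention; the
choice is isolated in one helper so the alternative is a one-line
change.

Per one-second window [w, w+1) — half-open, 0-based — the peak (valley)
amplitude is sum/count **truncated toward zero to two decimals**;
truncation, not rounding, is the convention the reference worked
example follows (e.g. 17.28/28 = 0.6171 reported as 0.61). Truncation
applies only at reporting boundaries; internal computation keeps full
precision. The implementation adds a 1e−9 guard before flooring so that
values that are exact two-decimal numbers in decimal (0.55) are not
pushed down by binary representation error. A session is ten valid
windows (configurable); its E_peak / E_valley are the arithmetic means
of the ten per-second values (the truncated per-window values, matching
the worked example's convention).

One known inconsistency in the reference worked example: the 8 s row's
printed averages (0.52, 0.22) do not follow from its own sums and
counts under any rounding mode (17.90/32 = 0.559, 7.41/32 = 0.2315);
that row is excluded from reproduction checks.

## Pressure model

    SBP = a0 + a1·E_peak   + BMI·(1 + a2·E_peak)
    DBP = a0 + a1·E_valley + BMI·(1 + a2·E_valley)

The parenthesised form is the only non-degenerate three-parameter
reading: expanding it gives the bilinear model
a0 + a1·x + BMI + a2·x·BMI, i.e. a four-parameter bilinear form with
the BMI coefficient pinned to 1, which is what makes three parameters
sufficient. Parameters live in a table of half-open BMI strata
(default width 2 kg/m² over [17, 29); both are configurable) with a
left-edge-inclusive lookup; a BMI outside the covered domain is an
out-of-range error naming the span. The table serialises to CSV and
JSON (columns `bmi_low,bmi_high,kind,a0,a1,a2`), with a spreadsheet
importer for parity with spreadsheet-maintained tables.

Reported agreement metrics: MAPE (fraction × 100, reported in percent),
RMSE, MAE, the sample standard deviation (N−1) of the **signed** errors
(a switch selects absolute-error STD instead), and R². The
absolute-error percentage for paired system/cuff readings divides by
the experimental (system) reading and truncates to two decimals — the
convention that reproduces the published comparison cells (one cell,
the near-distance diastolic pair, instead divides by the machine
reading and is excluded from reproduction checks).

## Hybrid optimizer

Calibration minimises prediction RMSE over (a0, a1, a2) in the box
[0, 120]³ with a Nelder–Mead / particle-swarm hybrid. Coefficients:
reflection α = 1, expansion γ = 2, contraction β = 0.5, shrink 0.5 (the
classical value; only the first three are externally specified),
acceleration c1 = c2 = 1.5 with per-particle per-dimension uniform
randoms, inertia w = 0.5. The population is 3N+1 particles for an
N-dimensional problem (10 at N = 3). Each iteration: sort; preserve the
N best; run one NM step (configurable via `nm_steps_per_iter`) on the
simplex of the best N+1 positions and write the resulting new vertex
into the (N+1)th particle; apply the PSO update to the whole population
but write positions, velocities and personal bests back only for the 2N
worst. The global best is only ever replaced by an improvement, so its
history is non-increasing; everything is deterministic under the config
seed (velocities initialise to zero for exact reproducibility).

Numerical choices that matter:

- **Velocity bounds.** The configured maximum velocity (120) is applied
  as a per-dimension magnitude clamp, |v| ≤ v_max, with the minimum
  velocity (0) meaning no lower speed bound. A one-sided clamp of v to
  [0, 120] would forbid all downhill moves inside the [0, 120] position
  box. Positions are clamped to the box after each move.
- **Box-aware Nelder–Mead.** Every NM trial point (reflection,
  expansion, contraction, shrink) is projected onto the box *before*
  evaluation. Projecting only the accepted point after the fact is
  unsound: the value that justified accepting the move belongs to an
  infeasible point, and at box corners this produced a deterministic
  livelock in which the same infeasible reflection was generated and
  clipped to the same mediocre feasible point every iteration.
- **Simplex restart on swarm collapse.** When the best N+1 particles
  become affinely dependent (the swarm has collapsed, typically onto a
  box corner where pbest = gbest kills the attraction terms), the NM
  simplex is rebuilt around the incumbent best with one vertex per axis
  at a 2%-of-box step, stepping inward at an active bound — the
  classical Nelder–Mead restart. This re-opens a descent path out of
  non-stationary corners.
- **Degenerate data.** Fits require ≥ 3 records with ≥ 3 distinct
  (feature, BMI) pairs; fewer raises an underdetermined error.

The calibration driver uses 300 iterations per fit (the generic default
is 100): the RMSE bowl of this model is narrow along the correlated
(a1, a2) directions and the extra refinement is cheap (each objective
evaluation is one vectorised pass over the stratum's records).

Per-stratum **data expansion** resamples a stratum's records into a
target number of groups (default 20) by bootstrap plus Gaussian feature
jitter of scale 1% of each feature's range, fits each group
independently, and averages the fitted triples component-wise. Zero
jitter degenerates to identical copies (so the average equals a single
fit), and an expansion target of 1 uses the stratum's records once,
unjittered.

## Synthetic cohorts and what passing tests show

`generate_cohort` draws BMI and both features uniformly (defaults:
BMI over the stratum, features over 0.1–0.9 — the range the published
per-second averages span), heights uniform over 1.5–1.9 m with weights
derived to reproduce the drawn BMI exactly, and reference pressures
from the formulas at known generating parameters (defaults
SBP (90, 10, 0.5), DBP (45, 8, 0.3) — resting-range pressures across
the BMI domain) plus Gaussian noise of configurable scale.

These cohorts establish *parameter recovery*: that the optimizer
drives prediction RMSE to ~0 on noiseless data and to the noise floor
at 2 mmHg noise. They do not establish clinical accuracy: real
reference pressures do not follow the model family exactly, features
are measured (not drawn independently of BMI), and the fitted triples
themselves are non-identifiable within narrow strata (near-collinear
regressors), which is why all recovery contracts are stated on
predictions, not coefficients. Likewise the separation tests use
stationary, exactly linearly mixed sources; real recordings add
non-stationarity, motion and illumination changes that ICA only
approximately removes.

One coherence caveat between stages: a zero-mean unit-variance pulse
has *negative* valley values, while the published amplitude tables
list positive valley magnitudes (their normalisation is unspecified).
The cohort generator follows the published positive ranges; the
end-to-end demo therefore extrapolates when it feeds pipeline-extracted
features into a table calibrated on generator-range features. A real
deployment calibrates and estimates with features from the same
extraction path, which removes the mismatch.

## Problem sizes

Defaults used by the test suite and the acceptance script: 2000–3000
samples for separation checks, 20 seeded runs for recovery and
optimizer-convergence rates, cohorts of 50 subjects per stratum, 6
strata, 100 optimizer iterations for the convergence benchmark and 300
for calibration fits. These sizes give stable statistics while keeping
a full run in the tens of seconds on one CPU.

## Limitations

- No camera, face-detection or ROI code: the input boundary is the
  per-frame channel-mean trace.
- The harmonic signal model omits dicrotic-notch morphology; features
  richer than peak/valley amplitudes (slopes, widths, transit times)
  are out of scope.
- The BMI-stratified linear model is a calibration device, not a
  physiological law; extrapolation outside the calibrated BMI domain is
  refused rather than attempted.
- No clinical-standard grading (AAMI/BHS) is implemented; the metrics
  module reports MAPE/RMSE/MAE/STD/R² only.
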