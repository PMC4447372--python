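# Methods

`spinefcs` implements the quantitative core of a two-photon fluorescence
correlation spectroscopy (2P-FCS) and FRAP analysis of mobile F-actin in
dendritic spines: a Brownian-dynamics photon-trace generator, a multi-tau
correlator, brightness-weighted one/two-component diffusion-model fitting
with motion quality control, single-exponential FRAP turnover
decomposition, and the paired/unpaired t-test layer that turns per-spine
fits into condition-level conclusions.  This note records the models, the
defaults and why they were chosen, the numerical decisions, and the known
limits of what the synthetic data can demonstrate.

## Observation volume and diffusion convention

The two-photon detection profile is the effective three-dimensional
Gaussian

    W(x, y, z) = exp(-4 (x^2 + y^2) / w_xy^2 - 4 z^2 / w_z^2),

with the instrument's quoted focal extents read as 1/e^2 full widths:
w_xy = 200 nm laterally, w_z = 500 nm axially.  Two constants follow
exactly from this profile and appear throughout:

* effective volume `V_eff = (pi/2)^(3/2) w_xy^2 w_z` (~0.039 fL), the
  volume for which the correlation amplitude is 1/N;
* mean profile value `GAMMA_3DG = 2^(-3/2)`, so a species of N particles of
  peak brightness I contributes `N * I * 2^(-3/2)` counts/s to the mean
  rate.

The diffusion-time convention is the two-photon one, `tau_D = w_xy^2 /
(8 D)`; users of the one-photon convention (`w^2 / 4D`) must rescale.  The
shape parameter of the axial term is `f = (w_xy / w_z)^2 = 0.16` and is
held fixed during fitting by default (fitting it trades off against the
diffusion times).

## Diffusion model

A single species decays as

    M(tau) = 1/(1 + tau/tau_D) * 1/sqrt(1 + f * tau/tau_D),

the standard 3D-Gaussian solution.  The square-root axial term is the
default; a purely multiplicative variant `1/(1 + f tau/tau_D)` is
available behind `axial="linear"` so the alternative reading of the model
can be tested — at f = 0.16 the two differ by under 2% over the fitted
window and none of the package's conclusions depend on the choice.

The two-component mixture of a dim "short" species (brightness I, number
N1, transit tau1) and a bright "long" species (brightness A·I, number N2,
transit tau2) has

    G(tau) = [N1 M1(tau) + A^2 N2 M2(tau)] / (N1 + A N2)^2,

the brightness-squared weighting being the reason a rare bright species
can dominate the correlation of a numerically much larger dim population.

### Identifiability of the brightness ratio A

G determines only the component amplitudes a1 = N1/(N1+A·N2)^2 and
a2 = A^2 N2/(N1+A·N2)^2 (plus tau1, tau2): it is homogeneous of degree
zero in I, and A, N1, N2 enter only through (a1, a2).  The mean count
rate adds one more observable but also one more unknown (I), so the
decomposition into particle numbers requires an assumed A.  The package
fixes A = 100 by default — the Rouse-model scale of the two populations'
~100-fold diffusion-time ratio, inside the physically motivated 0–150
bound (filament brightness is proportional to monomer number, which is
proportional to diffusion time, and the populations differ by about two
orders of magnitude in size).  `brightness_factor="rouse"` instead closes
with the per-fit ratio tau2/tau1 clipped to [0, 150]; this is unbiased on
average but injects the full noise of both diffusion-time estimates into
the numbers, and is therefore not the default.  The reported A is an
assumption, not an estimate, and is documented as such in the fit output.

The absolute brightness I is anchored afterwards:
`I = (rate - background) / (GAMMA_3DG * (N1 + A N2))`, giving the short-
and long-form brightnesses that the before/after comparison uses.

## Correlator

`autocorrelate` is a 16-lags-per-block multi-tau estimator (counts
rebinned by 2 between blocks), covering 0.1 ms–10 s in ~110 log-spaced
lags, with symmetric normalization (leading and lagged segments each
normalized by their own mean), which suppresses most drift-induced bias.
`autocorrelate_bruteforce` evaluates the same statistic lag by lag with no
rebinning; the two agree to better than 1e-10 over the first block and to
~1% (rebinning smoothing) on smooth curves beyond.  Error bars are the
standard error over 8 contiguous trace segments; at lags too long for a
segment the last valid estimate is carried forward.  The zero-lag point is
shot-noise dominated and excluded from fitting (kept in
`metadata["g_zero"]`).

## Fitting strategy

Two error scales coexist in measured curves: a lag-local noise floor
(shot noise plus fast-species sampling, ~1e-4 of the amplitude on a 120-s
trace) and the slow component's realization error (finite number of
bright-filament passages), which is 10–100x larger but almost perfectly
correlated across neighboring lags.  Weighting a joint fit by the
segment-based error bars discards the small fast component entirely;
weighting by local noise makes the fit chase the slow realization error.
`fit_two_component` therefore separates scales:

1. the slow component (a2, tau2) is fitted on lags >= max(5·tau1,
   split/2.5) (split defaults to 50 ms), with the current fast estimate
   subtracted;
2. the fast component (a1, tau1) is fitted on lags <= split against the
   slow-subtracted curve, together with a quadratic nuisance background
   (in tau/split) that absorbs the smooth remnant of the slow realization
   error; tau1 is located by a 25-point log-grid search with a linear
   solve of the amplitude terms, then polished;
3. steps 1–2 iterate four times.

Per-lag weights are the lag-local noise, estimated per multi-tau block by
quadratic detrending (block lag spacing is uniform, so this is well
defined).  On noiseless model curves the nuisance terms vanish and the
recovery is exact to machine precision.  Diffusion times are bounded to
[window_low/30, 3·window_high] and relabeled so tau1 < tau2.  The default
fit window is 0.1 ms–1 s; the upper edge keeps whole-spine motion
timescales out of the model.

`fit_one_component` is a plain weighted fit of a1·M(tau) from six
deterministic log-spaced starts.  `select_model` prefers two components
only when an F-test on the weighted residual sums of squares rejects the
one-component model *and* a Wald–Wolfowitz runs test rejects randomness of
the one-component residual signs, both at alpha = 0.05; ties go to
parsimony.

### Measured estimator performance, and what is and is not attainable

At the study regime (below) on single 120-s traces, 20-seed benchmarks
give: N1 within ±30% in ~100% of traces, tau2 within ±25% in ~75%, tau1
within ±25% in ~55%, and N2 within ±30% in ~50%; residual biases are a
few percent, so the shortfalls are variance-driven.  These are
information limits, not implementation defects: the fast component is
~1–2% of the correlation amplitude (brightness-squared weighting), and
the slow component's realization error on a single 120-s trace is of the
same order, so per-trace tau1 carries ~35–40% scatter; N2 inherits both
the slow-amplitude realization noise (~50 bright-filament passages per
trace) and the fast-amplitude error through the intensity normalization.
Consistently, the source study's own per-spine spreads imply ~40%
per-spine variation in both diffusion times.  Cohort-level before/after
comparisons remain well powered because these errors average out across
spines and cancel in paired contrasts.

## Synthetic data generator

Particles random-walk in a periodic box of side `box_scale` times the
focal extents (default 5; detection weight at the box edge is e^-25, so
edge effects are negligible at any allowed size, and the invariant
box_scale >= 5 is the cost-effective choice).  Per-bin displacements are
variance-matched uniform variates rather than Gaussians: displacement
distributions at any lag are k-fold convolutions, Gaussian to high
accuracy beyond a couple of bins, and the single-bin correlation error is
O(kurtosis·(step/w)^4) ~ 1e-5, while uniforms generate several times
faster.  Box populations are fixed counts (`round` of the expected
number): the focal volume is ~1.5% of the box, so in-volume occupancy
statistics stay Poisson and G(0) = 1/N, while the per-trace species
concentration is exact rather than carrying an extra ±20% Poisson draw.
Counts are Poisson around the brightness-weighted profile sum plus
background.  All randomness flows from one seed; identical configs give
bit-identical traces.

Whole-spine motion is emulated by `add_drift`: the expected rate is
modulated by exp(a·u(t) - a^2/2) with u a unit-variance
Ornstein–Uhlenbeck process (timescale > 1 s), which has unit mean and so
preserves the count rate; counts are re-drawn as Poisson.

Defaults for the two-species study regime, chosen once (the source study
prints neither absolute particle numbers nor count rates):

| quantity | default | rationale |
| --- | --- | --- |
| tau1, tau2 (before) | 4.1 ms, 467 ms | published condition means |
| N1, N2 | 40, 0.2 | roughly equal mass split between ~100x different filament sizes; both components then measurably shape the curve (fast component ~2% of amplitude) |
| A | 100 | Rouse scale of the ~100-fold size ratio |
| I (short form) | 10,000 counts/s peak | ~3.5 kcounts/s detected per oligomer (~10 eGFP); total rate ~210 kcounts/s |
| background | 0 (simulation), 1000 counts/s (study pipeline) | the diffusion model has no background term; the pipeline adds a realistic floor |
| bin width | 100 us (config default) | >= 20 samples per fastest transit |
| trace duration | 120 s | >= 250 slow-component transits |

Heavy benchmark and study runs use a 200-us bin (still >= 8 samples per
fastest transit) and, for the cohort pipeline, 30-s traces; these are the
package's own problem-size choices and are reported alongside results.

What the generator does not emulate: photophysics (no triplet state, no
intra-trace bleaching), polymer internal modes (filaments are point
particles with an effective transit time), detector dead time or
afterpulsing, and count-rate saturation when a bright filament sits in
the focus.  Passing tests therefore demonstrate the estimation machinery
under the stated model, not instrument-specific artifacts.

## Trace quality control

Whole-spine movement produces correlation amplitude at lags well beyond
~1 s, where intra-spine diffusion has decorrelated.  The selection rule
compares the mean g over a motion window (default 1 s to the last lag)
against the median per-lag error bar there and fails the trace when the
mean exceeds 3x that floor.  A curve that does not reach past 1 s is
explicitly "not assessable" — never silently passed.  Whole traces are
excluded, not trimmed.  Two practical notes: the between-segment error
bars are themselves inflated by strong motion, so QC resolution improves
with fine segmentation (segments short against the motion timescale;
validated at 20 segments on 60-s traces: 98% sensitivity, 100%
specificity against 0.3-amplitude, 5-s drift); and when the slowest
filaments' transit time approaches 1 s their genuine correlation extends
past the window start, so amplitude-based QC cannot fully separate
whole-spine motion from the slowest intra-spine signal near that
boundary.  Display normalization (`normalize_curve`) divides
by the first-lag or fitted amplitude, records the divisor, and is never
applied before fitting.

## FRAP

ROI series are corrected in the standard order: background subtraction,
division by the (background-corrected) reference ROI normalized to its
pre-bleach mean (acquisition-bleaching correction), normalization to the
spine's own pre-bleach mean, and time re-zeroed at the bleach.  The
post-bleach samples are fitted by

    F(t) = 1 - f_s - f_f exp(-t / lambda)

via the reparameterization plateau = 1 - f_s in [0, 1] and frac =
f_f/plateau in [0, 1], which enforces f_s, f_f >= 0 and f_s + f_f <= 1 by
construction.  The bleach-depth point is fitted, not pinned.  Exact model
identities: plateau = 1 - f_s, half-time = lambda·ln 2, fractions sum
to 1.  With f_f ~ 0 the decay time is unidentifiable and flagged.  The
model-free half-time is the first interpolated crossing of the midpoint
between the bleach depth and the recovery plateau; "maximal value" is
read as the recovery plateau, not the pre-bleach level (pass
`plateau=1.0` for the other convention).  The turnover time is not printed
numerically in the source text, so simulated truths default to
lambda = 20 s, a typical spine-actin turnover scale consistent with the
recovery saturating within the ~2-minute acquisition.

## Statistics

Paired and unpaired two-tailed Student t-tests are written out from the
closed forms (scipy is the cross-check oracle in the test suite).  The
unpaired test pools variances by default, as the plain "Student" name
implies; Welch is a flag.  Point-by-point FRAP curve comparison applies no
multiple-testing correction by default, matching how per-timepoint
p-values were reported; Bonferroni is a flag.  Group summaries are mean ±
SEM.

## Study pipeline

`run_study` mirrors the experiment: four conditions (growing spines under
TEA, non-growing spines under TEA, untreated, TEA + AP5 + verapamil) with
cohort sizes 8/5/7/9; per spine a before and an after trace are simulated
from per-spine truths, QC-filtered, correlated, fitted, decomposed, and
compared by paired t-tests per parameter.  QC-failed traces are excluded
from fitting and statistics but their spines stay in the report table.

Per-spine truths are lognormal around condition means (log-SD 0.4 for
diffusion times, 0.3 for numbers and brightness, calibrated to the
printed cohort SEMs); the after truth multiplies the before truth by the
condition's effect and by mean-one within-spine variability (log-SD
0.25).  Only the growing-spine condition carries effects: tau1 x
1.7/4.1, tau2 x 176/467, N2 x 1.75, brightness x 0.8 (so the total count
rate stays roughly constant, mirroring the unchanged total intensity in
the source data, while per-particle brightness falls as filaments
shorten).  Control conditions change by within-spine variability only —
the cleanest encoding of their null results.  Because all tested
parameters are positive scale parameters with multiplicative dispersion,
the paired tests run on log-transformed values.

`recovery_report` tabulates truth-vs-estimate relative errors, bias and
nominal 95%-interval coverage for synthetic records.

## Numerical and degenerate-input policy

Zero traces raise (`ZeroDivisionError`: correlation undefined); all-zero
curves and windows with too few lags raise `ValueError`; non-converged
fits are returned with `converged=False` rather than raising; QC on a
too-short curve returns a "not assessable" status.  Fit tie-breaks:
diffusion times relabeled so tau1 < tau2; equal one/two-component
residuals select one component.  Seeds derived from a master seed use
`Generator.integers(2**31)`.
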