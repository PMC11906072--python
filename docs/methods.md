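# Methods notes

This document records the modelling and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Beat editing and tachogram construction

Ectopic beats are the dominant artifact in RR streams.  The detector
flags beat *i* when its RR deviates from the median of its 11-beat
neighbourhood (excluding *i*) by more than a fraction `dev_frac`
(default 0.2).  A fixed, reproducible rule was preferred over
interactive editing; the threshold is a config knob.  Flagged beats are
deleted and each gap bridged by monotone piecewise-cubic (PCHIP)
interpolation of the surviving RR-vs-time curve, after which beat times
are rebuilt as cumulative RR sums so the rr↔time invariant holds again.
A window with more than 20 % of beats edited is rejected as unusable — a
usability guard in the spirit of the standard HRV task-force
recommendations, also configurable.

Spectral analysis needs an evenly sampled signal.  RR-vs-*time* (not
beat index) is interpolated with a cubic spline and sampled at 4 Hz over
a 120-s window: 2 Hz Nyquist comfortably clears the 0.4 Hz upper HF
edge, and 480 samples are dyadic-friendly for the wavelet stage.  A
coverage gap above 3 s aborts the window.

## Wavelet band power

LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) powers are computed with a
shift-invariant (maximal-overlap, non-decimated) Daubechies wavelet
*packet* decomposition, default `db12` (12 vanishing moments, 24 taps).
Two choices deserve explanation:

- **Packets rather than plain detail levels.**  Dyadic detail bands
  ([fs/2^{j+1}, fs/2^j]) cannot align with the 0.04/0.15/0.4 Hz edges,
  and attributing level variances to bands by nominal-band overlap
  fails badly when signal energy sits at a dyadic edge: a 0.25 Hz
  oscillation at fs 4 Hz splits its energy evenly between the level-3
  and level-4 details, of which only 60 % and 80 % nominally overlap
  HF, so the naive mapping loses ~30 % of the power.  A depth-6 packet
  tree has 0.031 Hz-wide nominal bands, and each packet's variance is
  attributed to LF/HF in proportion to the packet's *actual* squared
  transfer-function mass inside the band.  This reduces to fractional
  nominal overlap for ideal filters, respects filter leakage for real
  ones, and recovers A²/2 for pure tones anywhere in the band (the
  acceptance suite checks 15 % at two tone frequencies over 50 seeds,
  against an independent periodogram oracle).
- **Reflection + circular filtering.**  The depth-6 equivalent filter
  (1450 taps for db12) is longer than the 480-sample window, so
  excluding boundary-affected coefficients would exclude everything.
  Instead the mean-removed window is reflected once (making it
  circularly continuous) and the packet filters are applied as exact
  circular convolutions in the DFT domain.  Packet variances then
  partition the window variance exactly (machine precision), which the
  white-noise partition test asserts.

The filter order is a knob because "Daubechies-12" is ambiguous between
12 taps and 12 vanishing moments; both `db12` and shorter variants pass
the same tone oracles (the suite checks `db6`).  Normalized units are
defined as LF/(LF+HF)·100 — the conventional definition when a VLF band
is not reported.  Detrending is mean removal only.

## Baroreflex sequences

Classical spontaneous-sequence conventions: ramps are maximal runs of
≥ 3 beats with every per-beat SBP change exceeding 1 mmHg; the RR
segment is taken at a 1-beat lag by default (0–2 supported); a sequence
requires every per-beat RR change > 4 ms, concordant direction, and
regression r² ≥ 0.85; BRS is the unweighted mean slope and an estimate
needs ≥ 3 sequences (all knobs exposed).  The thresholds are applied
per adjacent beat pair, matching the "adjacent oscillations" reading.
The estimator's error message distinguishes "no ramps" (flat pressure
signal) from "ramps without RR response" (reflex absent/noisy), which
matters operationally.

## Pulse wave velocity and pressure calibration

The pulse foot uses the intersecting-tangent construction — the
consensus method in cfPWV devices: the crossing of the horizontal line
through the cycle's diastolic minimum with the tangent at the maximal
systolic upstroke slope, located to sub-sample precision by a quadratic
fit of the derivative peak (a max-second-derivative alternative sits
behind a flag).  Proximal and distal feet are matched by rank order;
mean transit over ≥ 10 matched beats is required for a valid result,
fewer beats only flags the result.  The carotid-femoral path distance
is multiplied by 0.8 (opposed propagation directions); other site pairs
use the measured distance unchanged.

Carotid calibration assumes pressure waveform shape is preserved from
brachial to carotid in the mean and minimum: a positive affine map
sends the waveform minimum to DBP and its time average to MAP, and the
rescaled maximum is the central systolic estimate.  MAP is an explicit
argument with a free-text source tag, because it may come from an
oscillometric cuff or from finger plethysmography and the two are not
interchangeable.

## Calorimetry

Weir coefficients 1.44·(3.94·V̇O₂ + 1.11·V̇CO₂) (flows in mL/min, result
kcal/day), no urinary-nitrogen term.  The steady-state search slides a
5-bin window over 1-min bins within minutes 5–15 (the first five
minutes are discarded), requires CV(V̇O₂) and CV(V̇CO₂) ≤ 10 % (sd/mean
of the 5 bins) and mean RER within 0.7–1.0, and among qualifying
windows keeps the lowest-REE one — the conservative choice when several
disjoint steady states exist.  AEE = TEE − (REE over the phase +
0.1·TEE); the identity aee + 0.1·tee + ree_over_phase = tee is asserted
to machine precision.  METs use each participant's measured resting
V̇O₂ rather than the 3.5 mL/kg/min convention (the convention is an
option).  Age-predicted HRmax is 220 − age; reserve percentages outside
[0, 100] are flagged, never clipped.  V̇O₂peak is the highest 10-s
average within the final 60 s, accepted when ≥ 2 of the five criteria
hold (≥ 90 % age-predicted HR, stage-to-stage plateau < 2.0 mL/kg/min,
RPE ≥ 18, RER ≥ 1.1, observer judgment); the plateau increment is a
caller-supplied stage statistic, since stage boundaries are protocol
knowledge the trace does not carry.

## Crossover mixed model

Outcome ~ condition × timepoint × group (full factorial, sum-to-zero
coding) + optional mean-centered covariates, with a random intercept
per participant, fitted by REML.  For a single variance component the
REML criterion is profiled over λ = τ²/σ² and optimised in one
dimension (bounded scalar search on log λ), with per-participant
Woodbury identities keeping each evaluation O(n).  Sum-to-zero coding
makes the per-term Wald F the type-III hypothesis; on balanced data all
classical ANOVA types coincide, and the test suite checks agreement
with both statsmodels' MixedLM (variance components, fixed effects) and
the classical between-participants ANOVA F.

Denominator degrees of freedom use the Satterthwaite approximation:
for a contrast ℓ, ν = 2φ²/Var(φ) with φ = ℓ'Ĉℓ, the gradient of φ in
(σ², τ²) by central differences, and the asymptotic covariance of
(σ̂², τ̂²) from the finite-difference observed REML information.  Multi-df
terms combine per-eigencontrast νᵣ as 2E/(E−q), E = Σνᵣ/(νᵣ−2) — the
same construction lmerTest uses.  On the balanced synthetic design
these reduce to the exact classical dfs (330 within / 22 between for
n = 12/group), and the 3-way interaction's null rejection rate
calibrates at 5 % (checked over 1000 replicates).  A τ̂² at the zero
boundary triggers a singular-fit warning and is equivalent to dropping
the random effect.

ω² = df₁(F−1)/(df₁(F−1)+df₁+df₂+1) was chosen because it reproduces the
published effect-size values from their printed F/df pairs; partial
η² = F·df₁/(F·df₁+df₂) is reported alongside with the Cohen-style
small/medium/large labels (0.05/0.25 cut-offs); negative ω² is reported
as computed.  Tukey-HSD post hocs act on estimated marginal means
averaged over the balanced factor grid (covariates at their means),
with the studentized-range family of all k marginal means and the
contrast's own Satterthwaite df; adjusted p can never undercut the raw
t-test p.  Group characteristics use Welch's t with
Welch–Satterthwaite df and 95 % CI, plus Shapiro-Wilk/Levene checks and
a Mann-Whitney U computed alongside when normality fails at 0.05.
`noncentral_f_power` is a documented utility for a-priori power
reasoning; mapping published effect sizes to noncentrality parameters
is software-convention dependent, so it makes no exact-replication
claim.

## Synthetic generators

Each generator takes a frozen spec with an explicit integer seed (no
global random state) and records its ground truth in the output
metadata.

- **RR tachograms**: RR(t) = mean + LF and HF sinusoids + Gaussian
  noise, beat times as cumulative RR sums; a tone of amplitude A holds
  A²/2 ms² of band power.  Ectopy is an isolated premature beat (0.6×
  local RR) plus a compensatory pause (1.4×), preserving the local mean
  — the simplest artifact the editing stage must catch.  Any RR
  ≤ 200 ms rejects the spec as non-physiological.
- **Baroreflex beats**: SBP alternates up/down ramps (per-beat steps
  uniform in [step, 1.5·step], so sub-threshold specs stay sub-threshold
  beat-wise); RR = base + gain·(SBP − base) at a configurable lag plus
  noise.
- **Waveform pairs**: a fixed analytic two-log-normal-bump beat template
  between DBP and SBP; the distal waveform is the template evaluated at
  delayed time, so the true transit is exact by construction.  Delays
  under half a sample period are rejected as unresolvable.
- **Gas traces**: resting flows with bounded noise inside the embedded
  steady segment (empirical CV ≤ cv_inside by construction) and a
  deterministic alternating ±3·cv_outside modulation outside, which
  guarantees every window touching a non-steady bin fails the CV
  criterion — iid noise alone cannot guarantee that postcondition.
- **Trial tables**: balanced 2×4×4 layout, participant intercepts and
  residuals Gaussian, cell shifts via an explicit effect map.  Defaults
  (n = 12/group, 4 conditions, 4 timepoints, between-SD 5, residual SD
  5) mirror the trial's design size.

What the generators deliberately do **not** emulate: respiratory sinus
arrhythmia and respiration coupling, 1/f RR backgrounds, pressure-wave
morphology changes with vasomotor tone, drift and breath-to-breath noise
structure of real gas analyzers, missing data and dropout.  Passing
tests therefore demonstrate estimator correctness against known truth,
not robustness to every physiological confound.

## Problem sizes and determinism

The simulation-based checks use sizes chosen to give stable Monte-Carlo
estimates while keeping the whole suite quick on one core: 50 seeds for
the spectral oracle, 300–500 beats for baroreflex recovery, 1000
replicates for the type-I calibration (binomial SE ≈ 0.7 %, asserted
band ±1.5 %), 40–60 replicates for power checks.  All randomness flows
from explicit seeds; `run_session` output is byte-deterministic given
its inputs and config.

## Known limitations

- The wavelet stage reports band power per window; no time-resolved
  (scalogram) output, no VLF, no nonlinear/Poincaré indices.
- Sequence BRS only; no spectral (α-index) or transfer-function BRS.
- Foot matching assumes proximal-before-distal ordering within a beat;
  no cross-correlation fallback for grossly misaligned recordings.
- The mixed model supports a single random intercept (the trial's
  design); random slopes or crossed random effects are out of scope.
- Readers handle the package's own CSV dialects, not device-native
  export formats.
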