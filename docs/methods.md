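# Methods

This note documents the models, conventions and numerical choices behind
`reachkin`, and what the synthetic-data validation does and does not
establish.

## Kinematic model

The forelimb is a tree rooted at the shoulder: shoulder → elbow → wrist →
{four digits}, each digit wrist → MCP → PIP → tip. The world frame is
right-handed with +Z up, +Y anterior (toward the reach targets) and +X to
the animal's right. The 24 angles are *extrinsic* Euler angles: each is
measured about a fixed world axis, and after each measurement the segment
and all of its children are counter-rotated ("neutralized") so that more
distal angles are measured in a parent-neutral frame.

Measurement order and axes:

| angle | axis | measured vector | neutral direction |
|---|---|---|---|
| shoulder_abd, shoulder_flex | Y, X | humerus (shoulder→elbow) | +Z |
| shoulder_rot, elbow_flex | Z, X | radius/ulna (elbow→wrist) | +Y |
| wrist_dev, wrist_flex | X, Z | vMC (wrist→mean(MCP2, MCP3)) | +Y |
| wrist_rot | Y | nMCP = (wrist→MCP2) × (wrist→MCP3) | +Z |
| opposition_MC1/4 | Y | wrist→MCP1/4 | template fan direction |
| splay_12 / splay_34 | Z | wrist→MCP1/4 azimuth | template fan direction |
| splay_23 | Z | opening between wrist→MCP2 and wrist→MCP3 | template opening |
| MCP_abd_d, MCP_flex_d | X, Z | proximal phalanx (MCP→PIP) | +Y |
| PIP_flex_d | X | distal phalanx (PIP→tip) | +Y |

Two constructions deserve comment. First, after wrist neutralization the
virtual metacarpus lies along +Y and the palm normal along +Z, which
forces MCP2 and MCP3 into the XY plane; the remaining degree of freedom
of that pair is a symmetric "scissor" opening, which is what `splay_23`
measures (the forward model solves the one-dimensional constraint in
closed form). Second, `PIP_flex` is the angle between the distal and
proximal phalanx; it is given a sign from the flexion direction in the
fully neutralized digit frame so that the parameterization stays
invertible. Because the wrist neutralization pins the paw frame
completely (two independent vectors are fixed), every distal angle is
exactly invariant to global rigid transforms of the keypoints; proximal
angles absorb them, as they must.

The neutral template is a stylized posture, not an anatomical rest pose:
humerus along +Z, forearm and phalanges along +Y, and the four wrist→MCP
vectors fanned at −90°, −45°, +45°, +90° azimuth in the palm plane.
The wide fan keeps every single-axis decomposition at least 10° away from
its gimbal degeneracy throughout the ±80° working range, which is what
makes the exact round trip (`IK∘FK = id` to <1e-6°, link lengths to
<1e-9 mm) possible. Default segment lengths (humerus 12 mm, radius/ulna
12 mm, metacarpus 4.5 mm, proximal/distal phalanx 2.5/2 mm) are
mouse-scale; all are configurable.

Degenerate measurements (projected vector shorter than 1e-8 of the
segment) are flagged and inherit the previous frame's value (0 at the
first frame). Angles are unwrapped in time per trial with a 180° jump
threshold. Angles are reported in degrees; internals are radians.

Paw aperture is the mean Euclidean distance of the four digit tips from
the centroid of the 12 digit markers — it responds to both digit splay
and MCP/PIP flexion and is rigid-transform invariant. The measure is a
plain function and can be swapped for any other frame-wise statistic.

## Event-locked preprocessing

All analyses run on a 10 ms grid, bins half-open `[t, t+10 ms)` with the
left edge at the locking event. Deconvolved events are resampled by
spreading each event's amplitude across the bins its ~32.2 ms source
frame overlaps (proportional to overlap), honoring each ROI's sub-frame
sampling offset; total amplitude is conserved inside the window.
Smoothing is a unit-mass Gaussian truncated at ±4 s.d. with reflective
edges (35 ms s.d. for neural traces, 15 ms for kinematics, 10 ms for
reaction-time projections; s.d. 0 is the identity).

Event amplitudes are normalized per ROI so the mode of the amplitude
distribution is 1: an Epanechnikov KDE with Silverman bandwidth is fit to
log amplitudes; since the amplitude-space density is g(s)e^(−s), its mode
solves (log g)′(s) = 1, which we obtain from a local quadratic fit to
log g over the density bulk — far more stable than taking the argmax of
the Jacobian-tilted product, which can jump into low-density tails. ROIs
with fewer than 20 positive events are left unscaled and flagged.

Trial screening uses per-side, per-angle bounds
(p₁+p₂)/2 ± |p₁−p₂| from the 2.5/97.5 percentiles over all trials ×
time points; a bin counts once if *any* angle is out of bounds and trials
with more than five offending bins are excluded. Movement-time grouping
splits each side at its median; trials exactly at the median go to
"long" (a deterministic tie rule).

## Time-series ZETA

The statistic is max |mean-centered (cumulative fraction − linear ramp)|
of the trial-averaged binned trace; it is invariant to positive rescaling
and zero for an exactly uniform trace. The null circularly permutes each
trial independently with shifts uniform on {1, …, B−1} (zero is excluded
so the identity permutation never contaminates the null) and is run on
unsmoothed binned data. With 100 shuffles the null maxima are summarized
by a Gumbel matched by moments (β = √(6v)/π, μ = m − γβ, γ the
Euler–Mascheroni constant). p-values are floored at machine epsilon.
Windows: cue and lift −200..+400 ms, contact −300..+300 ms, left and
right trials separately. Event-level modulation is Bonferroni-corrected
for the two sides (α/2), the overall call for all six tests (α/6); no
correction across ROIs is applied because the test serves as an inclusion
screen and an ROI-count correction would bias comparisons between
populations of different size. Calibration on constant-rate synthetic
ROIs gives a rejection rate of ~0.04–0.06 at α = 0.05 and a KS distance
from uniform of ~0.05 (the Gumbel tail is an approximation; exactness is
not claimed).

## Cross-validated PCA dimensionality

Five random 80/20 observation partitions; PCA on the training split
(training-mean centered); for each held-out observation each variable in
turn is hidden and its value reconstructed from the other 23 via
least-squares coordinates on the loading rows (ridge 1e-8 for
conditioning). The optimal rank minimizes the mean held-out error.
Candidates run 1..23: rank 24 is not identifiable from 23 remaining
variables. The procedure is deterministic given the seed and invariant
to variable reordering and to orthogonal rotation of the latents.

## Decoding

Trials — never time points — are the cross-validation unit; time samples
within a trial are strongly autocorrelated and splitting them would leak.

*Joint kinematics*: neural features are smoothed binned events reduced by
PCA to ⌊0.9 · n neurons⌋ components (fit on the training folds only),
then ridge regression with the penalty chosen by closed-form generalized
(leave-one-out) cross-validation on a 20-point log grid spanning the
squared-singular-value range; the selection rule is pluggable. Variance
explained is per joint on held-out trials, 1 − SSE/SStot with SStot about
the test-set mean pooled over (trial, time). 10 folds × 5 repeats give
50 fold estimates with each trial held out exactly five times; bagged
per-trial predictions average those five decoders. Optional lag
augmentation appends 10-ms-shifted feature copies (causal −100..0 ms or
acausal ±100 ms; shifted-in edge samples are zero). ROI selection takes
the 100 smallest minimum ZETA p-values (all, with a warning, if fewer).

*Target identity*: L2 logistic regression trained on all post-cue 10 ms
bins of the training trials (five stratified 80/20 trial splits),
evaluated per bin on held-out trials. The regularization is C = 1 in the
scikit-learn convention — the 1/n-scaled penalty that linear-classifier
routines default to. This matters: with many more ROIs than trials a
near-unregularized logistic converges toward a max-margin direction
dominated by single-trial noise, which destroys the projection-trace
signal-to-noise that the latency analyses depend on. Held-out
projections are signed so each trial's own class is positive and
normalized by the 90th percentile within trial type. The crossing
threshold is the midpoint of the across-trial median trace's extrema;
a crossing requires five consecutive supra-threshold bins and is linearly
interpolated at the run's leading edge; trials that never sustain a
crossing are discarded (NaN).

*Time generalization*: one classifier per non-overlapping 100 ms training
epoch (11 epochs for −100..+1000 ms), each tested on every 10 ms bin of
the held-out trials; entries are fold-mean accuracies (11 × 110).

*Reaction time*: a classifier discriminates the summed −100..0 ms from
the 0..+100 ms lift-locked bin; held-out lift-locked traces
(−200..+600 ms, 10 ms s.d. smoothing) are projected, the crossing offset
is added to the true RT, and the Pearson correlation of predicted vs true
RT is reported over trials with defined crossings.

*Residualization* is exact least squares with intercept (pseudo-inverse
with a warning if the regressors are rank deficient); it is a projection
(idempotent) and leaves residuals orthogonal to the regressors at machine
precision. Condition-mean residualization subtracts the per-target mean
trace.

## Synthetic sessions: what they emulate, and what they do not

Angle trajectories are a rank-r (default 7) linear image of latents: a
minimum-jerk-like reach ramp and a grasp close/open profile locked to
lift, a target-signed direction signal from ~50 ms post cue, and slow
smoothed-noise variability latents; loadings are scaled so all angles
stay within ±40° (gimbal-safe). Reaction times are a shifted log-normal
clipped to 0.15–0.6 s; movement times uniform 0.15–0.45 s; trials are 2 s
with the cue at 0.5 s, keypoints at 150 Hz. Tracking noise is isotropic
Gaussian (default 0.05 mm); optional glitch trials displace one marker by
20 mm for 100 ms. Neural intensity is
softplus(a + gain · w·[z(angles); z(velocities)] + target step drive) plus
a boxcar lift transient, sampled as Poisson counts per two-photon frame
(period 32.2 ms, per-ROI uniform sub-frame offsets) with log-normal
amplitude jitter whose mode is 1; a configurable fraction of ROIs is
strictly unmodulated. The per-ROI kinematic drive is normalized to unit
variance so `tuning_gain` sets modulation depth directly.

Named condition factories in `reachkin.synthetic` freeze the scenarios
used for validation: `zeta_null_conditions` (500 constant-rate ROIs, 40
trials), `zeta_power_conditions` (100 ms, 3× baseline transients, 50
trials), `linear_decoding_conditions` (100 ROIs, baseline 50 events/s,
modulation depth 100 — a high-rate regime in which the planted linear map
is recoverable through Poisson sampling), `target_latency_conditions`
(target-only populations with onsets 80 vs 140 ms), and
`rt_decoding_conditions` (strong lift transients). Default sessions use
60 trials; validation runs use 40–60 trials and 100–500 ROIs, sizes at
which every analysis completes in seconds on one CPU.

What passing these tests shows: the implementations recover planted
parameters (angles, ranks, latencies, reaction times, glitch trials) and
are statistically calibrated under their own null. What they do not
show: robustness to real tracking pathologies (identity swaps, occlusion,
skin slip), to calcium-indicator nonlinearity and deconvolution artifacts
(events are modeled directly, never fluorescence), to non-Poisson firing
statistics, or to nonlinear neural tuning. The latent reach profiles are
statistically adequate, not biomechanical; no muscle or torque model is
implied.

## Known limitations

- The inverse kinematics assigns signs by a fixed convention; absolute
  anatomical sign conventions (e.g. which direction is "abduction") are a
  labeling choice, and consistency, not anatomy, is the contract.
- The paw-base parameterization assumes MCP2/MCP3 straddle the virtual
  metacarpus; pathological tracking that collapses the palm triangle will
  trip the degeneracy flags rather than produce angles.
- The Gumbel tail with 100 shuffles is approximate; p-values near the
  floor should be read as "very small", not as exact tail mass.
- `decode_reaction_time` inherits a bias of its construction: predicted
  RT = true RT + crossing offset, so even offset noise that is
  independent of RT yields positive correlation; comparisons should use
  the permutation null (shuffle offsets across trials) as in the test
  suite.
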