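# reachkin

Analysis toolkit linking 3D forelimb pose tracking to joint-angle
kinematics and to neural population activity during head-fixed
reach-to-grasp behavior in mice. It is written for systems-neuroscience
labs that track ~15 forelimb keypoints with stereo cameras and record
layer-2/3 populations with two-photon calcium imaging, and for anyone who
needs a tested, seedable reference implementation of this analysis chain
on synthetic data.

## What it computes

**Kinematics.** Fifteen keypoints (four digit tips, four PIP joints, four
MCP joints, wrist, elbow, shoulder) are converted to 24 named joint angles
(7 proximal: shoulder abduction/flexion/rotation, elbow flexion, wrist
deviation/flexion/rotation; 17 distal: two oppositions, three splays, and
per-digit MCP abduction/flexion and PIP flexion). Each angle is the
extrinsic Euler angle about a fixed world axis that carries a limb segment
from its neutral direction to its observed direction; after each joint is
measured, its segment and all children are counter-rotated to neutralize
it, proceeding proximal to distal. The parameterization is exactly
invertible: `inverse_kinematics(forward_kinematics(θ)) = θ` to below
1e-6° for |θ| ≤ 80°, and forward kinematics preserves all inter-marker
link lengths. Paw aperture (mean distance of the digit tips from the
digit-marker centroid) yields the grasp events *collect* (first aperture
minimum after lift) and *extend* (next aperture maximum).

**Trial QA.** Per target side and joint angle, bounds
(p₁+p₂)/2 ± |p₁−p₂| are formed from the 2.5/97.5 percentiles over all
lift-locked samples; a trial is excluded when more than five 10-ms bins
have any angle out of bounds.

**Dimensionality.** Double-cross-validated PCA: observations *and*
variables are held out, the low-dimensional coordinates of a held-out
observation are regressed from its remaining variables, and the optimal
rank minimizes the held-out reconstruction error.

**Modulation (time-series ZETA).** For each ROI the trial-averaged,
event-locked fractional cumulative activity is compared with the linear
ramp of a uniform-rate cell; the statistic is max |mean-centered
deviation|. A null distribution from 100 per-trial circular permutations
is summarized by a moment-matched Gumbel (β = √(6v)/π, μ = m − γβ) whose
survival function gives the p-value.

**Decoding.** Joint angles/velocities are decoded with cross-validated
ridge regression (PCA rank = ⌊0.9 · n neurons⌋, 10-fold × 5 repeats = 50
folds, variance explained per joint on held-out trials). Target identity
is decoded per 10-ms bin with an L2 logistic classifier; single-trial
projections on the decoding axis give threshold-crossing latencies, and
training in separate 100-ms epochs produces an 11 × 110 temporal
generalization matrix. Reaction time is decoded by discriminating the
pre- from post-lift 100-ms bins and reading out each held-out trial's
projection crossing.

**Synthetic sessions.** `reachkin.synthetic` generates complete sessions
— latent-driven smooth angle trajectories, keypoints via forward
kinematics plus tracking noise, skewed reaction times, and deconvolved
calcium event trains (~31 Hz frames, per-ROI sub-frame offsets) with
linear kinematic tuning, latency-controlled target drive, lift-locked
transients and unmodulated null ROIs — with every planted parameter
recorded for recovery testing.

## Worked example

```python
import numpy as np
from reachkin import (SyntheticConfig, PopulationConfig, generate_session,
                      inverse_kinematics_trials, screen_trials, bin_kinematics,
                      bin_events_fractional, zeta_ts_pvalue,
                      cv_pca_dimensionality, decode_joint_timeseries,
                      RidgeConfig, select_rois)

cfg = SyntheticConfig(n_trials=40, seed=1,
                      populations={"M1": PopulationConfig(n_rois=120,
                                                          baseline_rate=30.0,
                                                          tuning_gain=45.0)})
ses = generate_session(cfg)

angles, flags = inverse_kinematics_trials(ses.keypoints, ses.template)
locked = bin_kinematics(angles.angles, angles.frame_times,
                        ses.events.lift_time, (-100, 400), 15.0)
qa = screen_trials(locked, ses.events.target)
print(f"retained {qa.retained.sum()}/{qa.retained.size} trials "
      f"(planted glitch trials: {ses.ground_truth.glitch_trials.tolist()})")

dims = cv_pca_dimensionality(locked[qa.retained].reshape(-1, 24), rng=0)
print(f"estimated angle dimensionality: {dims.optimal_dimensionality} "
      f"(planted latent rank: {cfg.latent_rank})")

binned = bin_events_fractional(ses.populations["M1"], ses.lock_times("lift"),
                               (-100, 400), "lift")
p = np.array([zeta_ts_pvalue(binned.data[qa.retained][:, r, :], 100,
                             rng=r).p_value for r in range(120)])
print(f"lift-modulated ROIs at p<0.05: {(p < 0.05).sum()}/120")

sel = select_rois(p, "top", 100)
res = decode_joint_timeseries(
    np.transpose(binned.data[qa.retained][:, sel, :], (0, 2, 1)),
    locked[qa.retained], RidgeConfig(seed=0))
print(f"joint decoding: median VE {np.median(res.median_ve):.2f} "
      f"(range {res.median_ve.min():.2f}-{res.median_ve.max():.2f} "
      f"across 24 angles)")
```

Output:

```
retained 38/40 trials (planted glitch trials: [6, 34])
estimated angle dimensionality: 14 (planted latent rank: 7)
lift-modulated ROIs at p<0.05: 87/120
joint decoding: median VE 0.82 (range 0.16-0.93 across 24 angles)
```

The two planted tracking-glitch trials are exactly the ones the QA
excludes. The dimensionality estimate (14) exceeds the planted latent
rank (7) because keypoint tracking noise propagated through inverse
kinematics adds independent variance to every angle — with noiseless
keypoints the estimate returns the planted rank exactly. At this
session's moderate event rates most angles decode well; the range
reflects angles whose variance is closest to the Poisson noise floor.

## Command line

```bash
reachkin run --outdir out --seed 7          # simulate + full analysis
reachkin simulate --outdir out --seed 7     # or stage by stage
reachkin zeta --outdir out
reachkin report --outdir out                # assemble report.json
```

Each stage caches its artifact (HDF5/CSV/JSON) in the output directory,
so single stages can be re-run against cached upstream results. The
report is timestamp-free: identical configuration and seed give a
byte-identical `report.json`.

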