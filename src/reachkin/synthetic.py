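"""Synthetic reach-to-grasp sessions with full ground truth.

Sessions emulate the structure of a head-fixed two-target water-reaching
experiment: smooth multi-joint angle trajectories built from a small
number of shared latents (reach, grasp, target-direction and slow
variability components), keypoints produced by forward kinematics plus
isotropic tracking noise, trial event timing with skewed reaction times,
and deconvolved-event neural populations whose ROIs combine linear tuning
to joint angles/velocities, target-dependent drive with a configurable
onset latency, event-locked transients, and a strictly unmodulated null
fraction.  Every planted parameter is recorded in :class:`GroundTruth`
so analyses can be validated by parameter recovery.

The latent reach profiles are minimum-jerk-like sigmoids and Gaussian
bumps; they are statistically adequate stand-ins for real kinematics, not
biomechanical simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .kinematics import (
    ANGLE_NAMES,
    JointAngleTensor,
    KeypointSession,
    N_ANGLES,
    SkeletonTemplate,
    forward_kinematics,
    joint_velocities,
)
from .preprocess import DEFAULT_FRAME_PERIOD, LEFT, RIGHT, PopulationActivity, TrialEvents


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PopulationConfig:
    """One imaged population's planted tuning structure."""

    n_rois: int = 150
    frac_unmodulated: float = 0.3
    frac_target: float = 0.4  # fraction of tuned ROIs with target drive
    frac_lift_transient: float = 0.4
    baseline_rate: float = 5.0  # events/s
    tuning_gain: float = 4.0  # rate modulation from kinematic drive
    target_gain: float = 4.0
    target_latency_ms: float = 80.0  # onset of target drive after cue
    target_code: str = "static"  # or "rotating": axis drifts over the trial
    target_rotation_period_s: float = 1.0  # half-turn time of a rotating code
    transient_amp_factor: float = 2.0  # transient adds factor x baseline
    transient_width_ms: float = 100.0  # boxcar width
    transient_latency_ms: float = 0.0  # relative to lift
    amplitude_sigma: float = 0.3  # lognormal event-size jitter


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic session."""

    n_trials: int = 60
    trial_length_s: float = 2.0
    cue_time_s: float = 0.5
    frame_rate_hz: float = 150.0
    frame_period_s: float = DEFAULT_FRAME_PERIOD
    keypoint_noise_sd_mm: float = 0.05
    latent_rank: int = 7
    angle_noise_sd_deg: float = 0.0
    angle_scale_deg: float = 40.0  # peak structured excursion
    # reaction times: shifted log-normal, clipped to [rt_min, rt_max]
    rt_shift_s: float = 0.15
    rt_median_s: float = 0.12
    rt_sigma: float = 0.5
    rt_max_s: float = 0.60
    # movement (lift -> contact) times, uniform
    mt_range_s: tuple = (0.15, 0.45)
    # grasp profile timing relative to lift
    collect_lag_s: float = 0.10
    extend_lag_s: float = 0.22
    glitch_fraction: float = 0.05  # trials with planted tracking glitches
    glitch_amplitude_mm: float = 20.0
    glitch_duration_s: float = 0.10
    populations: dict = field(default_factory=lambda: {
        "A": PopulationConfig(target_latency_ms=80.0),
        "B": PopulationConfig(target_latency_ms=140.0,
                              frac_lift_transient=0.6,
                              transient_amp_factor=3.0),
    })
    seed: int = 0

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.latent_rank < 3 or self.latent_rank > N_ANGLES:
            raise ValueError("latent_rank must be in 3..24")
        if self.keypoint_noise_sd_mm < 0:
            raise ValueError("noise sd must be nonnegative")


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic session."""

    angles: JointAngleTensor
    latents: np.ndarray  # (n_trials, n_time, r)
    loadings: np.ndarray  # (r, 24)
    latent_rank: int
    reaction_times: np.ndarray
    collect_times: np.ndarray  # trial-relative, s
    extend_times: np.ndarray
    glitch_trials: np.ndarray
    populations: dict = field(default_factory=dict)  # name -> planted dict
    seed: int = 0


@dataclass
class SyntheticSession:
    """Complete generated session bundle."""

    keypoints: KeypointSession
    events: TrialEvents  # trial-relative times
    populations: dict  # name -> PopulationActivity (absolute event times)
    ground_truth: GroundTruth
    config: SyntheticConfig
    template: SkeletonTemplate

    def lock_times(self, event: str) -> np.ndarray:
        """Absolute (session-clock) per-trial times of a locking event."""
        rel = self.events.event_times(event)
        starts = np.arange(self.events.n_trials) * self.config.trial_length_s
        return starts + rel


# ---------------------------------------------------------------------------
# latent profiles
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _bump(t, center, width):
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def generate_angle_trajectories(config: SyntheticConfig,
                                rng: np.random.Generator | None = None):
    """Joint angle tensor from ``latent_rank`` shared latents.

    Latent 0 is a minimum-jerk-like reach ramp locked to lift; latent 1 a
    grasp close/open profile (flexion peak at ``collect_lag_s``, dip at
    ``extend_lag_s`` after lift); latent 2 a target-signed direction
    signal from shortly after the cue; remaining latents are slow
    smoothed-noise variability.  Angles are a fixed rank-``r`` linear
    image of the latents (plus optional angle-specific noise), with
    loadings scaled so every angle stays within the gimbal-safe range.

    Returns (JointAngleTensor, TrialEvents, GroundTruth-fields dict).
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    n_tr = config.n_trials
    dt = 1.0 / config.frame_rate_hz
    t = np.arange(0.0, config.trial_length_s, dt)
    n_t = t.size
    r = config.latent_rank

    # trial events
    z = rng.standard_normal(n_tr)
    rt = config.rt_shift_s + config.rt_median_s * np.exp(config.rt_sigma * z)
    rt = np.clip(rt, config.rt_shift_s, config.rt_max_s)
    mt = rng.uniform(*config.mt_range_s, size=n_tr)
    cue = np.full(n_tr, config.cue_time_s)
    lift = cue + rt
    contact = lift + mt
    target = np.where(rng.random(n_tr) < 0.5, LEFT, RIGHT)
    sign = np.where(target == RIGHT, 1.0, -1.0)

    # structured latents, lift-locked
    lat = np.zeros((n_tr, n_t, r))
    amp = 1.0 + 0.2 * rng.standard_normal((n_tr, 3))
    for i in range(n_tr):
        tl = t - lift[i]
        lat[i, :, 0] = amp[i, 0] * _sigmoid((tl - 0.04) / 0.08)
        lat[i, :, 1] = amp[i, 1] * (
            _bump(tl, config.collect_lag_s, 0.04)
            - 0.6 * _bump(tl, config.extend_lag_s, 0.05)
        )
        lat[i, :, 2] = amp[i, 2] * sign[i] * _sigmoid((t - cue[i] - 0.05) / 0.02)
    # slow variability latents
    if r > 3:
        noise = rng.standard_normal((n_tr, n_t, r - 3))
        noise = gaussian_filter1d(noise, sigma=0.15 / dt, axis=1, mode="reflect")
        sd = noise.std(axis=(0, 1), keepdims=True)
        lat[:, :, 3:] = noise / np.where(sd > 0, sd, 1.0)
    peak = np.abs(lat).max(axis=(0, 1), keepdims=True)
    lat /= np.where(peak > 0, peak, 1.0)

    # loadings: structured rows touch specific angle groups, noise rows dense
    w = np.zeros((r, N_ANGLES))
    idx = {n: i for i, n in enumerate(ANGLE_NAMES)}
    reach = ["shoulder_abd", "shoulder_flex", "shoulder_rot", "elbow_flex",
             "wrist_dev", "wrist_flex"]
    grasp = ([f"MCP_flex_{d}" for d in range(1, 5)]
             + [f"PIP_flex_{d}" for d in range(1, 5)]
             + ["splay_12", "splay_23", "splay_34", "wrist_flex"])
    direction = ["shoulder_abd", "shoulder_rot", "wrist_dev", "opposition_MC1",
                 "opposition_MC4"]
    for names, row, lo in ((reach, 0, 0.5), (grasp, 1, 0.5), (direction, 2, 0.4)):
        for n in names:
            w[row, idx[n]] = rng.uniform(lo, 1.0) * rng.choice([1.0, 1.0, -1.0])
    # grasp latent closes the paw: positive flexion curls tips inward
    for d in range(1, 5):
        w[1, idx[f"MCP_flex_{d}"]] = abs(w[1, idx[f"MCP_flex_{d}"]])
        w[1, idx[f"PIP_flex_{d}"]] = abs(w[1, idx[f"PIP_flex_{d}"]])
        w[1, idx[f"splay_{min(d, 3)}{min(d, 3) + 1}"]] = -abs(
            w[1, idx[f"splay_{min(d, 3)}{min(d, 3) + 1}"]])
    # reach latent elevates the paw (+Z): flex both shoulder and elbow
    w[0, idx["shoulder_flex"]] = max(abs(w[0, idx["shoulder_flex"]]), 0.8)
    w[0, idx["elbow_flex"]] = max(abs(w[0, idx["elbow_flex"]]), 0.8)
    if r > 3:
        w[3:, :] = 0.25 * rng.standard_normal((r - 3, N_ANGLES))
    # keep every angle inside the gimbal-safe working range
    total = np.abs(w).sum(axis=0)
    w *= config.angle_scale_deg / np.maximum(total.max(), 1e-12)

    ang = lat.reshape(-1, r) @ w
    if config.angle_noise_sd_deg > 0:
        ang = ang + config.angle_noise_sd_deg * rng.standard_normal(ang.shape)
    ang = ang.reshape(n_tr, n_t, N_ANGLES)

    angles = JointAngleTensor(angles=ang, frame_times=t)
    events = TrialEvents(cue_time=cue, lift_time=lift, contact_time=contact,
                         target=target)
    extras = {
        "latents": lat, "loadings": w,
        "reaction_times": rt,
        "collect_times": lift + config.collect_lag_s,
        "extend_times": lift + config.extend_lag_s,
    }
    return angles, events, extras


# ---------------------------------------------------------------------------
# keypoints
# ---------------------------------------------------------------------------


def generate_keypoints(
    angles: JointAngleTensor,
    template: SkeletonTemplate,
    noise_sd: float,
    rng: np.random.Generator | int | None = None,
    glitch_trials: np.ndarray | None = None,
    glitch_window_s: tuple | None = None,
    glitch_amplitude: float = 20.0,
) -> KeypointSession:
    """Forward kinematics plus isotropic Gaussian tracking noise.

    ``glitch_trials`` optionally receive a large marker displacement over
    ``glitch_window_s`` (per-trial (start, stop) seconds) to emulate
    transient tracking failures.
    """
    rng = np.random.default_rng(rng)
    kp = forward_kinematics(angles.angles, template)
    if noise_sd > 0:
        kp = kp + noise_sd * rng.standard_normal(kp.shape)
    if glitch_trials is not None and len(glitch_trials):
        t = angles.frame_times
        for i, tr in enumerate(np.asarray(glitch_trials)):
            w0, w1 = glitch_window_s[i]
            m = (t >= w0) & (t < w1)
            marker = int(rng.integers(0, 15))
            kp[tr, m, marker, :] += glitch_amplitude * rng.choice([-1.0, 1.0], 3)
    return KeypointSession(positions=kp, frame_times=angles.frame_times)


# ---------------------------------------------------------------------------
# neural populations
# ---------------------------------------------------------------------------


def _softplus(x):
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _inv_softplus(y):
    return float(np.log(np.expm1(y)))


def generate_neural_population(
    angles: JointAngleTensor,
    events: TrialEvents,
    pop: PopulationConfig,
    trial_length_s: float,
    frame_period_s: float = DEFAULT_FRAME_PERIOD,
    rng: np.random.Generator | int | None = None,
    kinematic_drive: np.ndarray | None = None,
):
    """Deconvolved-event trains for one population.

    Per tuned ROI the event intensity (events/s) is

        softplus(a + gain * w . [z(angles); z(velocities)]
                   + target_gain * w_t * step(t - cue - latency))
        + transient(t - lift)

    with ``a`` the softplus inverse of the baseline rate, and a boxcar
    transient of amplitude ``transient_amp_factor x baseline`` over
    ``transient_width_ms``.  Events are Poisson counts per two-photon
    frame (sampled at the ROI's within-frame offset) with log-normal
    amplitude jitter.  Unmodulated ROIs have strictly constant intensity.

    Returns (PopulationActivity, planted-parameter dict).
    """
    rng = np.random.default_rng(rng)
    if pop.baseline_rate <= 0:
        raise ValueError("baseline rate must be positive")
    n_tr, n_t, _ = angles.angles.shape
    t = angles.frame_times
    dt = float(t[1] - t[0])
    feats = np.concatenate(
        [angles.angles, joint_velocities(angles.angles, dt)], axis=2
    ).reshape(-1, 2 * N_ANGLES)
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    feats = (feats - mu) / np.where(sd > 0, sd, 1.0)
    feats = feats.reshape(n_tr, n_t, 2 * N_ANGLES)

    n = pop.n_rois
    n_unmod = int(round(pop.frac_unmodulated * n))
    tuned = np.arange(n_unmod, n)
    modulated = np.zeros(n, dtype=bool)
    modulated[tuned] = True

    # dense heterogeneous tuning: every tuned ROI weights all angle and
    # velocity features (unit-expected-norm random projection)
    wkin = np.zeros((n, 2 * N_ANGLES))
    wkin[tuned] = rng.standard_normal((tuned.size, 2 * N_ANGLES)) / np.sqrt(2 * N_ANGLES)
    wtar = np.zeros(n)
    wtar2 = np.zeros(n)  # second pattern, used by a rotating target code
    tar_rois = rng.choice(tuned, size=int(round(pop.frac_target * tuned.size)),
                          replace=False)
    wtar[tar_rois] = rng.choice([-1.0, 1.0], tar_rois.size)
    wtar2[tar_rois] = rng.choice([-1.0, 1.0], tar_rois.size)
    tamp = np.zeros(n)
    tr_rois = rng.choice(tuned, size=int(round(pop.frac_lift_transient * tuned.size)),
                         replace=False)
    tamp[tr_rois] = pop.transient_amp_factor * pop.baseline_rate

    offsets = rng.uniform(0.0, frame_period_s, size=n)
    a0 = _inv_softplus(pop.baseline_rate)
    lat_s = pop.target_latency_ms / 1000.0
    width_s = pop.transient_width_ms / 1000.0
    sign = np.where(np.asarray(events.target) == RIGHT, 1.0, -1.0)

    if kinematic_drive is not None:
        drive = np.asarray(kinematic_drive, dtype=float).reshape(-1, n)
    else:
        drive = feats.reshape(-1, 2 * N_ANGLES) @ wkin.T  # (frames150, n)
    dsd = drive.std(axis=0)
    drive = drive / np.where(dsd > 0, dsd, 1.0)  # unit-sd drive per ROI
    drive = drive.reshape(n_tr, n_t, n)

    ev_times, ev_amps = [], []
    frame_starts = np.arange(0.0, trial_length_s - frame_period_s, frame_period_s)
    mode_correction = np.exp(pop.amplitude_sigma**2)  # lognormal mode at 1
    for r_i in range(n):
        ts = frame_starts + offsets[r_i]  # sample times within trial
        times, amps = [], []
        for i in range(n_tr):
            if modulated[r_i]:
                d = np.interp(ts, t, drive[i, :, r_i])
                x = a0 + pop.tuning_gain * d
                if pop.target_code == "rotating":
                    ph = np.pi * (ts - events.cue_time[i]) / pop.target_rotation_period_s
                    wt = np.cos(ph) * wtar[r_i] + np.sin(ph) * wtar2[r_i]
                else:
                    wt = wtar[r_i]
                x = x + (pop.target_gain * wt * sign[i]
                         * _sigmoid((ts - events.cue_time[i] - lat_s) / 0.01))
                rate = _softplus(x)
                dtl = ts - events.lift_time[i] - pop.transient_latency_ms / 1000.0
                rate = rate + tamp[r_i] * ((dtl >= 0) & (dtl < width_s))
            else:
                rate = np.full(ts.size, pop.baseline_rate)
            counts = rng.poisson(rate * frame_period_s)
            nz = np.flatnonzero(counts)
            if nz.size:
                reps = counts[nz]
                times.append(np.repeat(ts[nz] + i * trial_length_s, reps))
                amps.append(rng.lognormal(0.0, pop.amplitude_sigma,
                                          int(reps.sum())) * mode_correction)
        ev_times.append(np.concatenate(times) if times else np.empty(0))
        ev_amps.append(np.concatenate(amps) if amps else np.empty(0))

    activity = PopulationActivity(
        event_times=ev_times, event_amplitudes=ev_amps,
        frame_period=frame_period_s, roi_offsets=offsets,
    )
    planted = {
        "tuning_weights": wkin, "target_weights": wtar,
        "target_weights_2": wtar2, "target_code": pop.target_code,
        "target_latency_ms": pop.target_latency_ms,
        "transient_amplitudes": tamp,
        "transient_latency_ms": pop.transient_latency_ms,
        "transient_width_ms": pop.transient_width_ms,
        "modulated": modulated, "baseline_rate": pop.baseline_rate,
    }
    return activity, planted


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------


def generate_session(config: SyntheticConfig | None = None,
                     seed: int | None = None) -> SyntheticSession:
    """Generate a complete synthetic session (keypoints, events, two
    populations, ground truth).  Fully deterministic given the seed."""
    config = config or SyntheticConfig()
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)

    angles, events, extras = generate_angle_trajectories(
        config, rng=np.random.default_rng(rng.integers(2**31 - 1)))
    template = SkeletonTemplate.default()

    n_glitch = int(round(config.glitch_fraction * config.n_trials))
    glitch_rng = np.random.default_rng(rng.integers(2**31 - 1))
    glitch_trials = np.sort(glitch_rng.choice(config.n_trials, size=n_glitch,
                                              replace=False))
    starts = events.lift_time[glitch_trials] + glitch_rng.uniform(
        0.0, 0.2, size=n_glitch)
    windows = [(s, s + config.glitch_duration_s) for s in starts]
    keypoints = generate_keypoints(
        angles, template, config.keypoint_noise_sd_mm,
        rng=np.random.default_rng(rng.integers(2**31 - 1)),
        glitch_trials=glitch_trials, glitch_window_s=windows,
        glitch_amplitude=config.glitch_amplitude_mm,
    )

    populations, planted = {}, {}
    for name in sorted(config.populations):
        act, plant = generate_neural_population(
            angles, events, config.populations[name], config.trial_length_s,
            config.frame_period_s,
            rng=np.random.default_rng(rng.integers(2**31 - 1)),
        )
        populations[name] = act
        planted[name] = plant

    gt = GroundTruth(
        angles=angles, latents=extras["latents"], loadings=extras["loadings"],
        latent_rank=config.latent_rank,
        reaction_times=extras["reaction_times"],
        collect_times=extras["collect_times"],
        extend_times=extras["extend_times"],
        glitch_trials=glitch_trials, populations=planted, seed=config.seed,
    )
    return SyntheticSession(keypoints=keypoints, events=events,
                            populations=populations, ground_truth=gt,
                            config=config, template=template)


# ---------------------------------------------------------------------------
# named study conditions for parameter-recovery analyses
# ---------------------------------------------------------------------------


def linear_decoding_conditions(seed: int = 0) -> SyntheticConfig:
    """A 100-ROI population linearly tuned to all angles and velocities at
    high event rates (baseline 50 events/s, modulation depth 100 in
    softplus-input units per drive s.d.), the condition under which the
    planted linear map is recoverable by ridge decoding."""
    return SyntheticConfig(seed=seed, glitch_fraction=0.0, populations={
        "A": PopulationConfig(n_rois=100, frac_unmodulated=0.0, frac_target=0.0,
                              frac_lift_transient=0.0, baseline_rate=50.0,
                              tuning_gain=100.0)})


def target_latency_conditions(seed: int = 0, latency_a_ms: float = 80.0,
                              latency_b_ms: float = 140.0) -> SyntheticConfig:
    """Two populations whose only target-discriminating signal is a step
    drive along a fixed axis, with onsets 60 ms apart by default."""
    def mk(lat):
        return PopulationConfig(n_rois=100, frac_unmodulated=0.0,
                                frac_target=1.0, frac_lift_transient=0.0,
                                tuning_gain=0.0, baseline_rate=30.0,
                                target_gain=15.0, target_latency_ms=lat)
    return SyntheticConfig(seed=seed, glitch_fraction=0.0,
                           populations={"A": mk(latency_a_ms), "B": mk(latency_b_ms)})


def rotating_code_conditions(seed: int = 0, code: str = "rotating") -> SyntheticConfig:
    """Target-coding population whose decoding axis either stays fixed
    ('static') or drifts over the trial ('rotating', half turn in 0.8 s)."""
    return SyntheticConfig(seed=seed, glitch_fraction=0.0, populations={
        "A": PopulationConfig(n_rois=100, frac_unmodulated=0.0, frac_target=1.0,
                              frac_lift_transient=0.0, tuning_gain=0.0,
                              baseline_rate=30.0, target_gain=15.0,
                              target_latency_ms=80.0, target_code=code,
                              target_rotation_period_s=0.8)})


def zeta_null_conditions(seed: int = 0, n_rois: int = 500,
                         n_trials: int = 40) -> SyntheticConfig:
    """A purely unmodulated (constant-rate) population for null calibration."""
    return SyntheticConfig(seed=seed, n_trials=n_trials, glitch_fraction=0.0,
                           populations={"A": PopulationConfig(
                               n_rois=n_rois, frac_unmodulated=1.0)})


def zeta_power_conditions(seed: int = 0, n_rois: int = 100,
                          n_trials: int = 50) -> SyntheticConfig:
    """ROIs carrying a 100 ms lift-locked transient at 3x baseline rate."""
    return SyntheticConfig(seed=seed, n_trials=n_trials, glitch_fraction=0.0,
                           populations={"A": PopulationConfig(
                               n_rois=n_rois, frac_unmodulated=0.0,
                               frac_target=0.0, frac_lift_transient=1.0,
                               tuning_gain=0.0, transient_amp_factor=2.0,
                               transient_width_ms=100.0)})


def rt_decoding_conditions(seed: int = 0) -> SyntheticConfig:
    """Strong lift-locked transients for reaction-time readout."""
    return SyntheticConfig(seed=seed, glitch_fraction=0.0, populations={
        "A": PopulationConfig(n_rois=100, frac_unmodulated=0.0, frac_target=0.0,
                              frac_lift_transient=1.0, tuning_gain=0.0,
                              baseline_rate=20.0, transient_amp_factor=5.0,
                              transient_width_ms=100.0)})
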