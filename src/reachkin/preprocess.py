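"""Event-locked binning, smoothing, amplitude rescaling, trial QA and PETHs.

Deconvolved calcium events arrive on a ~31 Hz frame clock (frame period
about 32.2 ms) with a per-ROI sub-frame sampling offset set by where the
ROI centroid sits in the scan.  All analyses run on a common 10 ms grid
locked to a trial event; events are resampled by spreading each event's
amplitude over the 10 ms bins in proportion to how much each bin overlaps
the event's source frame, which conserves total amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

DEFAULT_FRAME_PERIOD = 0.0322  # s, two-photon frame clock
BIN_MS = 10.0

LEFT, RIGHT = "left", "right"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TrialEvents:
    """Per-trial task events (absolute seconds) and target side."""

    cue_time: np.ndarray
    lift_time: np.ndarray
    contact_time: np.ndarray
    target: np.ndarray  # "left" / "right"

    def __post_init__(self):
        self.cue_time = np.asarray(self.cue_time, dtype=float)
        self.lift_time = np.asarray(self.lift_time, dtype=float)
        self.contact_time = np.asarray(self.contact_time, dtype=float)
        self.target = np.asarray(self.target)

    @property
    def n_trials(self) -> int:
        return self.cue_time.size

    @property
    def reaction_time(self) -> np.ndarray:
        """Cue-to-lift interval, s."""
        return self.lift_time - self.cue_time

    @property
    def movement_time(self) -> np.ndarray:
        """Lift-to-first-contact interval, s."""
        return self.contact_time - self.lift_time

    def event_times(self, name: str) -> np.ndarray:
        return {"cue": self.cue_time, "lift": self.lift_time,
                "contact": self.contact_time}[name]

    def side_mask(self, side: str) -> np.ndarray:
        return self.target == side


@dataclass
class PopulationActivity:
    """Deconvolved event trains for one imaged population.

    event_times / event_amplitudes : list (one array per ROI) of event
        sample times (s, already including the ROI's sub-frame offset) and
        nonnegative amplitudes (a.u.).
    frame_period : s (~0.0322).
    roi_offsets : (n_rois,) s in [0, frame_period), the within-frame
        sampling time of each ROI centroid.
    """

    event_times: list
    event_amplitudes: list
    frame_period: float = DEFAULT_FRAME_PERIOD
    roi_offsets: np.ndarray | None = None

    def __post_init__(self):
        self.event_times = [np.asarray(t, dtype=float) for t in self.event_times]
        self.event_amplitudes = [np.asarray(a, dtype=float) for a in self.event_amplitudes]
        if len(self.event_times) != len(self.event_amplitudes):
            raise ValueError("event_times and event_amplitudes must align per ROI")
        for a in self.event_amplitudes:
            if a.size and a.min() < 0:
                raise ValueError("event amplitudes must be nonnegative")
        if self.roi_offsets is None:
            self.roi_offsets = np.zeros(len(self.event_times))
        self.roi_offsets = np.asarray(self.roi_offsets, dtype=float)
        if np.any((self.roi_offsets < 0) | (self.roi_offsets >= self.frame_period)):
            raise ValueError("roi_offsets must lie in [0, frame_period)")

    @property
    def n_rois(self) -> int:
        return len(self.event_times)


@dataclass
class BinnedPopulation:
    """Event-locked 10 ms-binned population activity.

    data : (n_trials, n_rois, n_bins), amplitude mass per bin
    window_ms : (start, stop) relative to the locking event
    """

    data: np.ndarray
    window_ms: tuple
    lock_event: str
    smoothing_sd_ms: float = 0.0
    truncated_events: int = 0
    bin_ms: float = BIN_MS

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    @property
    def bin_centers_ms(self) -> np.ndarray:
        w0 = self.window_ms[0]
        return w0 + self.bin_ms * (0.5 + np.arange(self.n_bins))

    def smoothed(self, sd_ms: float) -> "BinnedPopulation":
        return BinnedPopulation(
            data=gaussian_smooth(self.data, sd_ms, bin_ms=self.bin_ms),
            window_ms=self.window_ms, lock_event=self.lock_event,
            smoothing_sd_ms=sd_ms, truncated_events=self.truncated_events,
            bin_ms=self.bin_ms,
        )


@dataclass
class ScreenResult:
    """Trial QA outcome: retained flags, per-trial offending-bin counts and
    the per-angle percentile-derived bounds per target side."""

    retained: np.ndarray
    out_of_bounds_bins: np.ndarray
    bounds: dict  # side -> (2, 24) array [low, high]
    max_bad_bins: int = 5

    def to_frame(self, targets: np.ndarray):
        import pandas as pd

        return pd.DataFrame({
            "trial": np.arange(self.retained.size),
            "side": np.asarray(targets),
            "out_of_bounds_bins": self.out_of_bounds_bins,
            "retained": self.retained,
        })


# ---------------------------------------------------------------------------
# binning and smoothing
# ---------------------------------------------------------------------------


def bin_events_fractional(
    activity: PopulationActivity,
    lock_times: np.ndarray,
    window_ms: tuple = (-100.0, 400.0),
    lock_event: str = "event",
    bin_ms: float = BIN_MS,
) -> BinnedPopulation:
    """Resample deconvolved events into event-locked 10 ms bins.

    Each event's amplitude is distributed across the bins its source frame
    (``[t, t + frame_period)``, with ``t`` the ROI's offset-shifted sample
    time) overlaps, proportionally to the overlap.  Total amplitude is
    conserved for events whose frame lies fully inside the window; frames
    straddling a window edge lose the outside mass and are counted in
    ``truncated_events``.
    """
    w0, w1 = float(window_ms[0]), float(window_ms[1])
    if abs(w0 / bin_ms - round(w0 / bin_ms)) > 1e-9 or abs(w1 / bin_ms - round(w1 / bin_ms)) > 1e-9:
        raise ValueError("window bounds must be multiples of the bin width")
    lock_times = np.asarray(lock_times, dtype=float)
    if not np.all(np.isfinite(lock_times)):
        raise ValueError("lock times must be finite")
    n_bins = int(round((w1 - w0) / bin_ms))
    n_tr = lock_times.size
    fp_ms = activity.frame_period * 1000.0
    n_span = int(np.ceil(fp_ms / bin_ms)) + 1

    out = np.zeros((n_tr, activity.n_rois, n_bins))
    truncated = 0
    for r in range(activity.n_rois):
        t_ev = activity.event_times[r] * 1000.0  # ms
        amps = activity.event_amplitudes[r]
        if t_ev.size == 0:
            continue
        for i in range(n_tr):
            rel = t_ev - lock_times[i] * 1000.0 - w0  # frame start, ms from window start
            sel = (rel + fp_ms > 0) & (rel < n_bins * bin_ms)
            if not sel.any():
                continue
            rs, am = rel[sel], amps[sel]
            truncated += int(np.sum((rs < 0) | (rs + fp_ms > n_bins * bin_ms)))
            k0 = np.floor(rs / bin_ms).astype(int)
            for j in range(n_span):
                k = k0 + j
                lo = np.maximum(rs, k * bin_ms)
                hi = np.minimum(rs + fp_ms, (k + 1) * bin_ms)
                frac = np.clip(hi - lo, 0.0, None) / fp_ms
                ok = (k >= 0) & (k < n_bins) & (frac > 0)
                if ok.any():
                    np.add.at(out[i, r], k[ok], am[ok] * frac[ok])
    return BinnedPopulation(
        data=out, window_ms=(w0, w1), lock_event=lock_event,
        truncated_events=truncated, bin_ms=bin_ms,
    )


def bin_kinematics(
    angles: np.ndarray,
    frame_times: np.ndarray,
    lock_times: np.ndarray,
    window_ms: tuple = (-100.0, 400.0),
    smoothing_sd_ms: float = 15.0,
    bin_ms: float = BIN_MS,
) -> np.ndarray:
    """Event-lock kinematic traces onto the common 10 ms grid.

    Each angle is linearly interpolated from its native frame grid at the
    event-locked bin centers, then smoothed within trials (15 ms-s.d.
    Gaussian by default).  Returns (n_trials, n_bins, n_vars).
    """
    a = np.asarray(angles, dtype=float)
    ft = np.asarray(frame_times, dtype=float)
    lock_times = np.asarray(lock_times, dtype=float)
    w0, w1 = window_ms
    centers = (w0 + bin_ms * (0.5 + np.arange(int(round((w1 - w0) / bin_ms))))) / 1000.0
    n_tr, _, n_var = a.shape
    out = np.empty((n_tr, centers.size, n_var))
    for i in range(n_tr):
        tq = lock_times[i] + centers
        for j in range(n_var):
            out[i, :, j] = np.interp(tq, ft, a[i, :, j])
    return gaussian_smooth(out, smoothing_sd_ms, bin_ms=bin_ms, axis=1)


def gaussian_smooth(series: np.ndarray, sd_ms: float, bin_ms: float = BIN_MS,
                    axis: int = -1) -> np.ndarray:
    """Gaussian smoothing on a uniform grid.

    Unit-mass truncated Gaussian (+-4 s.d.) with reflective edge handling;
    ``sd_ms = 0`` is the identity.
    """
    x = np.asarray(series, dtype=float)
    if sd_ms < 0:
        raise ValueError("sd_ms must be nonnegative")
    if sd_ms == 0:
        return x.copy()
    return gaussian_filter1d(x, sigma=sd_ms / bin_ms, axis=axis,
                             mode="reflect", truncate=4.0)


# ---------------------------------------------------------------------------
# event amplitude rescaling
# ---------------------------------------------------------------------------


def rescale_event_amplitudes(
    amplitudes: np.ndarray, min_events: int = 20
) -> tuple[np.ndarray, float, bool]:
    """Normalize one ROI's event sizes so the mode of their distribution is 1.

    An Epanechnikov kernel density estimate on log amplitudes (Silverman
    bandwidth) is transformed back to amplitude space (Jacobian 1/a, as a
    log-support kernel density routine does); the located peak is the
    amplitude-space mode and all amplitudes are divided by it, so the
    density mode of the rescaled sizes is 1.  ROIs with fewer than
    ``min_events`` positive events are returned unscaled and flagged.

    Returns (rescaled, scale, flagged).
    """
    amps = np.asarray(amplitudes, dtype=float)
    pos = amps[amps > 0]
    if pos.size < min_events:
        return amps.copy(), 1.0, True
    la = np.log(pos)
    if la.std() < 1e-12 * max(1.0, abs(la.mean())):  # effectively constant
        scale = float(np.exp(la.mean()))
        return amps / scale, scale, False
    from statsmodels.nonparametric.kde import KDEUnivariate

    kde = KDEUnivariate(la)
    kde.fit(kernel="epa", fft=False, bw="silverman", gridsize=512)
    # The amplitude-space density is g(s)/exp(s) (Jacobian of the log
    # transform); its mode satisfies (log g)'(s) = 1.  A local quadratic
    # fit to log g over the density bulk solves this analytically, which
    # is much more stable than the argmax of the tilted product (that can
    # jump to low-density tails where 1/a blows up).
    s, g = kde.support, kde.density
    bulk = g > 0.5 * g.max()
    s0 = s[bulk].mean()  # center the abscissa for conditioning
    coef = np.polyfit(s[bulk] - s0, np.log(g[bulk]), 2)
    if coef[0] < 0 and bulk.sum() >= 3:
        peak = s0 + (1.0 - coef[1]) / (2.0 * coef[0])
    else:  # degenerate curvature: fall back to the raw density peak
        peak = s[int(np.argmax(g))]
    scale = float(np.exp(peak))
    return amps / scale, scale, False


# ---------------------------------------------------------------------------
# trial screening
# ---------------------------------------------------------------------------


def percentile_bounds(values: np.ndarray, p_lo: float = 2.5, p_hi: float = 97.5):
    """Per-angle QA bounds from the printed rule
    ``(pctile1 + pctile2)/2 +- abs(pctile1 - pctile2)``."""
    p1 = np.percentile(values, p_lo, axis=0)
    p2 = np.percentile(values, p_hi, axis=0)
    mid = (p1 + p2) / 2.0
    half = np.abs(p1 - p2)
    return np.stack([mid - half, mid + half])


def screen_trials(
    angles: np.ndarray,
    targets: np.ndarray,
    max_bad_bins: int = 5,
) -> ScreenResult:
    """Flag trials with problematic tracking from their joint angle traces.

    ``angles`` is the lift-locked (-100..+400 ms, 10 ms, 15 ms-s.d.
    smoothed) trial x bin x 24 tensor.  Per target side, each angle gets
    bounds from the 2.5/97.5 percentiles over all trials and time points;
    a time bin counts as offending if ANY angle is out of bounds, and a
    trial is retained iff it has at most ``max_bad_bins`` offending bins.
    """
    a = np.asarray(angles, dtype=float)
    targets = np.asarray(targets)
    n_tr, n_t, n_ang = a.shape
    counts = np.zeros(n_tr, dtype=int)
    bounds: dict = {}
    for side in np.unique(targets):
        m = targets == side
        if m.sum() < 2:
            warnings.warn(f"fewer than 2 trials for side {side!r}; screening skipped")
            bounds[str(side)] = None
            continue
        flat = a[m].reshape(-1, n_ang)
        b = percentile_bounds(flat)
        bounds[str(side)] = b
        oob = (a[m] < b[0]) | (a[m] > b[1])  # (trials, bins, angles)
        counts[m] = oob.any(axis=2).sum(axis=1)
    return ScreenResult(
        retained=counts <= max_bad_bins,
        out_of_bounds_bins=counts,
        bounds=bounds,
        max_bad_bins=max_bad_bins,
    )


# ---------------------------------------------------------------------------
# trial grouping and PETHs
# ---------------------------------------------------------------------------


def group_trials(events: TrialEvents) -> dict:
    """Median split of movement time within each target side.

    Returns ``{(side, 'brief'|'long'): trial index array}``; trials whose
    movement time equals the side's median go to 'long'.
    """
    groups: dict = {}
    mt = events.movement_time
    for side in (LEFT, RIGHT):
        idx = np.flatnonzero(events.side_mask(side))
        if idx.size == 0:
            continue
        med = np.median(mt[idx])
        groups[(side, "brief")] = idx[mt[idx] < med]
        groups[(side, "long")] = idx[mt[idx] >= med]
    return groups


def group_and_peth(
    binned: BinnedPopulation,
    events: TrialEvents,
    smoothing_sd_ms: float = 35.0,
) -> dict:
    """Grouped peri-event time histograms.

    PETH = within-group mean of the binned activity smoothed with a
    Gaussian (35 ms s.d. default); empty groups are omitted with a
    warning.  Returns ``{(side, speed): (n_rois, n_bins) array}``.
    """
    sm = binned.smoothed(smoothing_sd_ms).data
    peths = {}
    for key, idx in group_trials(events).items():
        if idx.size == 0:
            warnings.warn(f"empty trial group {key}; omitted")
            continue
        peths[key] = sm[idx].mean(axis=0)
    return peths
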