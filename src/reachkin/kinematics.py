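"""Forelimb kinematics: 15 tracked keypoints <-> 24 named joint angles.

The forelimb is represented by 15 keypoints (four digit tips, four PIP
joints, four MCP joints, wrist, elbow, shoulder) tracked in a right-handed
world frame with +Z up, +Y anterior (toward the reach targets) and +X to
the animal's right.  Joint angles are extrinsic Euler angles extracted
proximal-to-distal: each angle is the signed rotation about a fixed world
axis that carries the relevant limb segment from its neutral direction to
its observed direction, and after each angle is measured the segment and
all of its children are counter-rotated to neutralize that joint.  Because
every step is an exact single-axis decomposition, the 24 angles form an
invertible parameterization of the keypoint configuration (given segment
lengths): ``inverse_kinematics(forward_kinematics(theta)) == theta`` for
poses within the gimbal-safe range (|angle| <= 80 degrees).

Neutral directions: humerus along +Z; radius/ulna, the virtual metacarpus
(wrist -> mean of MCP2/MCP3) and all phalanges along +Y; the four
wrist->MCP vectors fan symmetrically in the palm (XY) plane.  All angles
are reported in degrees; computation is in radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# marker and angle bookkeeping
# ---------------------------------------------------------------------------

MARKER_NAMES = [
    "tip1", "tip2", "tip3", "tip4",
    "pip1", "pip2", "pip3", "pip4",
    "mcp1", "mcp2", "mcp3", "mcp4",
    "wrist", "elbow", "shoulder",
]

TIP = [0, 1, 2, 3]
PIP = [4, 5, 6, 7]
MCP = [8, 9, 10, 11]
WRIST, ELBOW, SHOULDER = 12, 13, 14
DIGIT_MARKERS = TIP + PIP + MCP

#: canonical angle order: 7 proximal then 17 distal
ANGLE_NAMES = [
    "shoulder_abd", "shoulder_flex", "shoulder_rot",
    "elbow_flex",
    "wrist_dev", "wrist_flex", "wrist_rot",
    "opposition_MC1", "opposition_MC4",
    "splay_12", "splay_23", "splay_34",
    "MCP_abd_1", "MCP_abd_2", "MCP_abd_3", "MCP_abd_4",
    "MCP_flex_1", "MCP_flex_2", "MCP_flex_3", "MCP_flex_4",
    "PIP_flex_1", "PIP_flex_2", "PIP_flex_3", "PIP_flex_4",
]
N_ANGLES = 24
PROXIMAL_ANGLES = ANGLE_NAMES[:7]
DISTAL_ANGLES = ANGLE_NAMES[7:]

#: gimbal-safe sampling range for round-trip checks, degrees
SAFE_ANGLE_RANGE = 80.0

_X, _Y, _Z = 0, 1, 2
# plane coordinates (u, v) such that a +rotation about the axis takes u -> v
_AXIS_PLANE = {_X: (1, 2), _Y: (2, 0), _Z: (0, 1)}


def _digit(d: int) -> list[int]:
    """Marker indices of digit ``d`` (1-based): tip, PIP, MCP."""
    return [d - 1, 4 + d - 1, 8 + d - 1]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class KeypointSession:
    """3D marker trajectories for one session.

    positions : (n_trials, n_time, 15, 3) float array, mm
    frame_times : (n_time,) seconds, strictly increasing (150 Hz nominal)
    """

    positions: np.ndarray
    frame_times: np.ndarray
    marker_order: list[str] = field(default_factory=lambda: list(MARKER_NAMES))

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.positions.ndim != 4 or self.positions.shape[2:] != (15, 3):
            raise ValueError("positions must have shape (trial, time, 15, 3)")
        if list(self.marker_order) != MARKER_NAMES:
            raise ValueError("marker_order must match the canonical 15-marker list")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.positions.shape[0]


@dataclass
class JointAngleTensor:
    """Per-trial 24-angle time series in degrees, canonical naming."""

    angles: np.ndarray  # (n_trials, n_time, 24)
    frame_times: np.ndarray
    names: list[str] = field(default_factory=lambda: list(ANGLE_NAMES))

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape[-1] != N_ANGLES:
            raise ValueError("expected 24 joint angles")
        if list(self.names) != ANGLE_NAMES:
            raise ValueError("angle names must match the canonical ordering")

    def to_frame(self):
        """Long-format DataFrame (trial, time_s, angle_name, degrees)."""
        import pandas as pd

        n_tr, n_t, _ = self.angles.shape
        trial = np.repeat(np.arange(n_tr), n_t * N_ANGLES)
        time = np.tile(np.repeat(self.frame_times, N_ANGLES), n_tr)
        name = np.tile(np.array(self.names), n_tr * n_t)
        return pd.DataFrame(
            {"trial": trial, "time_s": time, "angle_name": name,
             "degrees": self.angles.reshape(-1)}
        )


@dataclass
class GraspEvents:
    """Per-trial grasp event times (seconds; NaN when undefined)."""

    lift_time: np.ndarray
    collect_time: np.ndarray
    extend_time: np.ndarray
    max_z_velocity_time: np.ndarray
    aperture: np.ndarray  # (n_trials, n_time) mm


# ---------------------------------------------------------------------------
# skeleton template
# ---------------------------------------------------------------------------


@dataclass
class SkeletonTemplate:
    """Neutral posture (all 24 angles zero) and the implied segment lengths.

    The neutral paw is a symmetric fan in the palm plane: the wrist->MCP
    vectors of digits 1..4 sit at azimuths -90, -45, +45, +90 degrees from
    the anterior (+Y) axis by default, which keeps every angle's single-axis
    decomposition well away from its gimbal degeneracy over the +-80 degree
    working range.
    """

    neutral_keypoints: np.ndarray  # (15, 3) mm

    def __post_init__(self):
        self.neutral_keypoints = np.asarray(self.neutral_keypoints, dtype=float)
        if self.neutral_keypoints.shape != (15, 3):
            raise ValueError("neutral_keypoints must be (15, 3)")
        if not np.all(np.isfinite(self.neutral_keypoints)):
            raise ValueError("neutral_keypoints must be finite")
        for a, b in self.links():
            if np.linalg.norm(self.neutral_keypoints[b] - self.neutral_keypoints[a]) <= 0:
                raise ValueError("template segment lengths must be positive")

    @staticmethod
    def links() -> list[tuple[int, int]]:
        """Inter-marker links of the kinematic tree (parent, child)."""
        out = [(SHOULDER, ELBOW), (ELBOW, WRIST)]
        for d in range(1, 5):
            tip, pip, mcp = _digit(d)
            out += [(WRIST, mcp), (mcp, pip), (pip, tip)]
        return out

    def segment_lengths(self) -> dict[tuple[int, int], float]:
        kp = self.neutral_keypoints
        return {(a, b): float(np.linalg.norm(kp[b] - kp[a])) for a, b in self.links()}

    @property
    def root(self) -> np.ndarray:
        return self.neutral_keypoints[SHOULDER]

    @classmethod
    def default(
        cls,
        humerus: float = 12.0,
        radius_ulna: float = 12.0,
        metacarpus: float = 4.5,
        proximal_phalanx: float = 2.5,
        distal_phalanx: float = 2.0,
        mcp_azimuths_deg: tuple[float, float, float, float] = (-90.0, -45.0, 45.0, 90.0),
        root: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "SkeletonTemplate":
        kp = np.zeros((15, 3))
        kp[SHOULDER] = root
        kp[ELBOW] = kp[SHOULDER] + [0.0, 0.0, humerus]
        kp[WRIST] = kp[ELBOW] + [0.0, radius_ulna, 0.0]
        for d, phi in zip(range(1, 5), np.deg2rad(mcp_azimuths_deg)):
            u = np.array([-np.sin(phi), np.cos(phi), 0.0])  # R_z(phi) @ +Y
            tip, pip, mcp = _digit(d)
            kp[mcp] = kp[WRIST] + metacarpus * u
            kp[pip] = kp[mcp] + [0.0, proximal_phalanx, 0.0]
            kp[tip] = kp[pip] + [0.0, distal_phalanx, 0.0]
        return cls(neutral_keypoints=kp)


# ---------------------------------------------------------------------------
# rotation / angle primitives
# ---------------------------------------------------------------------------


def _signed_angle(axis: int, n: np.ndarray, v: np.ndarray, tol: float = 1e-8):
    """Signed angle (rad) about a world axis carrying ``n`` to ``v`` in-plane.

    Returns (theta, degenerate) where ``degenerate`` flags frames whose
    projection of ``v`` onto the rotation plane is shorter than ``tol``
    times the vector norm (gimbal degeneracy).
    """
    u_i, v_i = _AXIS_PLANE[axis]
    nu, nv = n[..., u_i], n[..., v_i]
    vu, vv = v[..., u_i], v[..., v_i]
    cross = nu * vv - nv * vu
    dot = nu * vu + nv * vv
    theta = np.arctan2(cross, dot)
    vnorm = np.linalg.norm(v, axis=-1)
    degenerate = np.hypot(vu, vv) < tol * np.maximum(vnorm, 1e-300)
    return np.where(degenerate, 0.0, theta), degenerate


def _rotate(pts: np.ndarray, idx, axis: int, theta: np.ndarray, pivot: np.ndarray):
    """Rotate markers ``idx`` of ``pts`` (N,15,3) in place about a world axis
    through per-frame ``pivot`` (N,3) by per-frame ``theta`` (N,) radians."""
    u_i, v_i = _AXIS_PLANE[axis]
    c = np.cos(theta)[:, None]
    s = np.sin(theta)[:, None]
    rel = pts[:, idx, :] - pivot[:, None, :]
    ru = c * rel[..., u_i] - s * rel[..., v_i]
    rv = s * rel[..., u_i] + c * rel[..., v_i]
    rel[..., u_i] = ru
    rel[..., v_i] = rv
    pts[:, idx, :] = rel + pivot[:, None, :]


_ALL_BUT_SHOULDER = list(range(14))
_FOREARM_DOWN = list(range(13))
_HAND = list(range(12))


def _template_geometry(template: SkeletonTemplate):
    """Neutral directions and paw-fan parameters used by IK/FK."""
    kp = template.neutral_keypoints
    w = kp[WRIST]
    u = {d: kp[_digit(d)[2]] - w for d in range(1, 5)}
    uhat = {d: u[d] / np.linalg.norm(u[d]) for d in u}
    nmcp = np.cross(u[2], u[3])
    nmcp = nmcp / np.linalg.norm(nmcp)
    # paw-fan azimuths about Z measured from +Y (direction = R_z(phi) @ +Y)
    phi = {d: float(np.arctan2(-uhat[d][0], uhat[d][1])) for d in u}
    ell = {d: float(np.linalg.norm(u[d])) for d in u}
    return {"uhat": uhat, "nmcp": nmcp, "phi": phi, "ell": ell}


def _ik_steps(geom):
    """Sequential single-axis measurement steps in canonical angle order.

    Each entry: (angle index, axis, vector-extractor, neutral direction,
    pivot marker, rotated marker subset).  splay_23 (index 10) is handled
    separately as a symmetric scissor of digits 2 and 3.
    """
    yhat = np.array([0.0, 1.0, 0.0])
    zhat = np.array([0.0, 0.0, 1.0])

    def seg(a, b):
        return lambda p: p[:, b, :] - p[:, a, :]

    def vmc(p):
        return 0.5 * (p[:, MCP[1], :] + p[:, MCP[2], :]) - p[:, WRIST, :]

    def nmcp(p):
        return np.cross(p[:, MCP[1], :] - p[:, WRIST, :],
                        p[:, MCP[2], :] - p[:, WRIST, :])

    steps = [
        (0, _Y, seg(SHOULDER, ELBOW), zhat, SHOULDER, _ALL_BUT_SHOULDER),
        (1, _X, seg(SHOULDER, ELBOW), zhat, SHOULDER, _ALL_BUT_SHOULDER),
        (2, _Z, seg(ELBOW, WRIST), yhat, ELBOW, _FOREARM_DOWN),
        (3, _X, seg(ELBOW, WRIST), yhat, ELBOW, _FOREARM_DOWN),
        (4, _X, vmc, yhat, WRIST, _HAND),
        (5, _Z, vmc, yhat, WRIST, _HAND),
        (6, _Y, nmcp, geom["nmcp"], WRIST, _HAND),
        (7, _Y, seg(WRIST, MCP[0]), geom["uhat"][1], WRIST, _digit(1)),
        (8, _Y, seg(WRIST, MCP[3]), geom["uhat"][4], WRIST, _digit(4)),
        (9, _Z, seg(WRIST, MCP[0]), geom["uhat"][1], WRIST, _digit(1)),
        # index 10 = splay_23 scissor, special-cased
        (11, _Z, seg(WRIST, MCP[3]), geom["uhat"][4], WRIST, _digit(4)),
    ]
    for d in range(1, 5):
        tip, pip, mcp = _digit(d)
        steps.append((12 + d - 1, _X, seg(mcp, pip), yhat, mcp, [tip, pip]))
    for d in range(1, 5):
        tip, pip, mcp = _digit(d)
        steps.append((16 + d - 1, _Z, seg(mcp, pip), yhat, mcp, [tip, pip]))
    for d in range(1, 5):
        tip, pip, mcp = _digit(d)
        steps.append((20 + d - 1, _X, seg(pip, tip), yhat, pip, [tip]))
    return steps


def _scissor_offsets(gamma: np.ndarray, geom):
    """Azimuth offsets (a2, a3) of digits 2/3 realizing a splay_23 opening
    change ``gamma`` while keeping the virtual metacarpus along +Y."""
    phi2, phi3 = geom["phi"][2], geom["phi"][3]
    l2, l3 = geom["ell"][2], geom["ell"][3]
    A = l2 * np.sin(phi2) + l3 * np.sin(phi3 + gamma)
    B = l2 * np.cos(phi2) + l3 * np.cos(phi3 + gamma)
    a2 = np.arctan2(-A, B)
    return a2, gamma + a2


class DegenerateSegmentError(ValueError):
    """A limb segment has (near-)zero length; angles are undefined."""


def _check_frames(pts: np.ndarray):
    if not np.all(np.isfinite(pts)):
        raise ValueError("keypoints contain non-finite values")
    for a, b in [(SHOULDER, ELBOW), (ELBOW, WRIST)]:
        if np.any(np.linalg.norm(pts[:, b] - pts[:, a], axis=-1) <= 1e-12):
            raise DegenerateSegmentError(f"zero-length segment {MARKER_NAMES[a]}->{MARKER_NAMES[b]}")
    vmc = 0.5 * (pts[:, MCP[1]] + pts[:, MCP[2]]) - pts[:, WRIST]
    if np.any(np.linalg.norm(vmc, axis=-1) <= 1e-12):
        raise DegenerateSegmentError("zero-length virtual metacarpus")


# ---------------------------------------------------------------------------
# inverse / forward kinematics
# ---------------------------------------------------------------------------


def inverse_kinematics(
    keypoints: np.ndarray,
    template: SkeletonTemplate | None = None,
    return_flags: bool = False,
):
    """Extract the 24 extrinsic Euler joint angles (degrees) from keypoints.

    Parameters
    ----------
    keypoints : (..., 15, 3) array
        One frame or a batch of frames, in mm.
    template : SkeletonTemplate, optional
        Supplies the neutral directions; defaults to
        ``SkeletonTemplate.default()``.
    return_flags : bool
        Also return a (..., 24) boolean array flagging gimbal-degenerate
        measurements (those angles are reported as 0 at frame level; the
        trial-level wrapper forward-fills them).

    Returns
    -------
    angles : (..., 24) array, degrees, in the canonical ``ANGLE_NAMES`` order.
    """
    if template is None:
        template = SkeletonTemplate.default()
    geom = _template_geometry(template)
    kp = np.asarray(keypoints, dtype=float)
    lead = kp.shape[:-2]
    pts = kp.reshape(-1, 15, 3).copy()
    _check_frames(pts)
    n = pts.shape[0]
    angles = np.zeros((n, N_ANGLES))
    flags = np.zeros((n, N_ANGLES), dtype=bool)

    steps = _ik_steps(geom)
    for ai, axis, vec, neutral, pivot, subset in steps:
        if ai == 11:
            # scissor comes between splay_12 (9) and splay_34 (11)
            _measure_scissor(pts, geom, angles, flags)
        theta, deg = _signed_angle(axis, neutral, vec(pts))
        angles[:, ai] = theta
        flags[:, ai] = deg
        _rotate(pts, subset, axis, -theta, pts[:, pivot, :].copy())

    angles = np.rad2deg(angles).reshape(*lead, N_ANGLES)
    flags = flags.reshape(*lead, N_ANGLES)
    if return_flags:
        return angles, flags
    return angles


def _measure_scissor(pts, geom, angles, flags):
    """Measure and neutralize splay_23 (angle index 10)."""
    w = pts[:, WRIST, :].copy()
    g2, d2 = _signed_angle(_Z, geom["uhat"][2], pts[:, MCP[1], :] - w)
    g3, d3 = _signed_angle(_Z, geom["uhat"][3], pts[:, MCP[2], :] - w)
    angles[:, 10] = g3 - g2
    flags[:, 10] = d2 | d3
    _rotate(pts, _digit(2), _Z, -g2, w)
    _rotate(pts, _digit(3), _Z, -g3, w)


def forward_kinematics(
    angles: np.ndarray, template: SkeletonTemplate | None = None
) -> np.ndarray:
    """Reconstruct 15 keypoints (mm) from 24 joint angles (degrees).

    Applies the documented single-axis rotations distal-to-proximal to the
    template's neutral posture, preserving all inter-marker link lengths
    exactly.  Inverse of :func:`inverse_kinematics` on its output.
    """
    if template is None:
        template = SkeletonTemplate.default()
    geom = _template_geometry(template)
    ang = np.asarray(angles, dtype=float)
    if ang.shape[-1] != N_ANGLES:
        raise ValueError("expected 24 angles")
    if not np.all(np.isfinite(ang)):
        raise ValueError("angles must be finite")
    lead = ang.shape[:-1]
    th = np.deg2rad(ang.reshape(-1, N_ANGLES))
    n = th.shape[0]
    pts = np.broadcast_to(template.neutral_keypoints, (n, 15, 3)).copy()

    steps = _ik_steps(geom)
    for ai, axis, _vec, _neutral, pivot, subset in reversed(steps):
        _rotate(pts, subset, axis, th[:, ai], pts[:, pivot, :].copy())
        if ai == 11:
            # apply the splay_23 scissor after splay_34, before splay_12
            w = pts[:, WRIST, :].copy()
            a2, a3 = _scissor_offsets(th[:, 10], geom)
            _rotate(pts, _digit(2), _Z, a2, w)
            _rotate(pts, _digit(3), _Z, a3, w)

    return pts.reshape(*lead, 15, 3)


def inverse_kinematics_trials(
    session: KeypointSession, template: SkeletonTemplate | None = None
) -> tuple[JointAngleTensor, np.ndarray]:
    """Per-trial IK with gimbal forward-fill and temporal unwrapping.

    Flagged (gimbal-degenerate) angle samples inherit the previous frame's
    value (0 at t=0); each angle is then unwrapped in time within each
    trial with a 180-degree jump threshold so traces are continuous.
    """
    n_tr, n_t = session.positions.shape[:2]
    ang, flags = inverse_kinematics(
        session.positions, template=template, return_flags=True
    )
    for tr in range(n_tr):
        for j in range(N_ANGLES):
            f = flags[tr, :, j]
            if f.any():
                vals = ang[tr, :, j]
                for t in np.flatnonzero(f):
                    vals[t] = vals[t - 1] if t > 0 else 0.0
    ang = np.unwrap(ang, axis=1, period=360.0)
    return JointAngleTensor(angles=ang, frame_times=session.frame_times), flags


# ---------------------------------------------------------------------------
# paw geometry and grasp events
# ---------------------------------------------------------------------------


def paw_aperture(keypoints: np.ndarray) -> np.ndarray:
    """Paw aperture (mm): mean distance of the four digit tips from the
    centroid of the 12 digit markers.

    Captures both digit splay and MCP/PIP flexion, and is invariant to
    rigid transforms of the keypoints.  Frames with non-finite digit
    markers yield NaN.
    """
    kp = np.asarray(keypoints, dtype=float)
    digits = kp[..., DIGIT_MARKERS, :]
    centroid = digits.mean(axis=-2, keepdims=True)
    tips = kp[..., TIP, :]
    d = np.linalg.norm(tips - centroid, axis=-1)
    ap = d.mean(axis=-1)
    bad = ~np.isfinite(digits).all(axis=(-1, -2))
    return np.where(bad, np.nan, ap)


def paw_centroid(keypoints: np.ndarray) -> np.ndarray:
    """Centroid of the 12 digit markers, (..., 3)."""
    kp = np.asarray(keypoints, dtype=float)
    return kp[..., DIGIT_MARKERS, :].mean(axis=-2)


def digit_centroid(keypoints: np.ndarray) -> np.ndarray:
    """Centroid of the four digit tips, (..., 3)."""
    kp = np.asarray(keypoints, dtype=float)
    return kp[..., TIP, :].mean(axis=-2)


def detect_grasp_events(
    aperture: np.ndarray,
    times: np.ndarray,
    lift_time: np.ndarray | float,
    paw_z_velocity: np.ndarray,
) -> GraspEvents:
    """Detect collect/extend grasp events from the aperture trace.

    collect = first strict local minimum of the aperture after the lift;
    extend = first subsequent strict local maximum; also returns the time
    of maximum paw-centroid Z velocity after lift.  Undefined events are
    NaN (the trial is flagged, never fabricated).
    """
    ap = np.atleast_2d(np.asarray(aperture, dtype=float))
    zv = np.atleast_2d(np.asarray(paw_z_velocity, dtype=float))
    times = np.asarray(times, dtype=float)
    lifts = np.broadcast_to(np.asarray(lift_time, dtype=float), (ap.shape[0],))
    n_tr, n_t = ap.shape

    collect = np.full(n_tr, np.nan)
    extend = np.full(n_tr, np.nan)
    maxzv = np.full(n_tr, np.nan)
    for i in range(n_tr):
        post = times > lifts[i]
        if post.any():
            j0 = int(np.argmax(post))
            k = j0 + int(np.argmax(zv[i, j0:]))
            maxzv[i] = times[k]
        interior = np.arange(1, n_t - 1)
        a = ap[i]
        mins = interior[(a[interior] < a[interior - 1]) & (a[interior] < a[interior + 1])]
        mins = mins[times[mins] > lifts[i]]
        if mins.size == 0:
            continue
        c = mins[0]
        collect[i] = times[c]
        maxs = interior[(a[interior] > a[interior - 1]) & (a[interior] > a[interior + 1])]
        maxs = maxs[maxs > c]
        if maxs.size:
            extend[i] = times[maxs[0]]
    return GraspEvents(
        lift_time=np.asarray(lifts, dtype=float).copy(),
        collect_time=collect,
        extend_time=extend,
        max_z_velocity_time=maxzv,
        aperture=ap,
    )


# ---------------------------------------------------------------------------
# correlations and velocities
# ---------------------------------------------------------------------------


def joint_correlations(
    angles: np.ndarray, contact_mask: np.ndarray | None = None
):
    """24x24 Pearson correlation matrix of joint angles.

    Frames where ``contact_mask`` is True (paw touching the spout) are
    excluded before concatenating trials.  Angles that are constant over
    the retained frames yield NaN rows/columns, returned in ``flags``.
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim == 3:
        a = a.reshape(-1, a.shape[-1])
        if contact_mask is not None:
            contact_mask = np.asarray(contact_mask, dtype=bool).reshape(-1)
    if contact_mask is not None:
        a = a[~contact_mask]
    if a.shape[0] < 2:
        raise ValueError("need at least 2 retained time points")
    sd = a.std(axis=0)
    flags = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(a, rowvar=False)
    corr[flags, :] = np.nan
    corr[:, flags] = np.nan
    np.fill_diagonal(corr, np.where(flags, np.nan, 1.0))
    return corr, flags


def joint_velocities(angles: np.ndarray, dt: float) -> np.ndarray:
    """Joint angular velocities (deg/s): central differences on a uniform
    grid, one-sided at the endpoints.  Time is the second-to-last axis for
    trial tensors, the first axis for 2D (time, angle) input."""
    a = np.asarray(angles, dtype=float)
    axis = a.ndim - 2 if a.ndim >= 2 else 0
    return np.gradient(a, dt, axis=axis)
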