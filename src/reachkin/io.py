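"""HDF5 / CSV / JSON persistence for sessions and results.

One session lives in a single HDF5 file:

``/keypoints``            (trial, time, 15, 3) float64, mm
``/frame_times``          (time,) s, trial-relative
``/marker_names``         the canonical 15-marker order
``/events/*``             cue/lift/contact times (s, trial-relative), target
``/populations/<name>/*`` concatenated event times/amplitudes with a per-event
                          ROI index, per-ROI sampling offsets, frame period
``/ground_truth/*``       planted parameters when the session is synthetic

The file root carries ``schema_version`` and the generating configuration
as JSON, so a run can be reproduced from the session file alone.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .kinematics import MARKER_NAMES, JointAngleTensor, KeypointSession
from .preprocess import PopulationActivity, TrialEvents
from .synthetic import (
    GroundTruth,
    PopulationConfig,
    SyntheticConfig,
    SyntheticSession,
    SkeletonTemplate,
)

SCHEMA_VERSION = 1


class SchemaVersionError(RuntimeError):
    """Session file written by an incompatible schema."""


def _config_to_json(config: SyntheticConfig) -> str:
    d = dataclasses.asdict(config)
    d["mt_range_s"] = list(d["mt_range_s"])
    return json.dumps(d, sort_keys=True)


def _config_from_json(text: str) -> SyntheticConfig:
    d = json.loads(text)
    d["populations"] = {k: PopulationConfig(**v)
                        for k, v in d["populations"].items()}
    d["mt_range_s"] = tuple(d["mt_range_s"])
    return SyntheticConfig(**d)


def write_session(path, session: SyntheticSession) -> None:
    """Write a complete session bundle to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["trial_length_s"] = session.config.trial_length_s
        f.attrs["config_json"] = _config_to_json(session.config)
        f.create_dataset("keypoints", data=session.keypoints.positions)
        f.create_dataset("frame_times", data=session.keypoints.frame_times)
        f.create_dataset("marker_names",
                         data=np.array(MARKER_NAMES, dtype="S"))
        f.create_dataset("template", data=session.template.neutral_keypoints)
        ev = f.create_group("events")
        ev.create_dataset("cue_time", data=session.events.cue_time)
        ev.create_dataset("lift_time", data=session.events.lift_time)
        ev.create_dataset("contact_time", data=session.events.contact_time)
        ev.create_dataset("target",
                          data=np.asarray(session.events.target, dtype="S"))
        pops = f.create_group("populations")
        for name, act in session.populations.items():
            g = pops.create_group(name)
            times = np.concatenate(act.event_times) if act.n_rois else np.empty(0)
            amps = np.concatenate(act.event_amplitudes) if act.n_rois else np.empty(0)
            roi = np.repeat(np.arange(act.n_rois),
                            [t.size for t in act.event_times])
            g.create_dataset("event_times", data=times)
            g.create_dataset("event_amplitudes", data=amps)
            g.create_dataset("event_roi", data=roi)
            g.create_dataset("roi_offsets", data=act.roi_offsets)
            g.attrs["frame_period"] = act.frame_period
            g.attrs["n_rois"] = act.n_rois
        _write_ground_truth(f, session.ground_truth)


def _write_ground_truth(f: h5py.File, gt: GroundTruth) -> None:
    g = f.create_group("ground_truth")
    g.attrs["latent_rank"] = gt.latent_rank
    g.attrs["seed"] = gt.seed
    g.create_dataset("angles", data=gt.angles.angles)
    g.create_dataset("latents", data=gt.latents)
    g.create_dataset("loadings", data=gt.loadings)
    g.create_dataset("reaction_times", data=gt.reaction_times)
    g.create_dataset("collect_times", data=gt.collect_times)
    g.create_dataset("extend_times", data=gt.extend_times)
    g.create_dataset("glitch_trials", data=np.asarray(gt.glitch_trials, dtype=int))
    pops = g.create_group("populations")
    for name, plant in gt.populations.items():
        pg = pops.create_group(name)
        for k, v in plant.items():
            arr = np.asarray(v)
            if arr.dtype.kind in "US":
                pg.attrs[k] = str(v)
            elif arr.ndim == 0:
                pg.attrs[k] = arr.item()
            else:
                pg.create_dataset(k, data=arr)


def read_session(path) -> SyntheticSession:
    """Read a session bundle written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"session schema {version} != supported {SCHEMA_VERSION}")
        config = _config_from_json(f.attrs["config_json"])
        keypoints = KeypointSession(
            positions=f["keypoints"][()], frame_times=f["frame_times"][()])
        events = TrialEvents(
            cue_time=f["events/cue_time"][()],
            lift_time=f["events/lift_time"][()],
            contact_time=f["events/contact_time"][()],
            target=f["events/target"][()].astype(str),
        )
        template = SkeletonTemplate(neutral_keypoints=f["template"][()])
        populations = {}
        for name, g in f["populations"].items():
            n = int(g.attrs["n_rois"])
            roi = g["event_roi"][()]
            times = g["event_times"][()]
            amps = g["event_amplitudes"][()]
            populations[name] = PopulationActivity(
                event_times=[times[roi == r] for r in range(n)],
                event_amplitudes=[amps[roi == r] for r in range(n)],
                frame_period=float(g.attrs["frame_period"]),
                roi_offsets=g["roi_offsets"][()],
            )
        gt = _read_ground_truth(f, keypoints.frame_times)
    return SyntheticSession(keypoints=keypoints, events=events,
                            populations=populations, ground_truth=gt,
                            config=config, template=template)


def _read_ground_truth(f: h5py.File, frame_times: np.ndarray) -> GroundTruth:
    g = f["ground_truth"]
    planted = {}
    for name, pg in g["populations"].items():
        d = {k: pg.attrs[k] for k in pg.attrs}
        d.update({k: pg[k][()] for k in pg})
        planted[name] = d
    return GroundTruth(
        angles=JointAngleTensor(angles=g["angles"][()], frame_times=frame_times),
        latents=g["latents"][()], loadings=g["loadings"][()],
        latent_rank=int(g.attrs["latent_rank"]),
        reaction_times=g["reaction_times"][()],
        collect_times=g["collect_times"][()],
        extend_times=g["extend_times"][()],
        glitch_trials=g["glitch_trials"][()],
        populations=planted, seed=int(g.attrs["seed"]),
    )


def write_ground_truth_json(path, gt: GroundTruth) -> None:
    """Scalar/planted-parameter summary of the ground truth as JSON."""
    out = {
        "latent_rank": gt.latent_rank, "seed": gt.seed,
        "n_trials": int(gt.reaction_times.size),
        "glitch_trials": np.asarray(gt.glitch_trials, dtype=int).tolist(),
        "reaction_times_s": gt.reaction_times.tolist(),
        "populations": {
            name: {"target_latency_ms": float(p["target_latency_ms"]),
                   "n_modulated": int(np.sum(p["modulated"])),
                   "baseline_rate": float(p["baseline_rate"])}
            for name, p in gt.populations.items()},
    }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)


def write_angles_csv(path, tensor: JointAngleTensor) -> None:
    """Long-format CSV export (trial, time_s, angle_name, degrees)."""
    tensor.to_frame().to_csv(path, index=False)


def write_report(path, report: dict) -> None:
    """Machine-readable pipeline report; deterministic byte layout."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
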