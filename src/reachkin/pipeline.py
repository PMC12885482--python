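"""End-to-end analysis pipeline: simulate/load -> IK -> QA -> events ->
dimensionality -> modulation -> decoding -> report.

Stages communicate through files in an output directory so any stage can
be re-run from cached upstream artifacts; re-running a single stage
reproduces the end-to-end result for that stage.  The report is a single
JSON document containing every summary statistic and the seeds that
produced them (no timestamps, so identical configurations yield
byte-identical reports).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio
from .decoding import (
    RidgeConfig,
    classify_target,
    decode_joint_timeseries,
    decode_reaction_time,
    select_rois,
    time_generalized_accuracy,
)
from .dimensionality import cv_pca_dimensionality
from .kinematics import (
    ANGLE_NAMES,
    detect_grasp_events,
    inverse_kinematics_trials,
    joint_correlations,
    joint_velocities,
    paw_aperture,
    paw_centroid,
)
from .modulation import ZETA_WINDOWS, screen_modulated, zeta_ts_pvalue
from .preprocess import (
    LEFT,
    RIGHT,
    bin_events_fractional,
    bin_kinematics,
    gaussian_smooth,
    screen_trials,
)
from .synthetic import SyntheticConfig, generate_session

logger = logging.getLogger("reachkin")

STAGES = ("simulate", "ik", "screen", "events", "cvpca", "zeta",
          "decode-joints", "decode-target", "decode-rt", "report")

ZETA_EVENTS = ("cue", "lift", "contact")
SIDES = (LEFT, RIGHT)


class PipelineValidationError(ValueError):
    """Invalid configuration, detected before execution."""


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the analysis conventions
    (10 ms bins, 15/35 ms smoothing, 100 shuffles, 50 decoding folds)."""

    outdir: str = "reachkin_out"
    session_path: str | None = None  # load instead of simulating
    simulate: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    # trial QA
    screen_window_ms: tuple = (-100.0, 400.0)
    screen_smoothing_sd_ms: float = 15.0
    max_bad_bins: int = 5
    # modulation testing
    zeta_n_shuffles: int = 100
    alpha: float = 0.05
    # dimensionality
    cvpca_candidates: tuple | None = None  # default 1..23
    cvpca_partitions: int = 5
    # joint decoding
    ridge: RidgeConfig = field(default_factory=RidgeConfig)
    n_top_rois: int = 100
    # target / RT decoding
    target_window_ms: tuple = (-100.0, 500.0)
    generalization_window_ms: tuple = (-100.0, 1000.0)
    rt_window_ms: tuple = (-200.0, 600.0)
    target_p_threshold: float = 0.01

    def validate(self) -> None:
        if self.ridge.n_folds < 2:
            raise PipelineValidationError("ridge.n_folds must be >= 2")
        if self.zeta_n_shuffles < 2:
            raise PipelineValidationError("zeta_n_shuffles must be >= 2")
        if not self.simulate and self.session_path is None:
            raise PipelineValidationError(
                "session_path required when simulate is false")
        for w in (self.screen_window_ms, self.target_window_ms,
                  self.generalization_window_ms, self.rt_window_ms):
            if w[1] <= w[0]:
                raise PipelineValidationError(f"empty window {w}")


def _stage_paths(outdir: Path) -> dict:
    return {
        "session": outdir / "session.h5",
        "ground_truth": outdir / "ground_truth.json",
        "angles": outdir / "angles.npz",
        "angles_csv": outdir / "angles.csv",
        "screen": outdir / "screening.csv",
        "events": outdir / "grasp_events.csv",
        "cvpca": outdir / "cvpca.json",
        "zeta": outdir / "zeta.csv",
        "decode_joints": outdir / "decode_joints.json",
        "decode_target": outdir / "decode_target.json",
        "decode_rt": outdir / "decode_rt.json",
        "report": outdir / "report.json",
    }


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages in dependency order.

    ``stages=None`` runs everything.  Each stage persists its artifact
    under ``config.outdir`` and later stages reload from disk, so a
    single stage can be re-run against cached upstream outputs.  Returns
    the report dict (assembled from whatever artifacts exist when the
    'report' stage runs).
    """
    config.validate()
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineValidationError(f"unknown stages {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = _stage_paths(outdir)
    runner = _Runner(config, paths)
    report = None
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        result = runner.run(stage)
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
        if stage == "report":
            report = result
    return report if report is not None else runner.partial_report()


class _Runner:
    def __init__(self, config: PipelineConfig, paths: dict):
        self.config = config
        self.paths = paths
        self._session = None

    # -- artifact access ---------------------------------------------------

    def _require(self, key: str, stage: str):
        if not Path(self.paths[key]).exists():
            raise DependencyError(
                f"stage '{stage}' requires missing artifact {self.paths[key]}")

    @property
    def session(self):
        if self._session is None:
            path = self.paths["session"]
            if self.config.session_path is not None:
                path = self.config.session_path
            if not Path(path).exists():
                raise DependencyError(f"no session file at {path}; "
                                      "run the simulate stage or set session_path")
            self._session = rio.read_session(path)
        return self._session

    def _angles_10ms(self):
        """Lift-locked 10 ms, 15 ms-smoothed angles from the IK artifact."""
        self._require("angles", "downstream")
        z = np.load(self.paths["angles"])
        ses = self.session
        return bin_kinematics(z["angles"], z["frame_times"],
                              ses.events.lift_time, self.config.screen_window_ms,
                              self.config.screen_smoothing_sd_ms)

    def _retained(self):
        import pandas as pd

        self._require("screen", "downstream")
        df = pd.read_csv(self.paths["screen"])
        return df["retained"].to_numpy(dtype=bool)

    # -- stages ------------------------------------------------------------

    def run(self, stage: str):
        return getattr(self, "stage_" + stage.replace("-", "_"))()

    def stage_simulate(self):
        if not self.config.simulate:
            return None
        cfg = dataclasses.replace(self.config.synthetic, seed=self.config.seed)
        session = generate_session(cfg)
        rio.write_session(self.paths["session"], session)
        rio.write_ground_truth_json(self.paths["ground_truth"],
                                    session.ground_truth)
        self._session = session
        return session

    def stage_ik(self):
        ses = self.session
        tensor, flags = inverse_kinematics_trials(ses.keypoints, ses.template)
        np.savez(self.paths["angles"], angles=tensor.angles,
                 frame_times=tensor.frame_times,
                 flags=flags.astype(np.uint8))
        rio.write_angles_csv(self.paths["angles_csv"], tensor)
        return tensor

    def stage_screen(self):
        ses = self.session
        locked = self._angles_10ms()
        res = screen_trials(locked, ses.events.target, self.config.max_bad_bins)
        res.to_frame(ses.events.target).to_csv(self.paths["screen"], index=False)
        return res

    def stage_events(self):
        import pandas as pd

        ses = self.session
        kp = ses.keypoints.positions
        t = ses.keypoints.frame_times
        dt = float(t[1] - t[0])
        ap = gaussian_smooth(paw_aperture(kp), 15.0, bin_ms=1000 * dt, axis=1)
        zv = gaussian_smooth(np.gradient(paw_centroid(kp)[..., 2], dt, axis=1),
                             15.0, bin_ms=1000 * dt, axis=1)
        ge = detect_grasp_events(ap, t, ses.events.lift_time, zv)
        pd.DataFrame({
            "trial": np.arange(ses.events.n_trials),
            "lift_time": ge.lift_time, "collect_time": ge.collect_time,
            "extend_time": ge.extend_time,
            "max_z_velocity_time": ge.max_z_velocity_time,
        }).to_csv(self.paths["events"], index=False)
        return ge

    def stage_cvpca(self):
        ses = self.session
        locked = self._angles_10ms()
        retained = self._retained()
        # exclude contact frames: window bins after first contact
        w0 = self.config.screen_window_ms[0]
        centers = w0 + 10.0 * (0.5 + np.arange(locked.shape[1]))
        contact = ((ses.events.contact_time - ses.events.lift_time)[:, None]
                   <= centers[None, :] / 1000.0)
        keep = retained[:, None] & ~contact
        obs = locked[keep]
        corr, corr_flags = joint_correlations(obs)
        out = {}
        for kind, data in (("angles", obs),
                           ("velocities", joint_velocities(locked, 0.01)[keep])):
            res = cv_pca_dimensionality(
                data, candidates=self.config.cvpca_candidates,
                n_partitions=self.config.cvpca_partitions,
                rng=self.config.seed)
            out[kind] = res.report()
        out["n_observations"] = int(obs.shape[0])
        out["correlation_flags"] = corr_flags.astype(int).tolist()
        with open(self.paths["cvpca"], "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
        np.save(Path(self.paths["cvpca"]).with_suffix(".corr.npy"), corr)
        return out

    def stage_zeta(self):
        import pandas as pd

        ses = self.session
        retained = self._retained()
        rows = []
        for pop_name, act in sorted(ses.populations.items()):
            for event in ZETA_EVENTS:
                window = ZETA_WINDOWS[event]
                binned = bin_events_fractional(
                    act, ses.lock_times(event), window, event)
                for side in SIDES:
                    m = ses.events.side_mask(side) & retained
                    data = binned.data[m]
                    for r in range(act.n_rois):
                        res = zeta_ts_pvalue(
                            data[:, r, :], self.config.zeta_n_shuffles,
                            rng=_zeta_seed(self.config.seed, pop_name, event,
                                           side, r),
                            window_ms=window, lock_event=event)
                        rows.append({
                            "population": pop_name, "roi": r, "event": event,
                            "target": side, "statistic": res.data_max_deviation,
                            "p": res.p_value, "log10p": res.log10_p,
                            "n_shuffles": res.n_shuffles,
                            "seed": self.config.seed,
                        })
        df = pd.DataFrame(rows)
        df.to_csv(self.paths["zeta"], index=False)
        return df

    def _zeta_table(self):
        import pandas as pd

        self._require("zeta", "decoding")
        return pd.read_csv(self.paths["zeta"])

    def _pmatrix(self, df, pop_name):
        """(n_rois, 6) p-values for one population, event x side order."""
        sub = df[df.population == pop_name]
        n = int(sub.roi.max()) + 1
        p = np.ones((n, len(ZETA_EVENTS) * len(SIDES)))
        for j, (ev, side) in enumerate(
                (e, s) for e in ZETA_EVENTS for s in SIDES):
            m = (sub.event == ev) & (sub.target == side)
            p[sub.roi[m].to_numpy(), j] = sub.p[m].to_numpy()
        return p

    def stage_decode_joints(self):
        ses = self.session
        retained = self._retained()
        locked = self._angles_10ms()[retained]
        df = self._zeta_table()
        out = {}
        for pop_name, act in sorted(ses.populations.items()):
            pmat = self._pmatrix(df, pop_name)
            sel = select_rois(pmat, "top", self.config.n_top_rois)
            binned = bin_events_fractional(
                act, ses.lock_times("lift"), self.config.screen_window_ms,
                "lift")
            neural = np.transpose(binned.data[retained][:, sel, :], (0, 2, 1))
            cfg = dataclasses.replace(self.config.ridge, seed=self.config.seed)
            res = decode_joint_timeseries(neural, locked, cfg)
            out[pop_name] = {
                "median_ve": dict(zip(ANGLE_NAMES,
                                      np.round(res.median_ve, 6).tolist())),
                "n_rois": int(sel.size),
                "n_folds": int(res.variance_explained.shape[1]),
            }
        with open(self.paths["decode_joints"], "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
        return out

    def stage_decode_target(self):
        ses = self.session
        retained = self._retained()
        df = self._zeta_table()
        out = {}
        for pop_name, act in sorted(ses.populations.items()):
            pmat = self._pmatrix(df, pop_name)
            sel = select_rois(pmat, "threshold",
                              p_threshold=self.config.target_p_threshold)
            entry = {"n_rois": int(sel.size)}
            binned = bin_events_fractional(
                act, ses.lock_times("cue"), self.config.target_window_ms, "cue")
            neural = np.transpose(binned.data[retained][:, sel, :], (0, 2, 1))
            targets = np.asarray(ses.events.target)[retained]
            cres = classify_target(neural, targets, binned.bin_centers_ms,
                                   (0.0, None), seed=self.config.seed)
            entry["accuracy_median"] = float(cres.overall_accuracy)
            entry["accuracy_per_bin"] = np.round(cres.accuracy_per_bin, 6).tolist()
            entry["median_crossing_s"] = _nanfloat(
                np.nanmedian(cres.crossing_times))
            gb = bin_events_fractional(
                act, ses.lock_times("cue"),
                self.config.generalization_window_ms, "cue")
            gneural = np.transpose(gb.data[retained][:, sel, :], (0, 2, 1))
            gmat = time_generalized_accuracy(gneural, targets,
                                             gb.bin_centers_ms,
                                             seed=self.config.seed)
            entry["generalization_shape"] = list(gmat.shape)
            entry["generalization_mean"] = float(gmat.mean())
            np.save(Path(self.paths["decode_target"]).with_suffix(
                f".{pop_name}.generalization.npy"), gmat)
            out[pop_name] = entry
        if {"A", "B"} <= set(out):
            a, b = out["A"]["median_crossing_s"], out["B"]["median_crossing_s"]
            out["latency_difference_s"] = (
                None if a is None or b is None else b - a)
        with open(self.paths["decode_target"], "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
        return out

    def stage_decode_rt(self):
        ses = self.session
        retained = self._retained()
        out = {}
        for pop_name, act in sorted(ses.populations.items()):
            binned = bin_events_fractional(
                act, ses.lock_times("lift"), self.config.rt_window_ms, "lift")
            neural = np.transpose(binned.data[retained], (0, 2, 1))
            try:
                _pred, offsets, r = decode_reaction_time(
                    neural, ses.events.reaction_time[retained],
                    np.asarray(ses.events.target)[retained],
                    binned.bin_centers_ms, seed=self.config.seed)
                out[pop_name] = {
                    "r": float(r),
                    "n_defined": int(np.isfinite(offsets).sum()),
                }
            except ValueError as exc:
                out[pop_name] = {"r": None, "error": str(exc)}
        with open(self.paths["decode_rt"], "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
        return out

    def stage_report(self):
        report = self.partial_report()
        rio.write_report(self.paths["report"], report)
        return report

    def partial_report(self) -> dict:
        import pandas as pd

        report = {"seed": self.config.seed, "schema_version": rio.SCHEMA_VERSION}
        if Path(self.paths["screen"]).exists():
            df = pd.read_csv(self.paths["screen"])
            report["screening"] = {
                "n_trials": int(len(df)),
                "n_retained": int(df.retained.sum()),
            }
        if Path(self.paths["cvpca"]).exists():
            with open(self.paths["cvpca"]) as fh:
                cv = json.load(fh)
            report["dimensionality"] = {
                k: cv[k]["optimal_dimensionality"]
                for k in ("angles", "velocities") if k in cv}
        if Path(self.paths["zeta"]).exists():
            df = pd.read_csv(self.paths["zeta"])
            zsum = {}
            for pop_name, sub in df.groupby("population"):
                flags = []
                for roi, rsub in sub.groupby("roi"):
                    pv = {(row.event, row.target): row.p
                          for row in rsub.itertuples()}
                    flags.append(screen_modulated(
                        pv, self.config.alpha)["overall_modulated"])
                zsum[pop_name] = {
                    "n_rois": int(len(flags)),
                    "frac_modulated": float(np.mean(flags)),
                }
            report["zeta"] = zsum
        for key, name in (("decode_joints", "ve"), ("decode_target", "target"),
                          ("decode_rt", "rt")):
            if Path(self.paths[key]).exists():
                with open(self.paths[key]) as fh:
                    report[name] = json.load(fh)
        return report


def _zeta_seed(seed: int, pop: str, event: str, side: str, roi: int) -> int:
    """Stable (process-independent) per-test shuffle seed below 2**31."""
    import zlib

    h = zlib.crc32(f"{pop}|{event}|{side}".encode()) % 9973
    return (seed * 1_000_003 + h * 7919 + roi) % (2**31 - 1)


def _nanfloat(x) -> float | None:
    x = float(x)
    return None if np.isnan(x) else x
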