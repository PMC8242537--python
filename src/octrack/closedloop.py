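"""Closed-loop depth-targeting simulation.

Reproduces, in silico, the bench experiments a handheld OCT-guided injector
is validated with:

* stationary sensor — no motion, no motor: the tracking noise floor;
* fixed motor — stationary sample, active depth targeting: control noise and
  convergence to the setpoint;
* free hand — the fiber follows a tremor trajectory (slow drift of hundreds
  of micrometers plus ~10 Hz tremor of tens of micrometers) while the motor
  compensates; boundary SD before vs. after activation quantifies efficacy.

The motor is modeled as an ideal position actuator with a per-cycle step
clamp (its velocity limit, 12.5 mm/s by default) and an optional integer
control-cycle latency.  One control unit u moves the measured boundary by
one pixel, so the plant obeys x_k = x_{k-1} + u_{k-1-delay} + hand motion.
Before activation the control output is computed but not applied.

Each cycle renders one fresh raw A-scan (standing in for an averaged block
of eight), crops it with a fixed window located once at run start, segments
it (trained network or ground-truth oracle), measures the targeted and
untargeted boundary positions, measures velocity by cross-correlating
consecutive cropped scans, and fuses both with the Kalman tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .phantom import (
    AScan,
    LabelMask,
    MScan,
    PhantomSpec,
    TremorTrajectory,
    BOUNDARY_NAMES,
    boundaries_from_thicknesses,
    render_averaged_ascan,
    sample_thicknesses,
)
from .preprocess import CROP_LENGTH
from .tracking import (
    ControlLaw,
    KalmanModel,
    KalmanState,
    control_step,
    kalman_step,
    measure_boundary,
    measure_velocity,
)
from .unet1d import SegmentationModel, predict_masks

__all__ = [
    "RigConfig",
    "RunResult",
    "run_stationary",
    "run_fixed_motor",
    "run_freehand",
    "align_mscan",
    "ORACLE",
]

#: sentinel selecting the ground-truth-mask segmenter
ORACLE = "oracle"

#: boundaries the tracker follows: retinal surface and the injection target
TRACKED_BOUNDARIES = (0, 5)  # VH/GCL, PR/CH


@dataclass
class RigConfig:
    """Actuation and loop-timing parameters of the simulated rig."""

    motor_vmax_mm_s: float = 12.5
    dt_s: float = 0.003
    loop_delay_cycles: int = 0
    target_boundary: int = 5  # PR/CH
    target_depth_um: float = 1000.0
    control_gain: float = 0.5
    #: A-scans averaged per control cycle before segmentation (the block
    #: averaging the acquisition chain performs)
    n_average: int = 8
    kalman: KalmanModel | None = None

    def __post_init__(self) -> None:
        if self.motor_vmax_mm_s <= 0 or self.dt_s <= 0:
            raise ValueError("motor_vmax_mm_s and dt_s must be positive")
        if self.loop_delay_cycles < 0:
            raise ValueError("loop_delay_cycles must be >= 0")
        if self.target_boundary not in TRACKED_BOUNDARIES:
            raise ValueError(
                f"target_boundary must be one of {TRACKED_BOUNDARIES} "
                f"({BOUNDARY_NAMES[TRACKED_BOUNDARIES[0]]}, "
                f"{BOUNDARY_NAMES[TRACKED_BOUNDARIES[1]]})"
            )

    def u_max_px(self, pixel_size_um: float) -> float:
        """Largest motor step per control cycle, in pixels."""
        return self.motor_vmax_mm_s * 1000.0 * self.dt_s / pixel_size_um


@dataclass
class RunResult:
    """Everything one closed-loop run produces."""

    mscan: MScan
    #: per tracked boundary: dict with z_pos, x_est, v_est, true_px arrays
    traces: dict
    controls: np.ndarray  # u computed per cycle (px)
    applied: np.ndarray  # u actually applied to the plant per cycle (px)
    active: np.ndarray  # bool per cycle: compensation applied
    crop_start: int
    pixel_size_um: float
    metrics: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.mscan.trajectory.t if self.mscan.trajectory is not None else None

    def raw_trace(self, boundary: int) -> np.ndarray:
        """Tracked boundary positions in raw (uncropped) row coordinates,
        ready for :func:`align_mscan`."""
        return self.traces[boundary]["x_est"] + self.crop_start


def _segment(segmenter, cropped: np.ndarray, true_labels: np.ndarray) -> np.ndarray:
    if segmenter == ORACLE:
        return true_labels
    if isinstance(segmenter, SegmentationModel):
        if not getattr(segmenter, "trained", False):
            raise ValueError("segmentation model has not been trained")
        return predict_masks(segmenter, cropped[None, :])[0]
    raise TypeError("segmenter must be ORACLE or a trained SegmentationModel")


def _thickness_series(
    spec: PhantomSpec, n: int, rng: np.random.Generator, drift: bool
) -> np.ndarray:
    """Per-cycle layer thicknesses (n, 6).

    With ``drift`` on, thicknesses wander smoothly around the per-run base
    values (low-pass-filtered white noise at the spec jitter SD), emulating
    the lateral component of hand tremor sweeping the beam across a retina
    of non-uniform thickness.  Off: constant base thicknesses.
    """
    base = sample_thicknesses(spec, rng)
    if not drift or spec.thickness_jitter_um == 0:
        return np.tile(base, (n, 1))
    noise = rng.normal(0.0, 1.0, size=(n, base.size))
    smooth = gaussian_filter1d(noise, sigma=30.0, axis=0, mode="nearest")
    sd = smooth.std(axis=0)
    sd[sd == 0] = 1.0
    smooth = smooth / sd * spec.thickness_jitter_um
    return np.maximum(base + smooth, 1.0)


def _simulate(
    spec: PhantomSpec,
    rig: RigConfig,
    hand_um: np.ndarray,
    active: np.ndarray,
    segmenter,
    seed: int,
    thickness_drift: bool = False,
) -> RunResult:
    """Shared closed-loop engine for all three experiment designs."""
    spec.validate()
    n = len(hand_um)
    px = spec.pixel_size_um
    u_max = rig.u_max_px(px)
    kmodel = rig.kalman or KalmanModel(dt=rig.dt_s)
    if abs(kmodel.dt - rig.dt_s) > 1e-12:
        kmodel = KalmanModel(rig.dt_s, kmodel.sigma_a, kmodel.r_pos, kmodel.r_vel)

    ss = np.random.SeedSequence(seed)
    rng0 = np.random.default_rng(ss)
    thick = _thickness_series(spec, max(n, 1), rng0, thickness_drift)
    col_rngs = [np.random.default_rng(s) for s in ss.spawn(n)]

    # fixed crop window, located once from the initial surface position
    b0 = boundaries_from_thicknesses(spec, thick[0], hand_um[0] if n else 0.0)
    crop_start = int(round(b0[0])) - 40
    crop_start = min(max(crop_start, 0), spec.raw_length_px - CROP_LENGTH)
    x_target = rig.target_depth_um / px - crop_start
    law = ControlLaw(rig.control_gain, x_target, u_max)

    intensity = np.empty((spec.raw_length_px, n))
    labels = np.empty((spec.raw_length_px, n), dtype=np.int64)
    true_bounds = np.empty((len(BOUNDARY_NAMES), n))
    traces = {
        b: {k: np.full(n, np.nan) for k in ("z_pos", "z_vel", "x_est", "v_est", "true_px", "p_trace")}
        for b in TRACKED_BOUNDARIES
    }
    controls = np.zeros(n)
    applied = np.zeros(n)

    states: dict[int, KalmanState | None] = {b: None for b in TRACKED_BOUNDARIES}
    prev_crop: np.ndarray | None = None
    u_hist = np.zeros(n + rig.loop_delay_cycles + 1)  # computed controls, by cycle
    motor_px = 0.0

    for k in range(n):
        # control computed delay cycles ago is applied to the plant now
        j = k - 1 - rig.loop_delay_cycles
        u_app = u_hist[j] if (j >= 0 and active[j]) else 0.0
        if abs(u_app) > u_max + 1e-9:
            raise AssertionError("motor step exceeded its velocity limit")
        motor_px += u_app
        applied[k] = u_app

        shift_um = hand_um[k] + motor_px * px
        bounds = boundaries_from_thicknesses(spec, thick[k], shift_um)
        try:
            ascan, mask = render_averaged_ascan(spec, bounds, col_rngs[k], rig.n_average)
        except ValueError as e:
            raise ValueError(f"cycle {k}: {e}") from e
        intensity[:, k] = ascan.intensity
        labels[:, k] = mask.labels
        true_bounds[:, k] = bounds

        cropped = ascan.intensity[crop_start : crop_start + CROP_LENGTH]
        true_crop_labels = mask.labels[crop_start : crop_start + CROP_LENGTH]
        seg = _segment(segmenter, cropped, true_crop_labels)
        seg_mask = LabelMask(seg)

        if prev_crop is None:
            z_vel, _ = 0.0, True
        else:
            z_vel, _ = measure_velocity(cropped, prev_crop, u_app, rig.dt_s)
        prev_crop = cropped

        for b in TRACKED_BOUNDARIES:
            z_pos = measure_boundary(seg_mask, b, b + 1)
            tr = traces[b]
            tr["z_pos"][k] = z_pos
            tr["z_vel"][k] = z_vel
            tr["true_px"][k] = bounds[b] - crop_start
            st = states[b]
            if st is None:
                if np.isfinite(z_pos):
                    st = KalmanState(z_pos, 0.0, np.diag([kmodel.r_pos, kmodel.r_vel]))
                    states[b] = st
            else:
                st = kalman_step(st, kmodel, (z_pos, z_vel), u_app)
                states[b] = st
            if st is not None:
                tr["x_est"][k] = st.x
                tr["v_est"][k] = st.v
                tr["p_trace"][k] = np.trace(st.P)

        est = traces[rig.target_boundary]["x_est"][k]
        controls[k] = control_step(law, est) if np.isfinite(est) else 0.0
        u_hist[k] = controls[k]

    t = np.arange(n) * rig.dt_s
    traj = TremorTrajectory(t, hand_um, {}, seed)
    mscan = MScan(intensity, labels, true_bounds, px, traj)
    result = RunResult(mscan, traces, controls, applied, active.copy(), crop_start, px)
    result.metrics = _metrics(result, rig)
    return result


def _metrics(result: RunResult, rig: RigConfig) -> dict:
    """Per-boundary targeting statistics over the compensation-active segment
    (or the whole run if compensation was never active)."""
    px = result.pixel_size_um
    seg = result.active if result.active.any() else np.ones_like(result.active)
    x_target = rig.target_depth_um / px - result.crop_start
    out = {}
    for b, tr in result.traces.items():
        est = tr["x_est"][seg.astype(bool)]
        est = est[np.isfinite(est)]
        truth = tr["true_px"][seg.astype(bool)]
        name = BOUNDARY_NAMES[b]
        out[name] = {
            "sd_um": float(est.std() * px) if est.size else float("nan"),
            "sd_true_um": float(truth.std() * px),
            "n": int(est.size),
        }
        if b == rig.target_boundary:
            out[name]["targeting_mse_px"] = (
                float((est - x_target).mean()) if est.size else float("nan")
            )
            out[name]["targeting_mse_um"] = out[name]["targeting_mse_px"] * px
            # steady-state statistics excluding the initial approach: from the
            # first active cycle with the estimate within 2 px of the setpoint
            full = tr["x_est"].copy()
            full[~seg.astype(bool)] = np.nan
            near = np.flatnonzero(np.abs(full - x_target) <= 2.0)
            if near.size:
                settled = full[near[0]:]
                settled = settled[np.isfinite(settled)]
                out[name]["sd_settled_um"] = float(settled.std() * px)
                out[name]["mse_settled_px"] = float((settled - x_target).mean())
    return out


def run_stationary(
    spec: PhantomSpec,
    duration_s: float = 1.0,
    seed: int = 0,
    segmenter=ORACLE,
    rig: RigConfig | None = None,
) -> RunResult:
    """Stationary sensor, no motor: per-boundary SD of tracked positions is
    the tracking noise floor."""
    rig = rig or RigConfig()
    n = int(round(duration_s / rig.dt_s))
    hand = np.zeros(n)
    active = np.zeros(n, dtype=bool)  # control computed, never applied
    return _simulate(spec, rig, hand, active, segmenter, seed)


def run_fixed_motor(
    spec: PhantomSpec,
    rig: RigConfig | None = None,
    duration_s: float = 1.0,
    seed: int = 0,
    segmenter=ORACLE,
) -> RunResult:
    """Stationary sample, motor active for depth targeting from cycle 0."""
    rig = rig or RigConfig()
    n = int(round(duration_s / rig.dt_s))
    hand = np.zeros(n)
    active = np.ones(n, dtype=bool)
    return _simulate(spec, rig, hand, active, segmenter, seed)


def run_freehand(
    spec: PhantomSpec,
    rig: RigConfig | None = None,
    trajectory: TremorTrajectory | None = None,
    duration_s: float | None = None,
    seed: int = 0,
    compensation_on_at: float = 0.0,
    segmenter=ORACLE,
    thickness_drift: bool = False,
) -> RunResult:
    """Free-hand run: the fiber follows ``trajectory`` while the motor
    compensates from ``compensation_on_at`` seconds onward.

    Metrics cover the active segment; ``pre_sd_um`` per boundary covers the
    segment before activation (if any).
    """
    rig = rig or RigConfig()
    if trajectory is None:
        raise ValueError("a tremor trajectory is required")
    n = len(trajectory)
    if duration_s is not None:
        n = min(n, int(round(duration_s / rig.dt_s)))
    t_end = n * rig.dt_s
    if not (0.0 <= compensation_on_at <= t_end):
        raise ValueError(
            f"compensation_on_at={compensation_on_at}s outside run [0, {t_end:.3f}]s"
        )
    k_on = int(round(compensation_on_at / rig.dt_s))
    active = np.arange(n) >= k_on
    result = _simulate(
        spec, rig, trajectory.z_um[:n], active, segmenter, seed, thickness_drift
    )
    if k_on > 0:
        px = result.pixel_size_um
        for b, tr in result.traces.items():
            pre = tr["x_est"][:k_on]
            pre = pre[np.isfinite(pre)]
            result.metrics[BOUNDARY_NAMES[b]]["pre_sd_um"] = (
                float(pre.std() * px) if pre.size else float("nan")
            )
    return result


def align_mscan(mscan: MScan, trace_px: np.ndarray) -> tuple[MScan, np.ndarray]:
    """Roll each column so the tracked boundary sits on a constant row (the
    rounded mean of the valid trace).  Invalid (non-finite) trace entries are
    flagged and their columns left unrolled.

    Returns ``(aligned, flags)`` where ``flags[j]`` is True for columns that
    could not be aligned.
    """
    trace_px = np.asarray(trace_px, dtype=np.float64)
    if trace_px.shape[0] != mscan.n_columns:
        raise ValueError("trace length must equal the number of columns")
    valid = np.isfinite(trace_px)
    if not valid.any():
        raise ValueError("trace has no valid entries")
    row0 = int(round(trace_px[valid].mean()))
    intensity = mscan.intensity.copy()
    labels = mscan.labels.copy()
    bounds = mscan.boundaries_px.copy()
    flags = ~valid
    for j in range(mscan.n_columns):
        if flags[j]:
            continue
        shift = row0 - int(round(trace_px[j]))
        if shift == 0:
            continue
        intensity[:, j] = _roll_edge(intensity[:, j], shift)
        labels[:, j] = _roll_edge(labels[:, j], shift)
        bounds[:, j] = bounds[:, j] + shift
    return MScan(intensity, labels, bounds, mscan.pixel_size_um, mscan.trajectory), flags


def _roll_edge(col: np.ndarray, s: int) -> np.ndarray:
    out = np.roll(col, s)
    if s > 0:
        out[:s] = col[0]
    elif s < 0:
        out[s:] = col[-1]
    return out


def save_runresult(result: RunResult, outdir) -> dict:
    """Serialize a run: NPZ bundle, per-cycle tracker log CSV, metrics CSV,
    and raw / boundary-aligned M-scan TIFF renders.  Returns written paths."""
    import pandas as pd
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    npz = outdir / "run.npz"
    np.savez_compressed(
        npz,
        intensity=result.mscan.intensity.astype(np.float32),
        labels=result.mscan.labels.astype(np.uint8),
        boundaries_px=result.mscan.boundaries_px,
        controls=result.controls,
        applied=result.applied,
        active=result.active,
        crop_start=result.crop_start,
        pixel_size_um=result.pixel_size_um,
        hand_um=result.mscan.trajectory.z_um,
        t=result.mscan.trajectory.t,
    )
    paths["npz"] = npz

    rows = {"t_s": result.t, "u_px": result.controls, "u_applied_px": result.applied,
            "active": result.active.astype(int)}
    for b, tr in result.traces.items():
        tag = BOUNDARY_NAMES[b].replace("/", "_")
        for key in ("z_pos", "z_vel", "x_est", "v_est", "true_px", "p_trace"):
            rows[f"{tag}_{key}"] = tr[key]
    log = outdir / "tracker_log.csv"
    pd.DataFrame(rows).to_csv(log, index=False)
    paths["log"] = log

    met = outdir / "metrics.csv"
    pd.DataFrame(result.metrics).T.to_csv(met)
    paths["metrics"] = met

    raw_tif = outdir / "mscan_raw.tif"
    tifffile.imwrite(raw_tif, result.mscan.intensity.astype(np.float32))
    paths["mscan_raw"] = raw_tif
    trace = result.raw_trace(5)
    if np.isfinite(trace).any():
        aligned, _ = align_mscan(result.mscan, np.where(np.isfinite(trace), trace, np.nan))
        ali_tif = outdir / "mscan_aligned.tif"
        tifffile.imwrite(ali_tif, aligned.intensity.astype(np.float32))
        paths["mscan_aligned"] = ali_tif
    return paths
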