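"""Simulate → detect → evaluate pipeline with config, logging and file I/O.

The pipeline runs the whole chain on disk artifacts: PNG stripe frames in,
ASCII PLY cloud / CSV centerlines / CSV separation lines out, metrics JSON
at the end.  All tunables live in a YAML config whose defaults are the
study conditions (gamma 8, conveyor 20 mm/s at 30 fps, 60 frames).
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import imageio.v3 as iio

from . import segmentation, centerline, detection, metrics
from .phantom import PhantomSpec, default_camera, make_phantom_surface, render_stripe_frames
from .reconstruction import CameraModel, profile_from_centerline, merge_profiles, write_ply

__all__ = ["PipelineConfig", "run_simulate", "run_detect", "run_evaluate"]

log = logging.getLogger("citruslines")


@dataclass
class PipelineConfig:
    calibration: str | None = None
    gamma: float = 8.0
    gamma_c: float = 1.0
    min_area_frac: float = 0.05
    subpixel: bool = True
    subpixel_half_width: int = 6
    tau: float = 0.8
    undistort: bool = False
    phantom: dict = field(default_factory=dict)
    lspia: dict = field(default_factory=lambda: {
        "n_controls": 8, "tol": 1e-8, "max_iter": 500, "trim_frac": 0.3})
    detection: dict = field(default_factory=lambda: {
        "window": 9, "n_samples": 400, "gate": 3.0, "min_support": 5,
        "min_run": 5, "max_range": 10.0, "z_floor": 0.5, "bin_width": None})
    icp: dict = field(default_factory=lambda: {
        "enabled": False, "max_iter": 50, "tol": 1e-6})
    eval_gate: float = 5.0
    pixel_bound: float = 4.0
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        base = PipelineConfig.__dataclass_fields__
        for name in ("lspia", "detection", "icp"):
            defaults = base[name].default_factory()
            merged = {**defaults, **(getattr(self, name) or {})}
            unknown = set(merged) - set(defaults)
            if unknown:
                raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
            setattr(self, name, merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.calibration is not None and not Path(cfg.calibration).exists():
            raise FileNotFoundError(f"calibration file not found: {cfg.calibration}")
        return cfg

    def camera(self) -> CameraModel:
        if self.calibration is not None:
            return CameraModel.from_yaml(self.calibration)
        spec = self.phantom_spec()
        return default_camera(spec.image_width, spec.image_height)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(**{**self.phantom, "seed": self.phantom.get("seed", self.seed)})


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Render the phantom frame sequence and write frames + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.phantom_spec()
    cam = config.camera()
    field_, truth = make_phantom_surface(spec, cam)
    seq = render_stripe_frames(field_, cam, spec)
    truth.true_centerlines = seq.true_rows

    for i, frame in enumerate(seq.frames):
        iio.imwrite(out / f"frame_{i:04d}.png", frame)

    rows = []
    for i in range(len(seq.frames)):
        for col in range(spec.image_width):
            rows.append((i, col, seq.true_rows[i, col]))
    pd.DataFrame(rows, columns=["frame", "col", "row"]).to_csv(
        out / "truth_centerlines.csv", index=False)

    lines = []
    for lid, line in enumerate(truth.true_lines):
        for x, y, z in line:
            lines.append((lid, x, y, z))
    pd.DataFrame(lines, columns=["line_id", "x", "y", "z"]).to_csv(
        out / "truth_lines.csv", index=False)

    spec.to_yaml(out / "phantom_spec.yaml")
    cam.to_yaml(out / "calibration.yaml")
    log.info("simulated %d frames to %s", len(seq.frames), out)
    return out


def _extract_frame_centerline(frame: np.ndarray, config: PipelineConfig):
    mask = segmentation.segment_stripe(frame, gamma=config.gamma,
                                       c=config.gamma_c,
                                       min_area_frac=config.min_area_frac)
    skel = centerline.thin(mask)
    path = centerline.prune_to_main_branch(skel)
    if config.subpixel:
        v = segmentation.extract_v_channel(frame)
        path = centerline.subpixel_refine(path, v,
                                          half_width=config.subpixel_half_width)
    return path


def run_detect(frames_dir: str | Path, config: PipelineConfig,
               out_dir: str | Path) -> Path:
    """Frames → masks → centerlines → 3D profiles → merged cloud → lines."""
    frames_dir = Path(frames_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cam = config.camera()
    frame_files = sorted(frames_dir.glob("frame_*.png"))
    if len(frame_files) < 2:
        raise FileNotFoundError(f"need at least 2 frames in {frames_dir}")

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    profiles = []
    center_rows = []
    failed = 0
    for f in frame_files:
        idx = int(f.stem.split("_")[1])
        frame = iio.imread(f)
        try:
            path = _extract_frame_centerline(frame, config)
        except ValueError as exc:
            failed += 1
            warnings.warn(f"frame {f.name} failed segmentation: {exc}")
            continue
        profiles.append(profile_from_centerline(path, idx, cam,
                                                undistort=config.undistort))
        for j, (r, c) in enumerate(path.points):
            center_rows.append((idx, j, r, c))
    if failed > 0.1 * len(frame_files):
        raise RuntimeError(f"{failed}/{len(frame_files)} frames failed segmentation")
    timings["centerline"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cloud = merge_profiles(profiles, cam, use_icp=config.icp["enabled"],
                           icp_max_iter=config.icp["max_iter"],
                           icp_tol=config.icp["tol"])
    timings["reconstruction"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    det = config.detection
    bin_width = det["bin_width"] or cam.conveyor_step
    lines = detection.detect_lines(
        cloud, tau=config.tau, bin_width=bin_width,
        n_controls=config.lspia["n_controls"],
        trim_frac=config.lspia["trim_frac"],
        n_samples=det["n_samples"], window=det["window"],
        max_range=det["max_range"], gate=det["gate"],
        min_support=det["min_support"], min_run=det["min_run"],
        z_floor=det["z_floor"])
    timings["detection"] = time.perf_counter() - t0

    write_ply(cloud, out / "cloud.ply")
    pd.DataFrame(center_rows, columns=["frame", "index", "row", "col"]).to_csv(
        out / "centerlines.csv", index=False)
    recs = []
    for line in lines:
        for (x, y, z), d in zip(line.points, line.deviations):
            recs.append((line.line_id, y, x, z, d))
    pd.DataFrame(recs, columns=["line_id", "y", "x", "z", "deviation"]).to_csv(
        out / "lines.csv", index=False)

    run_log = {"config": asdict(config), "n_frames": len(frame_files),
               "n_failed_frames": failed, "n_lines": len(lines),
               "timings_s": timings}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    log.info("detected %d lines from %d frames", len(lines), len(frame_files))
    return out


def _load_lines_csv(path: Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for lid, grp in df.groupby("line_id"):
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
        out[int(lid)] = pts[np.argsort(pts[:, 1], kind="stable")]
    return out


def run_evaluate(pred_dir: str | Path, truth_dir: str | Path,
                 config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Score predicted separation lines against the ground truth lines.

    Each truth line is matched to the closest predicted line (mean matched
    point distance, truth clipped to the prediction's y span); per-line MAE,
    RMSE, similarity and the fraction of points within ``pixel_bound``
    image-plane pixels are reported, with table-style aggregate means.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    cam = config.camera()
    preds = _load_lines_csv(pred_dir / "lines.csv") if (pred_dir / "lines.csv").exists() else {}
    truths = _load_lines_csv(truth_dir / "truth_lines.csv")
    if not truths:
        raise FileNotFoundError("no truth lines found")

    report = {"lines": [], "missed_truth": [], "unmatched_pred": []}
    used_pred: set[int] = set()
    for tid, truth in truths.items():
        best = None
        for pid, pred in preds.items():
            if pid in used_pred:
                continue
            clipped = metrics.clip_polyline_to_y_range(
                truth, pred[:, 1].min(), pred[:, 1].max())
            if clipped is None:
                continue
            mae, rmse, errors = metrics.point_errors(pred, clipped)
            if best is None or mae < best[1]:
                best = (pid, mae, rmse, errors, pred, clipped)
        if best is None or best[1] > config.eval_gate:
            report["missed_truth"].append(int(tid))
            continue
        pid, mae, rmse, errors, pred, clipped = best
        used_pred.add(pid)
        if clipped[-1, 1] < clipped[0, 1]:
            clipped = clipped[::-1]  # predictions are y-ascending
        k = len(errors)
        sim = metrics.similarity(
            metrics.resample_polyline(clipped[:, :2], k),
            metrics.resample_polyline(pred[:, :2], k))
        # per-point accuracy: distance from each detected point to the truth
        # polyline, expressed in image-plane pixels
        near = metrics.nearest_point_distances(pred, truth)
        frac = metrics.fraction_within(near / cam.lateral_scale,
                                       config.pixel_bound)
        report["lines"].append({
            "truth_id": int(tid), "pred_id": int(pid),
            "mae_mm": mae, "rmse_mm": rmse, "similarity": sim,
            f"fraction_within_{config.pixel_bound:g}px": frac,
            "errors_mm": [float(e) for e in errors]})
    report["unmatched_pred"] = sorted(set(preds) - used_pred)

    if report["lines"]:
        report["aggregate"] = {
            "mae_mm": metrics.table_averages([l["mae_mm"] for l in report["lines"]]),
            "rmse_mm": metrics.table_averages([l["rmse_mm"] for l in report["lines"]]),
            "similarity": metrics.table_averages([l["similarity"] for l in report["lines"]]),
            f"fraction_within_{config.pixel_bound:g}px": metrics.table_averages(
                [l[f"fraction_within_{config.pixel_bound:g}px"] for l in report["lines"]]),
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(report, indent=1))
        err_rows = [(l["truth_id"], i, e) for l in report["lines"]
                    for i, e in enumerate(l["errors_mm"])]
        pd.DataFrame(err_rows, columns=["truth_id", "index", "error_mm"]).to_csv(
            out / "errors.csv", index=False)
    return report
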