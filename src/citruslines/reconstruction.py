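"""Laser-triangulation 3D reconstruction of stripe centerlines.

A line laser projected at a fixed triangulation angle ``theta`` to the camera
optical axis shifts in the image plane when the surface height changes.  With
image distance ``M1`` (lens focal distance), object distance ``M2`` (reference
plane to lens) and sensor-plane stripe shift ``n`` the surface height is

    h = M2 * n / (n + M1 * tan(theta))

Per-frame centerlines become 3D profiles (x from the column position, y from
conveyor kinematics, z from triangulation), consecutive profiles are
optionally refined with point-to-point ICP initialized from the conveyor
prior, and everything is merged into one surface point cloud.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

__all__ = [
    "CameraModel",
    "Profile3D",
    "RigidTransform",
    "PointCloud",
    "triangulate_height",
    "height_to_shift",
    "distort_point",
    "undistort_point",
    "profile_from_centerline",
    "icp_align",
    "merge_profiles",
    "write_ply",
    "read_ply",
]


@dataclass
class CameraModel:
    """Geometric and optical constants of the acquisition system.

    Distances are mm, angles radians, image coordinates pixels with 0-based
    (row, col) indexing and row 0 at the top.  ``reference_row`` is the image
    row of the stripe on the flat reference plane (h = 0); ``lateral_scale``
    converts image columns to lateral mm on the reference plane and
    ``pixel_pitch`` converts pixel shifts to sensor-plane mm.
    """

    M1: float = 25.0
    M2: float = 150.0
    theta: float = math.atan(0.3)
    fx: float = 5000.0
    fy: float = 5000.0
    cx: float = 320.0
    cy: float = 240.0
    skew: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    pixel_pitch: float = 0.005
    lateral_scale: float = 0.15
    reference_row: float = 420.0
    conveyor_speed: float = 20.0
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if min(self.M1, self.M2, self.pixel_pitch, self.lateral_scale) <= 0:
            raise ValueError("M1, M2, pixel_pitch and lateral_scale must be positive")
        if not (0.0 < self.theta < math.pi / 2):
            raise ValueError("theta must lie in (0, pi/2)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def conveyor_step(self) -> float:
        """Conveyor displacement between consecutive frames, mm."""
        return self.conveyor_speed / self.frame_rate

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CameraModel":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"calibration file {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


@dataclass
class Profile3D:
    """Ordered 3D points reconstructed from one frame's centerline."""

    points: np.ndarray  # (N, 3) mm
    frame_index: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")

    @property
    def has_negative_heights(self) -> bool:
        """True when noise pushed some reconstructed z below the reference plane."""
        return bool(np.any(self.points[:, 2] < 0))


@dataclass
class RigidTransform:
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # 3-vector mm
    rms: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        R = self.rotation
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            rms=self.rms,
        )


@dataclass
class PointCloud:
    points: np.ndarray  # (N, 3) mm
    frame_index: np.ndarray = field(default=None)  # per-point provenance

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.frame_index is None:
            self.frame_index = np.zeros(len(self.points), dtype=int)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if len(self.frame_index) != len(self.points):
            raise ValueError("frame_index length mismatch")


# ---------------------------------------------------------------------------
# Triangulation
# ---------------------------------------------------------------------------

def triangulate_height(n_shift, cam: CameraModel):
    """Height h (mm) from sensor-plane stripe shift n (mm): h = M2·n/(n + M1·tanθ)."""
    n = np.asarray(n_shift, dtype=float)
    k = cam.M1 * math.tan(cam.theta)
    denom = n + k
    if np.any(denom <= 0):
        raise ValueError("non-positive triangulation denominator (n + M1·tanθ ≤ 0)")
    h = cam.M2 * n / denom
    return float(h) if np.isscalar(n_shift) else h


def height_to_shift(h, cam: CameraModel):
    """Inverse of :func:`triangulate_height`: n = h·M1·tanθ/(M2 − h)."""
    h = np.asarray(h, dtype=float)
    if np.any(h >= cam.M2):
        raise ValueError("height exceeds object distance")
    n = h * cam.M1 * math.tan(cam.theta) / (cam.M2 - h)
    return float(n) if n.ndim == 0 else n


# ---------------------------------------------------------------------------
# Lens distortion
# ---------------------------------------------------------------------------

def _normalize(p: np.ndarray, cam: CameraModel) -> np.ndarray:
    x = (p[..., 0] - cam.cx) / cam.fx
    y = (p[..., 1] - cam.cy) / cam.fy
    return np.stack([x, y], axis=-1)


def _denormalize(q: np.ndarray, cam: CameraModel) -> np.ndarray:
    return np.stack([q[..., 0] * cam.fx + cam.cx, q[..., 1] * cam.fy + cam.cy], axis=-1)


def _distort_normalized(q: np.ndarray, cam: CameraModel) -> np.ndarray:
    x, y = q[..., 0], q[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + cam.k1 * r2 + cam.k2 * r2**2 + cam.k3 * r2**3
    xd = x * radial + 2 * cam.p1 * x * y + cam.p2 * (r2 + 2 * x * x)
    yd = y * radial + cam.p1 * (r2 + 2 * y * y) + 2 * cam.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def distort_point(p, cam: CameraModel) -> np.ndarray:
    """Forward radial+tangential distortion of ideal pixel coordinates (x, y)."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    return np.squeeze(_denormalize(_distort_normalized(_normalize(p, cam), cam), cam))


def undistort_point(p, cam: CameraModel, max_iter: int = 10, tol: float = 1e-8) -> np.ndarray:
    """Invert the distortion model by fixed-point iteration (pixel coords (x, y))."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    qd = _normalize(p, cam)
    q = qd.copy()
    for _ in range(max_iter):
        delta = _distort_normalized(q, cam) - q
        q_new = qd - delta
        err = np.max(np.abs(_denormalize(q_new, cam) - _denormalize(q, cam)))
        q = q_new
        if err < tol:
            break
    else:
        if err >= tol:
            warnings.warn("undistort_point did not converge; returning last iterate")
    return np.squeeze(_denormalize(q, cam))


# ---------------------------------------------------------------------------
# Centerline -> 3D profile
# ---------------------------------------------------------------------------

def profile_from_centerline(path, frame_index: int, cam: CameraModel,
                            undistort: bool = False) -> Profile3D:
    """Convert an image centerline to a 3D profile.

    ``path`` is a CenterlinePath or an (N, 2) array of (row, col).  Per point:
    optional undistortion, pixel shift = reference_row − row, z from Eq.-style
    triangulation, x = (col − cx)·lateral_scale, y = frame_index·speed/rate.
    Slightly negative shifts (noise below the reference plane) are passed
    through; the resulting profile flags them via ``has_negative_heights``.
    """
    pts = np.asarray(getattr(path, "points", path), dtype=float)
    if pts.size == 0:
        raise ValueError("empty centerline")
    rows, cols = pts[:, 0].copy(), pts[:, 1].copy()
    if undistort:
        und = np.atleast_2d(undistort_point(np.stack([cols, rows], axis=1), cam))
        cols, rows = und[:, 0], und[:, 1]
    shift_px = cam.reference_row - rows
    n = shift_px * cam.pixel_pitch
    z = triangulate_height(n, cam)
    x = (cols - cam.cx) * cam.lateral_scale
    y = np.full_like(x, frame_index * cam.conveyor_step)
    return Profile3D(np.stack([x, y, z], axis=1), frame_index=frame_index)


# ---------------------------------------------------------------------------
# ICP registration
# ---------------------------------------------------------------------------

def _best_rigid(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform src -> dst (Kabsch/SVD)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S = np.diag([1.0, 1.0, d])
    R = Vt.T @ S @ U.T
    t = cd - R @ cs
    return RigidTransform(R, t)


def _coarse_align(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Centroid + principal-axes initial alignment.

    Matches the sorted covariance eigenvectors of the two clouds, choosing
    axis signs that keep the rotation as small as possible (the intended
    regime is a modest perturbation, not an arbitrary pose).
    """
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    _, Us = np.linalg.eigh(np.cov((src - cs).T))
    _, Ud = np.linalg.eigh(np.cov((dst - cd).T))
    best = None
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            for s3 in (1.0, -1.0):
                S = np.diag([s1, s2, s3])
                R = Ud @ S @ Us.T
                if np.linalg.det(R) < 0:
                    continue
                if best is None or np.trace(R) > np.trace(best):
                    best = R
    return RigidTransform(best, cd - best @ cs)


def icp_align(source, target, init: RigidTransform | None = None,
              max_iter: int = 50, tol: float = 1e-6) -> RigidTransform:
    """Point-to-point ICP aligning ``source`` onto ``target``.

    Nearest-neighbour correspondences (k-d tree), closed-form SVD update,
    iterate until the RMS change drops below ``tol`` or ``max_iter``.
    Without an explicit ``init`` a centroid/principal-axes coarse alignment
    seeds the iteration (plain identity starts are prone to grid-aliasing
    local minima on regularly sampled scan data).
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    dst = np.asarray(target, dtype=float).reshape(-1, 3)
    if len(src) < 3 or len(dst) < 3:
        raise ValueError("ICP needs at least 3 points in each set")
    if np.linalg.matrix_rank(dst - dst.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("rank-deficient (collinear) target")
    tf = init if init is not None else _coarse_align(src, dst)
    tree = cKDTree(dst)
    prev_rms = np.inf
    for _ in range(max_iter):
        moved = tf.apply(src)
        dist, idx = tree.query(moved)
        rms = float(np.sqrt(np.mean(dist**2)))
        if abs(prev_rms - rms) < tol:
            break
        prev_rms = rms
        step = _best_rigid(moved, dst[idx])
        tf = step.compose(tf)
    moved = tf.apply(src)
    dist, _ = tree.query(moved)
    tf.rms = float(np.sqrt(np.mean(dist**2)))
    return tf


def merge_profiles(profiles: list[Profile3D], cam: CameraModel,
                   use_icp: bool = False, icp_max_iter: int = 50,
                   icp_tol: float = 1e-6) -> PointCloud:
    """Merge per-frame profiles into one cloud.

    With ``use_icp`` off, profiles are stacked at their nominal conveyor
    positions.  With it on, each consecutive pair is refined by ICP
    initialized from the conveyor prior; because a single laser profile
    carries no information along the scan direction, the ICP correction is
    accepted only when it is a plausible refinement of the prior (translation
    ≤ half the conveyor step, rotation ≤ 2°) and its residual is below 5× the
    median pair residual — otherwise the nominal prior is kept with a warning.
    """
    if not profiles:
        raise ValueError("no profiles to merge")
    if not use_icp or len(profiles) == 1:
        pts = np.vstack([p.points for p in profiles])
        idx = np.concatenate([np.full(len(p.points), p.frame_index) for p in profiles])
        return PointCloud(pts, idx)

    corrections: list[RigidTransform] = []
    for prev, cur in zip(profiles[:-1], profiles[1:]):
        if len(cur.points) < 3 or len(prev.points) < 3:
            corrections.append(RigidTransform.identity())
            continue
        try:
            tf = icp_align(cur.points, prev.points,
                           init=RigidTransform.identity(),
                           max_iter=icp_max_iter, tol=icp_tol)
        except ValueError:
            tf = RigidTransform.identity()
        corrections.append(tf)

    rms_vals = np.array([c.rms for c in corrections])
    median_rms = float(np.median(rms_vals)) if len(rms_vals) else 0.0
    step_limit = 0.5 * cam.conveyor_step
    accepted: list[RigidTransform] = []
    for tf in corrections:
        angle = math.acos(np.clip((np.trace(tf.rotation) - 1) / 2, -1.0, 1.0))
        plausible = (np.linalg.norm(tf.translation) <= step_limit
                     and angle <= math.radians(2.0))
        if median_rms > 0 and tf.rms > 5 * median_rms:
            plausible = False
        if not plausible and (np.linalg.norm(tf.translation) > 1e-12
                              or angle > 1e-12):
            warnings.warn("ICP correction rejected; falling back to conveyor prior")
            tf = RigidTransform.identity()
        accepted.append(tf)

    out_pts = [profiles[0].points]
    out_idx = [np.full(len(profiles[0].points), profiles[0].frame_index)]
    cumulative = RigidTransform.identity()
    for prof, tf in zip(profiles[1:], accepted):
        cumulative = cumulative.compose(tf)
        out_pts.append(cumulative.apply(prof.points))
        out_idx.append(np.full(len(prof.points), prof.frame_index))
    return PointCloud(np.vstack(out_pts), np.concatenate(out_idx))


# ---------------------------------------------------------------------------
# ASCII PLY I/O
# ---------------------------------------------------------------------------

def write_ply(cloud: PointCloud, path: str | Path) -> None:
    """Write the cloud as ASCII PLY with x y z and a per-point frame index."""
    path = Path(path)
    n = len(cloud.points)
    lines = [
        "ply", "format ascii 1.0", f"element vertex {n}",
        "property float x", "property float y", "property float z",
        "property int frame", "end_header",
    ]
    body = [f"{x:.6f} {y:.6f} {z:.6f} {f}"
            for (x, y, z), f in zip(cloud.points, cloud.frame_index)]
    path.write_text("\n".join(lines + body) + "\n")


def read_ply(path: str | Path) -> PointCloud:
    text = Path(path).read_text().splitlines()
    try:
        start = text.index("end_header") + 1
    except ValueError as exc:
        raise ValueError("not an ASCII PLY file") from exc
    rows = [line.split() for line in text[start:] if line.strip()]
    pts = np.array([[float(r[0]), float(r[1]), float(r[2])] for r in rows])
    idx = np.array([int(r[3]) if len(r) > 3 else 0 for r in rows])
    return PointCloud(pts, idx)
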