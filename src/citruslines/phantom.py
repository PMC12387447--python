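"""Synthetic citrus phantom: surface, ground truth and rendered stripe frames.

The fruit is modelled as a half-ellipsoid dome z = c·sqrt(1 − (x/a)² −
(y/b)²) sitting on the conveyor reference plane, with each separation line a
Gaussian-in-azimuth groove of fixed depth carved toward the apex.  Frames are
rendered by inverting the triangulation relation — a surface height h shifts
the stripe by n(h) = h·M1·tanθ/(M2 − h) on the sensor — and drawing a
vertical-Gaussian stripe profile per column, plus sensor noise and optional
bright-blob / spurious-branch artifacts that emulate peel reflections and
texture.  Every stage downstream is testable against the returned ground
truth (per-frame centerline rows, 3D groove-bottom polylines, ideal
grooveless cross-sections).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .reconstruction import CameraModel, height_to_shift

__all__ = [
    "PhantomSpec",
    "HeightField",
    "GroundTruth",
    "FrameSequence",
    "default_camera",
    "make_phantom_surface",
    "render_stripe_frames",
    "make_skeleton_fixture",
]


def default_camera(image_width: int = 640, image_height: int = 480) -> CameraModel:
    """Desk-scale camera matched to the default phantom geometry."""
    return CameraModel(cx=image_width / 2.0, cy=image_height / 2.0,
                       reference_row=round(image_height * 0.875))


@dataclass
class PhantomSpec:
    """Generator conditions for one synthetic citrus scan.

    ``half_axes`` (a, b, c) are the dome semi-axes in mm (a lateral, b along
    the conveyor, c height); grooves are depressions of ``groove_depth`` mm
    with Gaussian azimuthal sigma ``groove_angular_width`` (radians) at
    ``groove_azimuths``.  Stripe rendering uses a Gaussian cross profile of
    sigma ``stripe_sigma`` px and peak ``stripe_peak``; ``noise_sigma`` is
    additive Gaussian intensity noise and ``artifact_rate`` the per-frame
    probability of a spurious bright blob or branch.  The same seed yields
    bit-identical output.
    """

    half_axes: tuple = (40.0, 18.0, 25.0)
    n_grooves: int = 3
    groove_depth: float = 2.0
    groove_angular_width: float = 0.12
    groove_azimuths: list = None
    noise_sigma: float = 2.0
    stripe_peak: int = 220
    stripe_sigma: float = 2.5
    artifact_rate: float = 0.1
    artifact_kind: str = "both"  # 'blob' | 'branch' | 'both'
    seed: int = 0
    n_frames: int = 60
    image_width: int = 640
    image_height: int = 480

    def __post_init__(self) -> None:
        if min(self.half_axes) <= 0:
            raise ValueError("half_axes must be positive")
        if not (0 <= self.n_grooves <= 16):
            raise ValueError("n_grooves must be in [0, 16]")
        if self.groove_depth < 0:
            raise ValueError("groove_depth must be non-negative")
        if self.stripe_sigma <= 0:
            raise ValueError("stripe_sigma must be positive")
        if self.artifact_kind not in ("blob", "branch", "both"):
            raise ValueError("artifact_kind must be 'blob', 'branch' or 'both'")
        if self.groove_azimuths is None:
            # evenly spaced about the apex, first groove pointing down-conveyor
            self.groove_azimuths = [math.pi / 2 + k * 2 * math.pi / max(self.n_grooves, 1)
                                    for k in range(self.n_grooves)]
        if len(self.groove_azimuths) != self.n_grooves:
            raise ValueError("groove_azimuths length must equal n_grooves")
        az = sorted(a % (2 * math.pi) for a in self.groove_azimuths)
        for i in range(len(az)):
            gap = (az[(i + 1) % len(az)] - az[i]) % (2 * math.pi) if len(az) > 1 else np.inf
            if len(az) > 1 and gap < 2 * self.groove_angular_width:
                raise ValueError("grooves overlap")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["half_axes"] = list(self.half_axes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        if "half_axes" in d:
            d["half_axes"] = tuple(d["half_axes"])
        return cls(**d)


@dataclass
class HeightField:
    """Surface heights (mm) sampled on the camera grid: z[frame, column]."""

    z: np.ndarray
    spacing: tuple  # (dy, dx) mm per grid step
    x: np.ndarray = None  # column centres, mm
    y: np.ndarray = None  # frame positions, mm

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)) or np.any(self.z < 0):
            raise ValueError("height field must be finite and non-negative")


@dataclass
class GroundTruth:
    true_centerlines: np.ndarray = None   # (n_frames, n_cols) stripe row per column
    true_lines: list = field(default_factory=list)   # per groove (K, 3) polylines
    true_sections: list = field(default_factory=list)  # per frame (n_cols, 2) ideal (x, z)


@dataclass
class FrameSequence:
    frames: list            # per frame (H, W, 3) uint8
    true_rows: np.ndarray   # (n_frames, n_cols) float stripe centre rows
    seed: int = 0


# radial taper keeps the apex (undefined azimuth) groove-free
_TAPER_FRAC = 0.1


def _groove_depression(x: np.ndarray, y: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Total groove depth at (x, y) about the apex at the origin."""
    if spec.n_grooves == 0 or spec.groove_depth == 0:
        return np.zeros(np.broadcast(x, y).shape)
    a, b, _ = spec.half_axes
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    r0 = _TAPER_FRAC * min(a, b)
    taper = 1.0 - np.exp(-((r / r0) ** 2))
    total = np.zeros(np.broadcast(x, y).shape)
    for az in spec.groove_azimuths:
        dphi = np.angle(np.exp(1j * (phi - az)))
        total += np.exp(-(dphi**2) / (2 * spec.groove_angular_width**2))
    return spec.groove_depth * taper * total


def _dome(x: np.ndarray, y: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    a, b, c = spec.half_axes
    return c * np.sqrt(np.clip(1.0 - (x / a) ** 2 - (y / b) ** 2, 0.0, None))


def make_phantom_surface(spec: PhantomSpec,
                         cam: CameraModel | None = None
                         ) -> tuple[HeightField, GroundTruth]:
    """Build the grooved dome height field and its ground truth.

    The field is sampled exactly at the camera grid: column c at
    x = (c − cx)·lateral_scale, frame i at y = i·conveyor_step, with the dome
    apex centred in the scanned span.  Grooves are subtracted from the dome
    and the result clipped at the conveyor plane (z = 0).
    """
    if cam is None:
        cam = default_camera(spec.image_width, spec.image_height)
    dy = cam.conveyor_step
    cols = np.arange(spec.image_width)
    x = (cols - cam.cx) * cam.lateral_scale
    y_frames = np.arange(spec.n_frames) * dy
    y0 = y_frames[-1] / 2.0 if spec.n_frames > 1 else 0.0
    X, Y = np.meshgrid(x, y_frames - y0)

    dome = _dome(X, Y, spec)
    depression = _groove_depression(X, Y, spec)
    z = np.clip(dome - depression, 0.0, None)
    # grooves exist only on the fruit
    z[dome <= 0] = 0.0

    field_ = HeightField(z=z, spacing=(dy, cam.lateral_scale), x=x, y=y_frames)

    truth = GroundTruth()
    truth.true_sections = [np.stack([x, dome[i]], axis=1) for i in range(spec.n_frames)]

    a, b, _ = spec.half_axes
    r0 = _TAPER_FRAC * min(a, b)
    for az in spec.groove_azimuths:
        cphi, sphi = math.cos(az), math.sin(az)
        denom = math.sqrt((cphi / a) ** 2 + (sphi / b) ** 2)
        r_rim = 1.0 / denom
        # trace from where the taper reaches half depth out to the rim
        r = np.linspace(r0 * math.sqrt(math.log(2.0)), r_rim * 0.999, 200)
        xl, yl = r * cphi, r * sphi
        zl = np.clip(_dome(xl, yl, spec) - _groove_depression(xl, yl, spec), 0.0, None)
        keep = _dome(xl, yl, spec) > 0
        line = np.stack([xl[keep], yl[keep] + y0, zl[keep]], axis=1)
        truth.true_lines.append(line)
    return field_, truth


def _add_blob(frame: np.ndarray, rng: np.random.Generator, row: float,
              spec: PhantomSpec) -> None:
    H, W = frame.shape[:2]
    r0 = float(np.clip(row + rng.uniform(-40, 40), 5, H - 6))
    c0 = rng.uniform(5, W - 6)
    radius = rng.uniform(3, 7)
    rr, cc = np.mgrid[0:H, 0:W]
    blob = spec.stripe_peak * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * radius**2))
    frame[:, :, 1] = np.clip(frame[:, :, 1] + blob, 0, 255)


def _add_branch(frame: np.ndarray, rng: np.random.Generator,
                rows: np.ndarray, spec: PhantomSpec) -> None:
    """Bright spur attached to the stripe, slanted off it."""
    H, W = frame.shape[:2]
    c0 = int(rng.integers(W // 8, 7 * W // 8))
    r0 = rows[c0]
    length = int(rng.integers(15, 31))
    drow = rng.choice([-1, 1])
    dcol = rng.choice([-1, 1])
    rr, cc = np.mgrid[0:H, 0:W]
    for t in range(length):
        r = r0 + drow * t
        c = c0 + dcol * t
        if not (0 <= r < H and 0 <= c < W):
            break
        spur = spec.stripe_peak * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * 1.2**2))
        frame[:, :, 1] = np.clip(frame[:, :, 1] + spur, 0, 255)


def render_stripe_frames(field: HeightField, cam: CameraModel,
                         spec: PhantomSpec) -> FrameSequence:
    """Render one green-laser stripe frame per conveyor position.

    The stripe centre row in column c of frame i is reference_row − n(h)/pitch
    with h = field.z[i, c]; the cross profile is Gaussian with sigma
    ``stripe_sigma`` and peak ``stripe_peak`` in the green channel.  Additive
    Gaussian noise and (with probability ``artifact_rate``) one bright blob or
    spurious branch per frame complete the image.  Deterministic per seed.
    """
    if np.any(field.z >= cam.M2):
        raise ValueError("height exceeds object distance")
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    n_frames = field.z.shape[0]
    row_axis = np.arange(H, dtype=float)[:, None]
    frames = []
    true_rows = np.empty((n_frames, W))
    for i in range(n_frames):
        shift_px = height_to_shift(field.z[i], cam) / cam.pixel_pitch
        centers = cam.reference_row - shift_px
        true_rows[i] = centers
        stripe = spec.stripe_peak * np.exp(
            -((row_axis - centers[None, :]) ** 2) / (2 * spec.stripe_sigma**2))
        frame = np.zeros((H, W, 3), dtype=float)
        frame[:, :, 1] = stripe
        frame[:, :, 0] = 0.15 * stripe
        if spec.artifact_rate > 0 and rng.random() < spec.artifact_rate:
            kind = spec.artifact_kind
            if kind == "both":
                kind = "blob" if rng.random() < 0.5 else "branch"
            if kind == "blob":
                _add_blob(frame, rng, float(np.median(centers)), spec)
            else:
                _add_branch(frame, rng, centers, spec)
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, frame.shape)
        frames.append(np.clip(np.round(frame), 0, 255).astype(np.uint8))
    return FrameSequence(frames=frames, true_rows=true_rows, seed=spec.seed)


def make_skeleton_fixture(seed: int, size: int = 64,
                          n_branches: int = 0) -> tuple[np.ndarray, "np.ndarray"]:
    """Random single-pixel tree skeleton: a main path plus short spurs.

    The main path runs left to right with E/NE/SE unit steps (one pixel per
    column, so no 2×2 blocks and no cycles); each spur is a straight vertical
    run attached at an interior column, kept short enough that the main path
    remains the unique longest endpoint-to-endpoint path.  Returns the
    boolean mask and the true main path as an ordered (N, 2) array.
    """
    if size < 16:
        raise ValueError("size must be at least 16")
    for restart in range(100):
        rng = np.random.default_rng((seed, restart))
        out = _try_skeleton_fixture(rng, size, n_branches)
        if out is not None:
            return out
    raise RuntimeError("could not place requested spurs")


def _try_skeleton_fixture(rng: np.random.Generator, size: int,
                          n_branches: int) -> tuple[np.ndarray, np.ndarray] | None:
    n_cols = size
    row = size // 2
    path = [(row, 0)]
    for c in range(1, n_cols):
        step = int(rng.choice([-1, 0, 1]))
        row = int(np.clip(row + step, 3, size - 4))
        path.append((row, c))
    path_arr = np.array(path)
    row_of = {c: r for r, c in path}

    mask = np.zeros((size, size), dtype=bool)
    mask[path_arr[:, 0], path_arr[:, 1]] = True

    # spurs attach only at strict local extrema of the path so the spur run
    # touches nothing but its attachment pixel (keeps the skeleton a tree)
    max_spur = max(2, n_cols // 6)
    used_cols: set[int] = set()
    placed = 0
    for _ in range(500):
        if placed >= n_branches:
            break
        c = int(rng.integers(n_cols // 3, 2 * n_cols // 3))
        if any(abs(c - u) < 3 for u in used_cols):
            continue
        r = row_of[c]
        rl, rr_ = row_of[c - 1], row_of[c + 1]
        if rl > r and rr_ > r:
            direction = -1          # strict local minimum: spur goes up
        elif rl < r and rr_ < r:
            direction = 1           # strict local maximum: spur goes down
        else:
            continue
        length = int(rng.integers(2, max_spur + 1))
        rows = [r + direction * t for t in range(1, length + 1)]
        if rows[-1] < 1 or rows[-1] > size - 2:
            continue
        mask[rows, c] = True
        used_cols.add(c)
        placed += 1
    if placed < n_branches:
        return None
    return mask, path_arr.astype(float)
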