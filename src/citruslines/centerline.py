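"""Stripe centerline extraction by skeleton pruning.

The stripe mask is thinned to a single-pixel skeleton (Zhang–Suen).  Surface
texture and reflections grow short spurious branches on that skeleton; the
pruning step classifies pixels by their 8-neighbourhood count Np (endpoint
Np=1, branch point Np>2), traces every endpoint-to-endpoint path with an
8-neighbourhood tracking strategy and a branch-point backtrack stack, and
keeps the longest path — the main branch — as the centerline.  A perpendicular
intensity-centroid refinement provides sub-pixel coordinates, and the classic
per-column grayscale centre-of-gravity extractor is included as the
comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "SkeletonGraph",
    "CenterlinePath",
    "thin",
    "classify_points",
    "prune_to_main_branch",
    "subpixel_refine",
    "grayscale_centroid",
]

# fixed 8-neighbour visit order: E, SE, S, SW, W, NW, N, NE
_NEIGHBOR_ORDER = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass
class SkeletonGraph:
    """Single-pixel-wide skeleton with 8-adjacency bookkeeping.

    ``pixels`` is the ordered (row-major) array of skeleton coordinates;
    ``neighbor_count`` the per-pixel Np over the 8-neighbourhood restricted
    to skeleton pixels; ``endpoints`` the set Me (Np = 1), ``branch_points``
    the set Mb (Np > 2) and ``isolated`` the Np = 0 pixels.
    """

    pixels: np.ndarray                    # (N, 2) int (row, col)
    neighbor_count: np.ndarray            # (N,)
    endpoints: set = field(default_factory=set)
    branch_points: set = field(default_factory=set)
    isolated: set = field(default_factory=set)

    @classmethod
    def from_mask(cls, skel_mask: np.ndarray) -> "SkeletonGraph":
        skel_mask = np.asarray(skel_mask, dtype=bool)
        rows, cols = np.nonzero(skel_mask)
        pixels = np.stack([rows, cols], axis=1)
        kernel = np.ones((3, 3), dtype=int)
        kernel[1, 1] = 0
        counts = ndimage.convolve(skel_mask.astype(int), kernel, mode="constant")
        np_counts = counts[rows, cols]
        endpoints = {tuple(p) for p, n in zip(pixels, np_counts) if n == 1}
        branch_points = {tuple(p) for p, n in zip(pixels, np_counts) if n > 2}
        isolated = {tuple(p) for p, n in zip(pixels, np_counts) if n == 0}
        return cls(pixels=pixels, neighbor_count=np_counts,
                   endpoints=endpoints, branch_points=branch_points,
                   isolated=isolated)

    def as_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        if shape is None:
            shape = (int(self.pixels[:, 0].max()) + 1, int(self.pixels[:, 1].max()) + 1)
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class CenterlinePath:
    """Ordered (sub)pixel centerline coordinates (row, col)."""

    points: np.ndarray  # (N, 2) float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def length(self) -> int:
        return len(self.points)


def thin(mask: np.ndarray) -> SkeletonGraph:
    """Zhang–Suen thinning of a binary mask to a single-pixel skeleton."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    skel = skeletonize(mask, method="zhang")
    return SkeletonGraph.from_mask(skel)


def classify_points(skel: SkeletonGraph) -> tuple[set, set]:
    """Endpoint set Me (Np = 1) and branch-point set Mb (Np > 2)."""
    if len(skel.pixels) == 0:
        raise ValueError("empty skeleton")
    return skel.endpoints, skel.branch_points


def _adjacency(pixel_set: set) -> dict:
    adj = {}
    for r, c in pixel_set:
        adj[(r, c)] = [(r + dr, c + dc) for dr, dc in _NEIGHBOR_ORDER
                       if (r + dr, c + dc) in pixel_set]
    return adj


def prune_to_main_branch(skel: SkeletonGraph) -> CenterlinePath:
    """Keep only the main branch: the longest endpoint-to-endpoint path.

    Endpoints are visited in row-major order; from each, an iterative
    8-neighbourhood trace explores the skeleton, pushing branch points on a
    backtrack stack Vb and popping it when a dead end or endpoint is reached.
    Path length is the inclusive pixel count; strictly longer paths replace
    the incumbent, so equal-length ties resolve to the first traced path.
    Isolated pixels are dropped before tracing; a skeleton with no endpoints
    (a pure cycle) is rejected.
    """
    pixel_set = {tuple(p) for p in skel.pixels} - skel.isolated
    if not pixel_set:
        raise ValueError("empty skeleton")
    endpoints = sorted(skel.endpoints)
    if not endpoints:
        raise ValueError("cyclic skeleton: no endpoints to trace from")
    adj = _adjacency(pixel_set)

    best: list | None = None
    best_len = 0
    for start in endpoints:
        # depth-first simple-path enumeration; the explicit stack of
        # (pixel, neighbor cursor) is the branch-point backtrack stack Vb.
        path = [start]
        on_path = {start}
        cursor = [0]
        while path:
            node = path[-1]
            advanced = False
            while cursor[-1] < len(adj[node]):
                nxt = adj[node][cursor[-1]]
                cursor[-1] += 1
                if nxt in on_path:
                    continue
                path.append(nxt)
                on_path.add(nxt)
                cursor.append(0)
                if nxt in skel.endpoints and len(path) > 1:
                    if len(path) > best_len:
                        best_len = len(path)
                        best = list(path)
                    # endpoint terminates this trace; backtrack
                    on_path.discard(path.pop())
                    cursor.pop()
                else:
                    advanced = True
                break
            if not advanced and path:
                if cursor[-1] >= len(adj[path[-1]]):
                    on_path.discard(path.pop())
                    cursor.pop()
    if best is None:
        # single isolated endpoint pair degenerate case: one pixel
        best = [endpoints[0]]
    if best[0] > best[-1]:
        best = best[::-1]
    return CenterlinePath(np.array(best, dtype=float))


def subpixel_refine(path: CenterlinePath, img: np.ndarray,
                    half_width: int = 5) -> CenterlinePath:
    """Refine each point to the intensity centroid along the local normal.

    The tangent is a central difference over the ordered path; intensities
    are sampled by bilinear interpolation at unit steps within ±half_width
    along the perpendicular.  Windows falling outside the image leave the
    point unchanged; each refined point moves less than half_width.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    img = np.asarray(img, dtype=float)
    pts = path.points.copy()
    n = len(pts)
    if n == 0:
        return CenterlinePath(pts)
    offsets = np.arange(-half_width, half_width + 1, dtype=float)
    refined = pts.copy()
    for i in range(n):
        lo, hi = max(0, i - 2), min(n - 1, i + 2)
        tangent = pts[hi] - pts[lo]
        norm = np.hypot(*tangent)
        if norm == 0:
            continue
        tangent /= norm
        normal = np.array([-tangent[1], tangent[0]])
        sample = pts[i][None, :] + offsets[:, None] * normal[None, :]
        if (sample[:, 0].min() < 0 or sample[:, 0].max() > img.shape[0] - 1
                or sample[:, 1].min() < 0 or sample[:, 1].max() > img.shape[1] - 1):
            continue
        vals = ndimage.map_coordinates(img, sample.T, order=1, mode="nearest")
        total = vals.sum()
        if total <= 0:
            continue
        shift = float((vals * offsets).sum() / total)
        refined[i] = pts[i] + shift * normal
    return CenterlinePath(refined)


def grayscale_centroid(img: np.ndarray, mask: np.ndarray) -> CenterlinePath:
    """Per-column grayscale centre-of-gravity baseline.

    For every image column containing masked pixels the centre row is the
    intensity-weighted mean Σ(row·I)/ΣI over those pixels.  Considering only
    the longitudinal (per-column) distribution, two bright regions in one
    column fold into a centre between them — the known failure mode on
    branched stripes.
    """
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    points = []
    for col in range(img.shape[1]):
        rows = np.nonzero(mask[:, col])[0]
        if rows.size == 0:
            continue
        weights = img[rows, col]
        total = weights.sum()
        center = float(rows.mean()) if total <= 0 else float((rows * weights).sum() / total)
        points.append((center, float(col)))
    return CenterlinePath(np.array(points, dtype=float).reshape(-1, 2))
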