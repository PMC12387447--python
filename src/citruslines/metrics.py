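"""Evaluation statistics for centerlines and separation lines.

Two RMSE-like quantities appear in this problem and they are not the same:
``rmse_spread`` is the spread of the centre-point distances about their own
mean, R = sqrt(Σ(x_i − x̄)²/n) — the per-frame centerline accuracy statistic —
while ``point_errors`` reports conventional MAE and RMS-about-zero of matched
point distances between a detected and a reference separation line.  The
similarity S between two position sequences is their cosine,
S = ΣM_iN_i / sqrt(ΣM_i²·ΣN_i²); an alternate "printed form" without the
square root is kept for auditability (it is not 1 for identical inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np

from .spline import lspia_fit, evaluate_curve

__all__ = [
    "MetricsReport",
    "rmse_spread",
    "centerline_rmse",
    "resample_polyline",
    "clip_polyline_to_y_range",
    "point_errors",
    "similarity",
    "fraction_within",
    "table_averages",
]


@dataclass
class MetricsReport:
    rmse_spread: float = None
    mae: float = None
    rmse: float = None
    similarity: float = None
    errors: list = field(default_factory=list)
    fraction_within: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def rmse_spread(distances, about_zero: bool = False) -> float:
    """R = sqrt(Σ(x_i − x̄)²/n): spread of distances about their mean.

    ``about_zero=True`` gives the conventional RMS about zero instead.
    """
    x = np.asarray(distances, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 distances")
    if about_zero:
        return float(np.sqrt(np.mean(x**2)))
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def _orthogonal_distances(points: np.ndarray, curve, n_dense: int = 2000) -> np.ndarray:
    """Distance of each point to the curve, minimized over the parameter by
    dense sampling plus local parabolic refinement."""
    lo, hi = curve.domain
    u = np.linspace(lo, hi, n_dense)
    samples = np.atleast_2d(evaluate_curve(curve, u))
    d2 = ((points[:, None, :] - samples[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(points)), idx])
    # parabolic refinement on the squared distance over neighbouring samples
    interior = (idx > 0) & (idx < n_dense - 1)
    ii = idx[interior]
    f0 = d2[interior, ii - 1]
    f1 = d2[interior, ii]
    f2 = d2[interior, ii + 1]
    denom = f0 - 2 * f1 + f2
    ok = np.abs(denom) > 1e-300
    off = np.where(ok, 0.5 * (f0 - f2) / np.where(ok, denom, 1.0), 0.0)
    off = np.clip(off, -1.0, 1.0)
    fmin = f1 - 0.25 * (f0 - f2) * off
    dist[interior] = np.sqrt(np.clip(fmin, 0.0, None))
    return dist


def centerline_rmse(path, n_controls: int = 8) -> float:
    """Per-frame centerline accuracy: fit the centre points with LSPIA and
    report the spread of their orthogonal distances to the fitted curve."""
    pts = np.asarray(getattr(path, "points", path), dtype=float)
    if len(pts) < n_controls + 2:
        raise ValueError("too few points for the requested fit")
    fit = lspia_fit(pts, n_controls=n_controls)
    distances = _orthogonal_distances(pts, fit.curve)
    return rmse_spread(distances)


def resample_polyline(poly: np.ndarray, k: int) -> np.ndarray:
    """Resample an ordered polyline to k points uniform in normalized arc length."""
    poly = np.asarray(poly, dtype=float)
    if len(poly) < 2:
        raise ValueError("degenerate polyline")
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise ValueError("degenerate polyline")
    s /= s[-1]
    targets = np.linspace(0.0, 1.0, k)
    out = np.empty((k, poly.shape[1]))
    for d in range(poly.shape[1]):
        out[:, d] = np.interp(targets, s, poly[:, d])
    return out


def clip_polyline_to_y_range(poly: np.ndarray, y_min: float, y_max: float,
                             pad: float = 0.0) -> np.ndarray | None:
    """Restrict a polyline (with y in column 1) to [y_min − pad, y_max + pad]."""
    poly = np.asarray(poly, dtype=float)
    sel = (poly[:, 1] >= y_min - pad) & (poly[:, 1] <= y_max + pad)
    if sel.sum() < 2:
        return None
    return poly[sel]


def point_errors(pred, truth, k_min: int = 50) -> tuple[float, float, np.ndarray]:
    """One-to-one matched Euclidean distance errors between two lines.

    Both polylines are resampled to the same count by normalized arc length
    (the smaller of the two lengths, raised to at least ``k_min``); errors
    are the per-index distances, reported as (MAE, RMSE, errors).
    """
    p = np.asarray(getattr(pred, "points", pred), dtype=float)
    t = np.asarray(truth, dtype=float)
    if len(p) < 2 or len(t) < 2:
        raise ValueError("degenerate line")
    k = max(k_min, min(len(p), len(t)))
    rp = resample_polyline(p, k)
    rt = resample_polyline(t, k)
    if rp.shape[1] != rt.shape[1]:
        raise ValueError("dimension mismatch")
    errors = np.linalg.norm(rp - rt, axis=1)
    # polylines carry no canonical direction; match the consistent orientation
    flipped = np.linalg.norm(rp - rt[::-1], axis=1)
    if flipped.mean() < errors.mean():
        errors = flipped
    return float(errors.mean()), float(np.sqrt(np.mean(errors**2))), errors


def nearest_point_distances(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest location on a polyline."""
    points = np.asarray(points, dtype=float)
    poly = np.asarray(poly, dtype=float)
    if len(poly) < 2:
        raise ValueError("degenerate polyline")
    a, b = poly[:-1], poly[1:]
    d = b - a
    seg_len2 = (d * d).sum(axis=1)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        t = np.clip(((p - a) * d).sum(axis=1) / seg_len2, 0.0, 1.0)
        proj = a + t[:, None] * d
        out[i] = np.linalg.norm(proj - p, axis=1).min()
    return out


def similarity(M, N, printed_form: bool = False) -> float:
    """Cosine similarity of two flattened position sequences.

    S = ΣM_iN_i / sqrt(ΣM_i²·ΣN_i²) ∈ [−1, 1]; S = 1 iff N = cM with c > 0.
    ``printed_form`` drops the square root from the denominator.
    """
    m = np.asarray(M, dtype=float).ravel()
    n = np.asarray(N, dtype=float).ravel()
    if m.shape != n.shape:
        raise ValueError("sequences must have equal length")
    mm = float(np.dot(m, m))
    nn = float(np.dot(n, n))
    if mm == 0 or nn == 0:
        raise ValueError("zero-norm input")
    num = float(np.dot(m, n))
    if printed_form:
        return num / (mm * nn)
    return num / np.sqrt(mm * nn)


def fraction_within(errors, bound: float) -> float:
    """Fraction of errors strictly below the bound."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("errors must be non-empty")
    if bound <= 0:
        raise ValueError("bound must be positive")
    return float(np.mean(e < bound))


def table_averages(values, decimals: int = 3) -> float:
    """Arithmetic mean reported at fixed decimals (round-half-even)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    return float(round(float(v.mean()), decimals))
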