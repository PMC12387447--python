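"""Separation-line localization by deviation from the ideal cross-section.

Each cross-section of the merged cloud is fitted with a robust trimmed
LSPIA spline — the "ideal curve", the section as if no separation groove
existed.  Local PCA on sampled curve windows gives outward unit normals
(tangent = major eigenvector of the de-meaned point covariance, normal =
minor); casting each normal against the actual section polyline yields a
signed deviation, negative where the surface lies below the ideal curve.
Runs of deviations below −τ mark groove candidates, and candidates are
linked across sections into 3D separation lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spline import BSplineCurve, lspia_fit, evaluate_curve
from .reconstruction import PointCloud
from . import metrics as _metrics

__all__ = [
    "CrossSection",
    "DeviationProfile",
    "SeparationLine",
    "slice_cross_sections",
    "fit_ideal_section",
    "pca_normal",
    "deviation_profile",
    "detect_feature_regions",
    "assemble_separation_lines",
    "detect_lines",
    "calibrate_threshold",
]

MIN_SECTION_POINTS = 10


@dataclass
class CrossSection:
    """One y-slice of the cloud: (x, z) points ordered along the profile."""

    y_value: float
    points: np.ndarray  # (N, 2) mm, ordered by x

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)


@dataclass
class DeviationProfile:
    samples: np.ndarray      # (K, 2) ideal curve points
    normals: np.ndarray      # (K, 2) outward unit normals
    deviations: np.ndarray   # (K,) signed mm, NaN where no intersection
    hits: np.ndarray         # (K,) bool
    y_value: float = 0.0
    tau: float = 0.0


@dataclass
class SeparationLine:
    line_id: int
    points: np.ndarray       # (N, 3) mm ordered by y
    deviations: np.ndarray   # (N,)
    support: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.deviations = np.asarray(self.deviations, dtype=float)


@dataclass
class RegionHit:
    """Deepest sample of one below-threshold run within a section."""
    x: float
    z: float
    y: float
    deviation: float
    run_length: int


def slice_cross_sections(cloud: PointCloud, bin_width: float,
                         z_floor: float = 0.0) -> list[CrossSection]:
    """Bucket cloud points by y into sections of (x, z) points ordered by x.

    Points at or below ``z_floor`` (conveyor plane / rim clutter) are
    excluded; bins with fewer than 10 usable points are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pts = cloud.points
    if len(pts) == 0:
        raise ValueError("no usable sections")
    usable = pts[pts[:, 2] > z_floor]
    if len(usable) == 0:
        raise ValueError("no usable sections")
    bins = np.floor(usable[:, 1] / bin_width + 0.5).astype(int)
    sections = []
    for b in np.unique(bins):
        sel = usable[bins == b]
        if len(sel) < MIN_SECTION_POINTS:
            continue
        order = np.argsort(sel[:, 0], kind="stable")
        xz = sel[order][:, [0, 2]]
        sections.append(CrossSection(y_value=float(b * bin_width), points=xz))
    if not sections:
        raise ValueError("no usable sections")
    return sections


def fit_ideal_section(section: CrossSection, n_controls: int = 8,
                      trim_frac: float = 0.3, tol: float = 1e-8,
                      max_iter: int = 2000, trim_passes: int = 5
                      ) -> BSplineCurve:
    """Robust trimmed LSPIA fit of the grooveless "ideal" section curve.

    Fit all points, then repeatedly discard the points with the most negative
    below-curve residuals (groove candidates depress the surface) and refit,
    until no material outlier remains, at most ``trim_passes`` refits, with
    at most ``trim_frac`` of the points discarded in total.  A groove
    candidate must be a material outlier — more than 3 robust (MAD) sigmas
    below the median residual — so ordinary spline-approximation wiggle is
    never trimmed.  ``trim_frac=0`` is a plain fit.  A deliberately small
    control count keeps the spline stiff so broad grooves cannot pull the
    ideal curve down before they are trimmed.
    """
    Q = section.points
    if len(Q) < MIN_SECTION_POINTS:
        raise ValueError("section too small to fit")
    fit = lspia_fit(Q, n_controls=n_controls, tol=tol, max_iter=max_iter)
    cap = int(trim_frac * len(Q))
    if trim_frac <= 0 or cap == 0:
        return fit.curve
    keep = np.arange(len(Q))
    dropped = 0
    for _ in range(trim_passes):
        below = fit.residuals[:, 1]  # actual z minus curve z, same parameter
        mad_sigma = 1.4826 * np.median(np.abs(below - np.median(below)))
        gate = np.median(below) - 3.0 * max(mad_sigma, 1e-12)
        order = np.argsort(below, kind="stable")
        budget = cap - dropped
        drop = [i for i in order[:budget].tolist() if below[i] < min(gate, 0.0)]
        if not drop:
            break
        if len(keep) - len(drop) < max(n_controls + 1, MIN_SECTION_POINTS):
            raise ValueError("too few points left after trimming")
        mask = np.ones(len(keep), dtype=bool)
        mask[drop] = False
        keep = keep[mask]
        dropped += len(drop)
        fit = lspia_fit(Q[keep], n_controls=n_controls, tol=tol,
                        max_iter=max_iter)
    return fit.curve


def pca_normal(points: np.ndarray, orient_away_from: np.ndarray | None = None
               ) -> np.ndarray:
    """Outward unit normal of a local 2D curve window via PCA.

    The window is de-meaned, its covariance C = XXᵀ/(n−1) eigen-decomposed;
    the major eigenvector is the local tangent and the minor one the normal.
    The sign points away from ``orient_away_from`` (e.g. the section
    centroid) when given, else toward +z.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(P) < 3:
        raise ValueError("window needs at least 3 points")
    X = P - P.mean(axis=0)
    C = X.T @ X / (len(P) - 1)
    if not np.any(np.abs(C) > 1e-15):
        raise ValueError("degenerate window: zero covariance")
    w, V = np.linalg.eigh(C)
    normal = V[:, 0]  # minor eigenvector
    if orient_away_from is not None:
        outward = P.mean(axis=0) - np.asarray(orient_away_from, dtype=float)
        if np.dot(normal, outward) < 0:
            normal = -normal
    elif normal[1] < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


def _ray_polyline_hits(origin: np.ndarray, direction: np.ndarray,
                       poly: np.ndarray, max_range: float) -> float:
    """Signed parameter of the nearest intersection of the normal line with
    the polyline, or NaN.  Vectorized over polyline segments."""
    a = poly[:-1]
    d_seg = poly[1:] - a
    # solve origin + t*direction = a + s*d_seg
    det = direction[0] * (-d_seg[:, 1]) - direction[1] * (-d_seg[:, 0])
    ok = np.abs(det) > 1e-12
    rhs = a - origin
    t = (rhs[:, 0] * (-d_seg[:, 1]) - rhs[:, 1] * (-d_seg[:, 0]))
    s = (direction[0] * rhs[:, 1] - direction[1] * rhs[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, t / det, np.nan)
        s = np.where(ok, s / det, np.nan)
    valid = ok & (s >= 0.0) & (s <= 1.0) & (np.abs(t) <= max_range)
    if not np.any(valid):
        return float("nan")
    tv = t[valid]
    return float(tv[np.argmin(np.abs(tv))])


def deviation_profile(ideal: BSplineCurve, actual: CrossSection,
                      n_samples: int = 400, window: int = 9,
                      max_range: float = 10.0,
                      edge_margin: float = 0.03) -> DeviationProfile:
    """Signed normal-direction deviation of the actual section from the ideal.

    The ideal curve is sampled uniformly in parameter; per sample the PCA
    normal over ``window`` neighbouring samples is cast both ways (up to
    ``max_range`` mm) against the actual polyline, and the deviation is the
    signed distance along the outward normal to the first intersection —
    negative where the actual surface lies below the ideal (a groove).
    Samples within ``edge_margin`` of either curve end are excluded: the
    spline is least constrained there and rim slopes are steep.
    """
    lo, hi = ideal.domain
    span = hi - lo
    u = np.linspace(lo + edge_margin * span, hi - edge_margin * span, n_samples)
    samples = np.atleast_2d(evaluate_curve(ideal, u))
    centroid = actual.points.mean(axis=0)
    half = max(1, window // 2)
    normals = np.empty_like(samples)
    deviations = np.full(n_samples, np.nan)
    poly = actual.points
    for i in range(n_samples):
        a, b = max(0, i - half), min(n_samples, i + half + 1)
        normals[i] = pca_normal(samples[a:b], orient_away_from=centroid)
        deviations[i] = _ray_polyline_hits(samples[i], normals[i], poly, max_range)
    hits = np.isfinite(deviations)
    return DeviationProfile(samples=samples, normals=normals,
                            deviations=deviations, hits=hits,
                            y_value=actual.y_value)


def detect_feature_regions(profile: DeviationProfile, tau: float,
                           min_run: int = 2, signed: bool = True
                           ) -> list[RegionHit]:
    """Maximal runs of samples deviating past the threshold.

    With ``signed`` (default) only depressions count: deviation < −τ.  With
    ``signed=False`` the absolute deviation is thresholded.  Runs shorter
    than ``min_run`` are discarded; each region reports its deepest sample,
    refined by parabolic interpolation of the deviation over the three
    samples around the minimum.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    dev = profile.deviations
    if signed:
        flag = profile.hits & (dev < -tau)
    else:
        flag = profile.hits & (np.abs(dev) > tau)
    regions: list[RegionHit] = []
    i = 0
    n = len(flag)
    while i < n:
        if not flag[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flag[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            seg = dev[i:j + 1]
            k = i + int(np.argmin(seg) if signed else np.argmax(np.abs(seg)))
            # parabolic sub-sample refinement of the extremum location
            pos = profile.samples[k] + dev[k] * profile.normals[k]
            if 0 < k < n - 1 and profile.hits[k - 1] and profile.hits[k + 1]:
                d0, d1, d2 = dev[k - 1], dev[k], dev[k + 1]
                denom = d0 - 2 * d1 + d2
                if abs(denom) > 1e-12:
                    off = 0.5 * (d0 - d2) / denom
                    off = float(np.clip(off, -1.0, 1.0))
                    base = profile.samples[k] + off * (
                        profile.samples[min(k + 1, n - 1)] - profile.samples[k]
                        if off >= 0 else
                        profile.samples[k] - profile.samples[max(k - 1, 0)])
                    pos = base + dev[k] * profile.normals[k]
            regions.append(RegionHit(x=float(pos[0]), z=float(pos[1]),
                                     y=profile.y_value,
                                     deviation=float(dev[k]),
                                     run_length=j - i + 1))
        i = j + 1
    return regions


def assemble_separation_lines(regions_per_section: list[list[RegionHit]],
                              gate: float = 3.0, min_support: int = 5,
                              depth_ratio: float = 0.6
                              ) -> list[SeparationLine]:
    """Greedy nearest-neighbour linking of region hits across sections.

    Sections are processed in y order; each hit extends the nearest active
    track within ``gate`` mm in the x–z plane (greedy, closest pair first)
    or starts a new track.  A physical groove has near-constant depth, so
    hits whose measured |deviation| falls below ``depth_ratio`` times the
    track's median depth are rejected as unresolved crossings (their
    localization is unreliable); 0 disables the filter.  Tracks supported by
    fewer than ``min_support`` sections are discarded; output lines are
    ordered by y.
    """
    tracks: list[list[RegionHit]] = []
    ordered = sorted(regions_per_section,
                     key=lambda regs: regs[0].y if regs else np.inf)
    for regs in ordered:
        if not regs:
            continue
        pairs = []
        for ti, tr in enumerate(tracks):
            last = tr[-1]
            for ri, r in enumerate(regs):
                d = float(np.hypot(r.x - last.x, r.z - last.z))
                if d <= gate:
                    pairs.append((d, ti, ri))
        pairs.sort()
        used_t: set[int] = set()
        used_r: set[int] = set()
        for d, ti, ri in pairs:
            if ti in used_t or ri in used_r:
                continue
            tracks[ti].append(regs[ri])
            used_t.add(ti)
            used_r.add(ri)
        for ri, r in enumerate(regs):
            if ri not in used_r:
                tracks.append([r])
    lines = []
    lid = 0
    for tr in tracks:
        if depth_ratio > 0 and len(tr) >= 3:
            median_depth = float(np.median([abs(r.deviation) for r in tr]))
            tr = [r for r in tr
                  if abs(r.deviation) >= depth_ratio * median_depth]
        if len(tr) < min_support:
            continue
        tr = sorted(tr, key=lambda r: r.y)
        pts = np.array([[r.x, r.y, r.z] for r in tr])
        devs = np.array([r.deviation for r in tr])
        lines.append(SeparationLine(line_id=lid, points=pts, deviations=devs,
                                    support=len(tr)))
        lid += 1
    return lines


def detect_lines(cloud: PointCloud, tau: float, bin_width: float,
                 n_controls: int = 8, trim_frac: float = 0.3,
                 n_samples: int = 400, window: int = 9,
                 max_range: float = 10.0, gate: float = 3.0,
                 min_support: int = 5, min_run: int = 5,
                 z_floor: float = 0.5, signed: bool = True,
                 profiles: list[DeviationProfile] | None = None
                 ) -> list[SeparationLine]:
    """Full detection chain: slice → ideal fit → deviations → threshold → link.

    Precomputed deviation profiles may be passed in (they are independent of
    τ), which is how threshold sweeps avoid refitting every section.
    """
    if profiles is None:
        profiles = compute_deviation_profiles(
            cloud, bin_width, n_controls=n_controls, trim_frac=trim_frac,
            n_samples=n_samples, window=window, max_range=max_range,
            z_floor=z_floor)
    regions = [detect_feature_regions(p, tau=tau, min_run=min_run, signed=signed)
               for p in profiles]
    return assemble_separation_lines(regions, gate=gate, min_support=min_support)


def compute_deviation_profiles(cloud: PointCloud, bin_width: float,
                               n_controls: int = 8, trim_frac: float = 0.3,
                               n_samples: int = 400, window: int = 9,
                               max_range: float = 10.0, z_floor: float = 0.5
                               ) -> list[DeviationProfile]:
    sections = slice_cross_sections(cloud, bin_width, z_floor=z_floor)
    profiles = []
    for sec in sections:
        try:
            ideal = fit_ideal_section(sec, n_controls=n_controls,
                                      trim_frac=trim_frac)
        except ValueError:
            continue
        profiles.append(deviation_profile(ideal, sec, n_samples=n_samples,
                                          window=window, max_range=max_range))
    if not profiles:
        raise ValueError("no usable sections")
    return profiles


def calibrate_threshold(profiles: list[DeviationProfile],
                        truth_lines: list[np.ndarray],
                        taus: np.ndarray | None = None,
                        miss_penalty: float = 10.0,
                        gate: float = 3.0, min_support: int = 5,
                        min_run: int = 2) -> tuple[float, np.ndarray]:
    """Sweep τ, score each detection against the truth lines, return the best.

    For each τ, detection runs on the precomputed deviation profiles; each
    truth line is matched to the closest detected line (mean point distance
    after arc-length resampling) and unmatched truth lines incur
    ``miss_penalty`` mm.  Returns (τ*, per-τ mean errors); ties resolve to
    the smallest τ.
    """
    if taus is None:
        taus = np.linspace(0.2, 3.0, 15)
    if not truth_lines:
        raise ValueError("truth lines required for calibration")
    errors = np.empty(len(taus))
    any_detection = False
    for k, tau in enumerate(taus):
        regions = [detect_feature_regions(p, tau=float(tau), min_run=min_run)
                   for p in profiles]
        lines = assemble_separation_lines(regions, gate=gate,
                                          min_support=min_support)
        if lines:
            any_detection = True
        per_truth = []
        for truth in truth_lines:
            best = miss_penalty
            for line in lines:
                clipped = _metrics.clip_polyline_to_y_range(
                    truth, line.points[:, 1].min(), line.points[:, 1].max())
                if clipped is None:
                    continue
                mae, _, _ = _metrics.point_errors(line.points, clipped)
                best = min(best, mae)
            per_truth.append(best)
        errors[k] = float(np.mean(per_truth))
    if not any_detection:
        raise ValueError("no detections at any threshold")
    return float(taus[int(np.argmin(errors))]), errors
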