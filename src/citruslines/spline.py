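"""Cubic B-spline curve fitting by LSPIA.

LSPIA (least-squares progressive iterative approximation) fits a cubic
B-spline C(u) = Σ_i P_i N_i^3(u) to ordered data Q_j by repeatedly moving
every control point along the basis-weighted average of the current
residuals r_j = Q_j − C(u_j):

    P_i ← P_i + μ Σ_j N_i^3(u_j) r_j

In matrix form P^{k+1} = (I − μ BᵀB) P^k + μ BᵀQ with collocation matrix
B[j,i] = N_i^3(u_j); the iteration converges to the least-squares fit, and
the step μ = 2/(λ0 + λn) built from the extreme eigenvalues of BᵀB gives
the fastest contraction, with spectral radius ρ = (λ0 − λn)/(λ0 + λn).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BSplineCurve",
    "LSPIAFit",
    "chord_parameterize",
    "clamped_uniform_knots",
    "build_collocation",
    "optimal_step",
    "lspia_fit",
    "evaluate_curve",
]

DEGREE = 3


@dataclass
class BSplineCurve:
    """Clamped cubic B-spline: controls count = len(knots) − 4."""

    knots: np.ndarray
    controls: np.ndarray  # (n+1, d)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.controls = np.asarray(self.controls, dtype=float)
        if np.any(np.diff(self.knots) < 0):
            raise ValueError("knot vector must be non-decreasing")
        if len(self.controls) != len(self.knots) - DEGREE - 1:
            raise ValueError("controls count must equal len(knots) - 4")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[DEGREE]), float(self.knots[-DEGREE - 1])

    def __call__(self, u) -> np.ndarray:
        return evaluate_curve(self, u)

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {"knots": self.knots.tolist(),
                   "controls": self.controls.tolist(), **extra}
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class LSPIAFit:
    curve: BSplineCurve
    data: np.ndarray
    params: np.ndarray
    residuals: np.ndarray          # r_j at the final iterate
    mu: float
    rho: float
    iterations: int
    converged: bool
    residual_norms: np.ndarray = field(default=None)  # ‖r‖ per iteration


def chord_parameterize(Q: np.ndarray) -> np.ndarray:
    """Normalized chord-length parameters: u_0 = 0, u_m = 1, strictly increasing."""
    Q = np.asarray(Q, dtype=float)
    if len(Q) < 2:
        raise ValueError("need at least 2 points")
    chords = np.linalg.norm(np.diff(Q, axis=0), axis=1)
    if np.any(chords == 0):
        raise ValueError("zero chord: repeated consecutive points")
    u = np.concatenate([[0.0], np.cumsum(chords)])
    return u / u[-1]


def clamped_uniform_knots(n_controls: int) -> np.ndarray:
    """Clamped knot vector on [0, 1] with uniformly spaced interior knots."""
    if n_controls < DEGREE + 1:
        raise ValueError("need at least 4 control points for a cubic")
    interior = np.linspace(0.0, 1.0, n_controls - DEGREE + 1)[1:-1]
    return np.concatenate([np.zeros(DEGREE + 1), interior, np.ones(DEGREE + 1)])


def build_collocation(u: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Collocation matrix B[j, i] = N_i^3(u_j); rows sum to 1 on a clamped basis."""
    u = np.asarray(u, dtype=float)
    knots = np.asarray(knots, dtype=float)
    lo, hi = knots[DEGREE], knots[-DEGREE - 1]
    if np.any(u < lo) or np.any(u > hi):
        raise ValueError("parameters outside the knot domain")
    return BSpline.design_matrix(u, knots, DEGREE, extrapolate=False).toarray()


def optimal_step(B: np.ndarray) -> tuple[float, float]:
    """Fastest-convergence step μ = 2/(λ0+λn) and spectral radius ρ of I − μBᵀB."""
    B = np.asarray(B, dtype=float)
    eigvals = np.linalg.eigvalsh(B.T @ B)
    lam_min = float(max(eigvals[0], 0.0))
    lam_max = float(eigvals[-1])
    if lam_max <= 0:
        raise ValueError("empty basis: BᵀB has no positive eigenvalue")
    mu = 2.0 / (lam_max + lam_min)
    rho = (lam_max - lam_min) / (lam_max + lam_min)
    if rho >= 1.0 - 1e-15:
        warnings.warn("collocation matrix is rank-deficient; iteration is not contractive")
    return mu, rho


def lspia_fit(Q: np.ndarray, n_controls: int, tol: float = 1e-8,
              max_iter: int = 500, u: np.ndarray | None = None,
              knots: np.ndarray | None = None) -> LSPIAFit:
    """Fit a cubic B-spline to ordered points by LSPIA.

    Initial control points are taken from Q at uniformly spaced indices;
    iteration stops when the largest control-point displacement max_i‖δ_i‖
    drops below ``tol``.  The converged fit satisfies the normal equations
    BᵀB P = BᵀQ of the direct least-squares problem.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim == 1:
        Q = Q[:, None]
    m1 = len(Q)
    if n_controls > m1:
        raise ValueError("more control points than data points")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if u is None:
        u = chord_parameterize(Q)
    if knots is None:
        knots = clamped_uniform_knots(n_controls)
    B = build_collocation(u, knots)
    mu, rho = optimal_step(B)

    P = Q[np.linspace(0, m1 - 1, n_controls).round().astype(int)].copy()
    norms = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = Q - B @ P
        norms.append(float(np.linalg.norm(r)))
        delta = mu * (B.T @ r)
        P = P + delta
        if float(np.max(np.linalg.norm(delta, axis=1))) < tol:
            converged = True
            break
    r = Q - B @ P
    norms.append(float(np.linalg.norm(r)))
    if not converged:
        warnings.warn("LSPIA did not converge within max_iter")
    curve = BSplineCurve(knots=knots, controls=P)
    return LSPIAFit(curve=curve, data=Q, params=np.asarray(u), residuals=r,
                    mu=mu, rho=rho, iterations=it, converged=converged,
                    residual_norms=np.array(norms))


def evaluate_curve(curve: BSplineCurve, u) -> np.ndarray:
    """Evaluate C(u) = Σ P_i N_i^3(u); rejects out-of-domain parameters."""
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    lo, hi = curve.domain
    if np.any(u_arr < lo - 1e-12) or np.any(u_arr > hi + 1e-12):
        raise ValueError("parameter outside the curve domain")
    u_arr = np.clip(u_arr, lo, hi)
    spl = BSpline(curve.knots, curve.controls, DEGREE, extrapolate=False)
    out = spl(u_arr)
    # right-endpoint is half-open in the basis; patch u = u_max explicitly
    at_end = u_arr >= hi - 1e-15
    if np.any(at_end):
        out[at_end] = curve.controls[-1]
    out = np.nan_to_num(out, nan=0.0)
    return out[0] if np.isscalar(u) and np.ndim(u) == 0 else out
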