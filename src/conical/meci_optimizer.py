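"""Direct MECI optimization on a GP surrogate.

The minimizing step combines two components: one proportional to the
predicted gap along the oriented difference-gradient direction (driving the
two surfaces together), and the average-energy gradient projected onto the
seam space (driving downhill along the seam without breaking degeneracy):

    d = c1 * 2*dE * x_hat + c2 * P grad(omega),   P = I - xx' - yy'.

The branching frame (x_hat, y_hat) comes from the two leading eigenvectors
of the gap-squared Hessian, refreshed periodically, and supplies the seam
projector P; the gap-closing direction x_hat is the oriented unit gradient
of the smooth gap-squared surface, so stepping along ``-d`` reduces both
terms.  No second-order step model is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_backends import Geometry
from .surrogate import (
    DegeneracyConfidence,
    GPSurrogate,
    degeneracy_confidence,
    gradient,
    hessian_delta_E2,
)

__all__ = [
    "BranchingFrame",
    "MECIResult",
    "OptimizerOptions",
    "orthogonalize_gh",
    "branching_frame",
    "seam_projector",
    "direct_step",
    "optimize_meci",
]


class DegenerateRotation(ValueError):
    """g/h orthogonalization undefined (parallel, equal-norm input vectors)."""


class NoConeDetected(ValueError):
    """Gap-squared Hessian has no positive leading curvature."""


@dataclass(frozen=True)
class BranchingFrame:
    """Orthonormal branching-plane basis with its Hessian eigenvalues.

    ``eigenvalues`` are the two leading gap-squared Hessian eigenvalues
    (descending); ``seam_eigenvalue`` is the third-largest, reported for
    seam-dimension diagnostics.
    """

    x_hat: np.ndarray
    y_hat: np.ndarray
    eigenvalues: tuple[float, float]
    seam_eigenvalue: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x_hat, dtype=float)
        y = np.asarray(self.y_hat, dtype=float)
        object.__setattr__(self, "x_hat", x)
        object.__setattr__(self, "y_hat", y)
        for v, name in ((x, "x_hat"), (y, "y_hat")):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError(f"{name} is not unit length")
        if abs(float(x @ y)) > 1e-8:
            raise ValueError("branching vectors are not orthogonal")
        if self.eigenvalues[0] < self.eigenvalues[1]:
            raise ValueError("eigenvalues must be ordered descending")


@dataclass(frozen=True)
class MECIResult:
    geometry: Geometry
    delta_e: float
    omega: float
    iterations: int
    converged: bool
    stall_reason: str  # gradient_norm | noise_floor | max_iter | clamp_stall
    frame: BranchingFrame
    confidence: DegeneracyConfidence
    trace: tuple[tuple[int, float, float, float], ...] = ()  # (it, dE, omega, |d|)


@dataclass(frozen=True)
class OptimizerOptions:
    c1: float = 0.2
    c2: float = 0.9
    step_size: float = 0.1
    max_iter: int = 500
    grad_tol: float = 1e-4
    refresh_every: int = 1
    max_backtracks: int = 20
    max_expansions: int = 12
    # optional box (lo, hi) restricting iterates to the region the surrogate
    # was trained on; candidates outside are rejected by the line searches
    bounds: tuple[np.ndarray, np.ndarray] | None = None


def orthogonalize_gh(
    g_vec: np.ndarray, h_vec: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the (g, h) pair so the outputs are orthogonal, preserving span.

    The mixing angle beta solves ``tan(2 beta) = 2<g,h> / (<g,g> - <h,h>)``;
    already-orthogonal inputs come back unchanged (beta = 0).
    """
    g = np.asarray(g_vec, dtype=float)
    h = np.asarray(h_vec, dtype=float)
    if np.linalg.norm(g) == 0 or np.linalg.norm(h) == 0:
        raise ValueError("orthogonalization needs two nonzero vectors")
    gh = float(g @ h)
    diff = float(g @ g - h @ h)
    if abs(gh) < 1e-15:
        return g.copy(), h.copy()
    scale = float(np.linalg.norm(g) * np.linalg.norm(h))
    if abs(abs(gh) - scale) < 1e-12 * scale and abs(diff) < 1e-12 * scale:
        raise DegenerateRotation(
            "rotation angle undefined for parallel equal-norm vectors"
        )
    beta = 0.5 * np.arctan2(2.0 * gh, diff)
    cos_b, sin_b = np.cos(beta), np.sin(beta)
    return cos_b * g + sin_b * h, -sin_b * g + cos_b * h


def branching_frame(hessian: np.ndarray) -> BranchingFrame:
    """Branching frame from the two leading gap-squared Hessian eigenpairs.

    Eigenvector signs are fixed so the first component above round-off is
    positive, making the frame deterministic up to eigenvalue degeneracy.
    """
    hess = np.asarray(hessian, dtype=float)
    if not np.allclose(hess, hess.T, atol=1e-10 * max(1.0, np.abs(hess).max())):
        raise ValueError("Hessian must be symmetric")
    evals, evecs = np.linalg.eigh(hess)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise NoConeDetected("leading gap-squared curvature is not positive")
    vectors = []
    for k in (0, 1):
        v = evecs[:, k]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
        vectors.append(v)
    seam_eval = float(evals[2]) if evals.size > 2 else 0.0
    return BranchingFrame(
        x_hat=vectors[0],
        y_hat=vectors[1],
        eigenvalues=(float(evals[0]), float(evals[1])),
        seam_eigenvalue=seam_eval,
    )


def seam_projector(frame: BranchingFrame) -> np.ndarray:
    """Projector onto the seam space: ``P = I - xx' - yy'``."""
    x, y = frame.x_hat, frame.y_hat
    return np.eye(x.size) - np.outer(x, x) - np.outer(y, y)


def _gap_direction(
    s: GPSurrogate, geometry: Geometry, frame: BranchingFrame
) -> np.ndarray:
    """Unit vector along the ascending predicted gap.

    The difference gradient itself is ill-conditioned near degeneracy, so
    the direction is taken from the smooth gap-squared surface:
    ``grad(dE) = grad(dE^2) / (2 dE)`` shares its direction with
    ``grad(dE^2) = -4 grad(c0)``.  Where that gradient vanishes (clamped
    plateau) the frame's leading eigenvector is used as a fallback.
    """
    gap2_grad = gradient(s, geometry, "delta_E2")
    norm = float(np.linalg.norm(gap2_grad))
    if norm < 1e-14:
        return frame.x_hat
    return gap2_grad / norm


def direct_step(
    s: GPSurrogate,
    geometry: Geometry,
    frame: BranchingFrame,
    c1: float = 0.2,
    c2: float = 0.9,
) -> np.ndarray:
    """Composite minimizing gradient ``c1*2*dE*x_hat + c2*P grad(omega)``.

    ``x_hat`` here is the oriented unit difference-gradient direction at the
    current geometry (the branching frame supplies only the seam projector).
    When the c0 prediction is clamped the gap term vanishes identically and
    only the projected seam term can make progress.
    """
    delta_e = s.delta_e_at(geometry)
    x_signed = _gap_direction(s, geometry, frame)
    omega_grad = gradient(s, geometry, "omega")
    return c1 * 2.0 * delta_e * x_signed + c2 * (seam_projector(frame) @ omega_grad)


def _line_descend(
    f, x0: np.ndarray, direction: np.ndarray, f0: float, opt: "OptimizerOptions"
):
    """Find the best decrease of ``f`` along ``-direction``.

    Scans a geometric ladder of step lengths around ``step_size`` (halvings
    and doublings) and keeps the minimizer: the learned surfaces carry
    small-scale regression wiggles, so a pure backtracking rule can be
    trapped by a local bump even when larger steps descend.  Returns
    (new point, new value) or None when no step improves on ``f0``.
    """
    best = None
    for k in range(-opt.max_backtracks, opt.max_expansions + 1):
        alpha = opt.step_size * 2.0**k
        cand = x0 - alpha * direction
        val = f(cand)
        if val < f0 - 1e-15 and (best is None or val < best[1]):
            best = (cand, val)
    return best


def optimize_meci(
    s: GPSurrogate,
    start: Geometry,
    options: OptimizerOptions | None = None,
) -> MECIResult:
    """First-order direct MECI search on the surrogate.

    Each iteration applies the two components of the composite gradient in
    sequence, with independent backtracking/expansion line control: the gap
    component descends the smooth gap-squared surface, and the seam
    component descends the average energy along the seam projector.  The
    seam step may not grow the gap beyond the noise-floor bound — on a
    tilted cone the average energy necessarily rises while the gap closes,
    so there is no single scalar merit; each component owns its objective.

    Convergence requires the composite gradient norm below ``grad_tol``
    *and* the splitting to be consistent with degeneracy at the noise
    floor; stalls are labelled clamp_stall / noise_floor / max_iter.
    """
    opt = options or OptimizerOptions()
    geometry = start
    conf = degeneracy_confidence(s, geometry)  # delta_min is geometry-free
    gap_slack = max(conf.delta_E_bound, 1e-9)

    def in_bounds(x: np.ndarray) -> bool:
        if opt.bounds is None:
            return True
        lo, hi = opt.bounds
        return bool(np.all(x >= lo) and np.all(x <= hi))

    def gap2(x: np.ndarray) -> float:
        # raw (unclamped) gap-squared surface: descending -4*c0 keeps a
        # signal inside a clamped plateau and settles at the c0 maximum,
        # the best-resolved degeneracy of the surrogate
        if not in_bounds(x):
            return np.inf
        return -4.0 * s.c0_at(geometry.with_flat(x))

    def omega(x: np.ndarray) -> float:
        if not in_bounds(x):
            return np.inf
        return s.omega_at(geometry.with_flat(x))

    frame = branching_frame(hessian_delta_E2(s, geometry))
    trace: list[tuple[int, float, float, float]] = []
    stall_reason = "max_iter"
    converged = False
    iterations = 0

    for it in range(opt.max_iter):
        iterations = it + 1
        if opt.refresh_every > 0 and it > 0 and it % opt.refresh_every == 0:
            frame = branching_frame(hessian_delta_E2(s, geometry))
        d = direct_step(s, geometry, frame, opt.c1, opt.c2)
        d_norm = float(np.linalg.norm(d))
        gap = s.delta_e_at(geometry)
        trace.append((it, gap, s.omega_at(geometry), d_norm))

        if d_norm < opt.grad_tol:
            # polish: the composite gradient can vanish inside a clamped
            # plateau; settle at the c0 maximum before declaring done
            polish = _line_descend(
                gap2, geometry.flat, _gap_direction(s, geometry, frame),
                gap2(geometry.flat), opt,
            )
            if polish is not None:
                geometry = geometry.with_flat(polish[0])
                continue
            conf = degeneracy_confidence(s, geometry)
            if conf.consistent_with_degeneracy:
                converged = True
                stall_reason = "gradient_norm"
            else:
                stall_reason = "noise_floor"
            break

        moved = False
        flat = geometry.flat

        # gap component: descends the raw gap-squared surface along the
        # oriented difference-gradient direction (unit vector; the step
        # ladder owns the displacement scale)
        gap_dir = _gap_direction(s, geometry, frame)
        if np.linalg.norm(gap_dir) > 0:
            step = _line_descend(gap2, flat, gap_dir, gap2(flat), opt)
            if step is not None:
                flat = step[0]
                moved = True

        # seam component: c2 * P grad(omega) descends omega along the seam,
        # rejected if it grows the gap beyond the noise-floor slack
        here = geometry.with_flat(flat)
        seam_dir = opt.c2 * (seam_projector(frame) @ gradient(s, here, "omega"))
        if np.linalg.norm(seam_dir) > 0:
            gap_here = s.delta_e_at(here)

            def omega_guarded(x: np.ndarray) -> float:
                if s.delta_e_at(geometry.with_flat(x)) > gap_here + gap_slack:
                    return np.inf
                return omega(x)

            step = _line_descend(omega_guarded, flat, seam_dir, omega(flat), opt)
            if step is not None:
                flat = step[0]
                moved = True

        if not moved:
            clamped = s.c0_at(geometry) > 0
            stall_reason = "clamp_stall" if clamped else "noise_floor"
            break
        geometry = geometry.with_flat(flat)

    frame = branching_frame(hessian_delta_E2(s, geometry))
    conf = degeneracy_confidence(s, geometry)
    return MECIResult(
        geometry=geometry,
        delta_e=s.delta_e_at(geometry),
        omega=s.omega_at(geometry),
        iterations=iterations,
        converged=converged,
        stall_reason=stall_reason,
        frame=frame,
        confidence=conf,
        trace=tuple(trace),
    )
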