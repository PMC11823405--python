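"""First-order topography of an optimized conical intersection.

At a (near-)degenerate point the two surfaces are modelled to first order by
``E± = s_x x + s_y y ± sqrt(g²x² + h²y²)`` in the branching plane.  The four
primitive parameters are extracted from the gap-squared Hessian eigenvalues
(``g = sqrt(lambda1/8)``, ``h = sqrt(lambda2/8)``) and the average-energy
gradient projected on the branching vectors (tilts).  Two composite
parameters classify the cone:

* ``P = (s_x/g)**2 + (s_y/h)**2`` — peaked (P < 1) vs sloped (P > 1):
  whether the upper cone has a minimum in the branching plane.  In terms of
  the relative tilt ``sigma = s/d_gh`` (with pitch ``d_gh``), asymmetry
  ``Delta_gh`` and tilt heading ``theta_s`` this is
  ``sigma² (1 - Delta cos 2θ) / (1 - Delta²)``.
* ``B = ((s_x g)**(2/3) + (s_y h)**(2/3)) / (g² - h²)**(2/3)`` —
  single-path (B > 1) vs bifurcating (B < 1): whether the lower surface has
  one or two steepest-descent valleys.  The unit level set of B is the
  astroid of tilt vectors where two valleys merge.

A brute-force angular-scan classifier over the same first-order model acts
as the independent oracle for both thresholds, and branching planes of two
methods are compared by the projected-parallelogram-area overlap r_IJ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meci_optimizer import BranchingFrame, branching_frame
from .model_backends import Geometry
from .surrogate import GPSurrogate, gradient, hessian_delta_E2

__all__ = [
    "ConeTopography",
    "cone_parameters",
    "composite_parameters",
    "classify_numeric",
    "branching_overlap",
    "characterize",
]


@dataclass(frozen=True)
class ConeTopography:
    g_tilde: float
    h_tilde: float
    s_x: float
    s_y: float
    delta_gh: float
    sigma_tilt: float
    theta_s: float
    P: float
    B: float
    peaked: bool
    single_path: bool

    @property
    def labels(self) -> tuple[str, str]:
        return (
            "peaked" if self.peaked else "sloped",
            "single_path" if self.single_path else "bifurcating",
        )


def cone_parameters(s: GPSurrogate, meci: Geometry) -> dict:
    """Primitive cone parameters (g, h, s_x, s_y) and frame at a MECI.

    Tilts are reported as magnitudes; their signed values are kept under
    ``s_x_signed``/``s_y_signed`` for classification use.
    """
    hess = hessian_delta_E2(s, meci)
    frame = branching_frame(hess)
    lam1, lam2 = frame.eigenvalues
    if lam2 <= 0:
        raise ValueError("no two-dimensional cone resolved (second eigenvalue <= 0)")
    omega_grad = gradient(s, meci, "omega")
    sx = float(frame.x_hat @ omega_grad)
    sy = float(frame.y_hat @ omega_grad)
    return {
        "g_tilde": float(np.sqrt(lam1 / 8.0)),
        "h_tilde": float(np.sqrt(lam2 / 8.0)),
        "s_x": abs(sx),
        "s_y": abs(sy),
        "s_x_signed": sx,
        "s_y_signed": sy,
        "frame": frame,
    }


def composite_parameters(
    g_tilde: float, h_tilde: float, s_x: float, s_y: float
) -> dict:
    """Asymmetry, relative tilt, heading and the composite P/B parameters."""
    if g_tilde <= 0 or h_tilde <= 0:
        raise ValueError("cone slopes must be positive")
    g2, h2 = g_tilde**2, h_tilde**2
    delta_gh = (g2 - h2) / (g2 + h2)
    pitch = np.sqrt(0.5 * (g2 + h2))
    tilt = np.hypot(s_x, s_y)
    sigma_tilt = tilt / pitch
    theta_s = float(np.arctan2(s_y, s_x)) if tilt > 0 else 0.0
    p_param = (s_x / g_tilde) ** 2 + (s_y / h_tilde) ** 2
    denom = g2 - h2
    if abs(denom) < 1e-300:
        b_param = 0.0 if tilt == 0 else np.inf
    else:
        b_param = (
            (abs(s_x) * g_tilde) ** (2.0 / 3.0) + (abs(s_y) * h_tilde) ** (2.0 / 3.0)
        ) / abs(denom) ** (2.0 / 3.0)
    return {
        "delta_gh": float(delta_gh),
        "sigma_tilt": float(sigma_tilt),
        "theta_s": theta_s,
        "P": float(p_param),
        "B": float(b_param),
        "peaked": bool(p_param < 1.0),
        "single_path": bool(b_param > 1.0),
    }


def classify_numeric(
    g_tilde: float,
    h_tilde: float,
    s_x: float,
    s_y: float,
    n_grid: int = 3600,
) -> tuple[str, str]:
    """Brute-force classification by angular scan of the first-order model.

    Peaked iff the upper-surface radial slope ``s·u(φ) + sqrt(g²c² + h²s²)``
    is positive for every direction φ; the path count is the number of
    strict local minima of the lower-surface radial slope on the periodic
    grid (plateaus collapse to a single minimum).
    """
    if g_tilde <= 0 or h_tilde <= 0:
        raise ValueError("cone slopes must be positive")
    phi = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
    tilt = s_x * np.cos(phi) + s_y * np.sin(phi)
    cone = np.sqrt(g_tilde**2 * np.cos(phi) ** 2 + h_tilde**2 * np.sin(phi) ** 2)
    peaked = bool(np.min(tilt + cone) > 0.0)

    lower = tilt - cone
    # collapse consecutive equal values so plateaus count once
    keep = np.ones(lower.size, dtype=bool)
    keep[1:] = np.abs(np.diff(lower)) > 1e-15
    seq = lower[keep]
    n = seq.size
    minima = 0
    for i in range(n):
        if seq[i] < seq[(i - 1) % n] and seq[i] < seq[(i + 1) % n]:
            minima += 1
    single_path = minima <= 1
    return (
        "peaked" if peaked else "sloped",
        "single_path" if single_path else "bifurcating",
    )


def branching_overlap(frame_i: BranchingFrame, frame_j: BranchingFrame) -> float:
    """Projected-area overlap of two branching planes.

    The unit vectors of frame I are projected onto the plane of frame J and
    r_IJ is the area of the parallelogram they span: 1 for parallel planes,
    0 for orthogonal ones, symmetric in its arguments.
    """
    if frame_i.x_hat.size != frame_j.x_hat.size:
        raise ValueError("frames live in different ambient dimensions")
    basis_j = np.column_stack([frame_j.x_hat, frame_j.y_hat])
    proj = basis_j @ basis_j.T
    a = proj @ frame_i.x_hat
    b = proj @ frame_i.y_hat
    area2 = float(a @ a) * float(b @ b) - float(a @ b) ** 2
    return float(np.sqrt(max(area2, 0.0)))


def characterize(s: GPSurrogate, meci: Geometry) -> ConeTopography:
    """Full first-order characterization of a surrogate MECI."""
    prim = cone_parameters(s, meci)
    comp = composite_parameters(
        prim["g_tilde"], prim["h_tilde"], prim["s_x"], prim["s_y"]
    )
    return ConeTopography(
        g_tilde=prim["g_tilde"],
        h_tilde=prim["h_tilde"],
        s_x=prim["s_x"],
        s_y=prim["s_y"],
        **comp,
    )
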