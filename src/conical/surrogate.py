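"""Paired GP surrogates for the average energy and splitting coefficient.

A surrogate bundles two single-output GP models trained on the same
featurized geometries: one for the average energy ``omega`` and one for the
0th-order characteristic-polynomial coefficient ``c0`` of the splitting
matrix.  Adiabatic energies are reconstructed through the two-state closed
form ``E± = omega_bar ± sqrt(-c0_bar)`` with positive predictions clamped to
zero gap.  Derivatives are taken by central finite differences on the
composed (descriptor -> GP mean) map, which is smooth by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gpr_core
from .cp_surfaces import decompose, two_state_closed_form
from .descriptors import DescriptorConfig, featurize
from .gpr_core import FitOptions, GPModel
from .model_backends import Geometry, SurfaceSample
from .sampling import SamplingConfig, lhs_displacements

__all__ = [
    "GPSurrogate",
    "EnergyPrediction",
    "DegeneracyConfidence",
    "build_surrogate",
    "predict_energies",
    "gradient",
    "hessian_delta_E2",
    "branching_cut",
    "degeneracy_confidence",
]


@dataclass(frozen=True)
class EnergyPrediction:
    """Surrogate energies and the underlying surface values at one geometry."""

    e_lower: float
    e_upper: float
    delta_e: float
    omega: float
    c0: float
    std_c0: float
    clamped: bool


@dataclass(frozen=True)
class DegeneracyConfidence:
    """Noise-floor diagnostic at a geometry.

    ``delta_min`` is the minimum latent predictive standard deviation of the
    c0 model over its training set; a point is consistent with degeneracy
    when ``-c0_bar <= 2 * delta_min`` (the predicted splitting is within the
    95% confidence band of zero), and the resolvable gap is bounded by
    ``delta_E_bound = 2 * sqrt(2 * delta_min)``.
    """

    delta_min: float
    consistent_with_degeneracy: bool
    delta_E_bound: float


@dataclass
class GPSurrogate:
    omega_model: GPModel
    c0_model: GPModel
    descriptor_config: DescriptorConfig
    center: Geometry
    training_manifest: list[SurfaceSample] = field(default_factory=list)
    fd_step: float = 1e-3
    fd_step_hessian: float = 1e-2

    # -- featurization helpers ------------------------------------------

    def _feature(self, geometry: Geometry) -> np.ndarray:
        return featurize(geometry, self.descriptor_config)

    def omega_at(self, geometry: Geometry) -> float:
        return gpr_core.predict(self.omega_model, self._feature(geometry))[0]

    def c0_at(self, geometry: Geometry) -> float:
        return gpr_core.predict(self.c0_model, self._feature(geometry))[0]

    def delta_e_at(self, geometry: Geometry) -> float:
        """Clamped predicted gap 2*sqrt(-min(c0, 0))."""
        return 2.0 * np.sqrt(max(-self.c0_at(geometry), 0.0))

    # -- serialization ---------------------------------------------------

    def save(self, directory) -> None:
        """Write the bundle: two model JSONs, config, center and manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "omega_model.json").write_text(self.omega_model.to_json())
        (directory / "c0_model.json").write_text(self.c0_model.to_json())
        cfg = {
            "descriptor": self.descriptor_config.__dict__,
            "fd_step": self.fd_step,
            "fd_step_hessian": self.fd_step_hessian,
            "center_elements": list(self.center.elements),
            "center_coords": self.center.coords.tolist(),
        }
        (directory / "config.json").write_text(json.dumps(cfg, indent=1))
        lines = ["id,gap,noise_amplitude,backend_tag"]
        for i, s in enumerate(self.training_manifest):
            lines.append(f"{i},{s.gap:.12g},{s.noise_amplitude:.12g},{s.backend_tag}")
        (directory / "manifest.csv").write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, directory) -> "GPSurrogate":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text())
        return cls(
            omega_model=GPModel.from_json((directory / "omega_model.json").read_text()),
            c0_model=GPModel.from_json((directory / "c0_model.json").read_text()),
            descriptor_config=DescriptorConfig(**cfg["descriptor"]),
            center=Geometry(cfg["center_elements"], np.asarray(cfg["center_coords"])),
            fd_step=cfg["fd_step"],
            fd_step_hessian=cfg["fd_step_hessian"],
        )


class BackendSampleError(RuntimeError):
    """Backend failed while evaluating a training geometry."""


def build_surrogate(
    backend,
    center: Geometry,
    sampling: SamplingConfig,
    descriptor: DescriptorConfig,
    fit_options: FitOptions | None = None,
) -> GPSurrogate:
    """Sample around ``center``, decompose energies, and fit both GP models."""
    fit_options = fit_options or FitOptions()
    geometries = lhs_displacements(center, sampling)
    samples: list[SurfaceSample] = []
    for i, geom in enumerate(geometries):
        try:
            samples.append(
                backend.sample(geom)
                if hasattr(backend, "sample")
                else SurfaceSample(geom, backend.energies(geom))
            )
        except Exception as exc:
            raise BackendSampleError(f"backend failed on training geometry {i}") from exc

    features = np.array([featurize(s.geometry, descriptor) for s in samples])
    points = [decompose(s.energies) for s in samples]
    omega_targets = np.array([p.omega for p in points])
    c0_targets = np.array([p.c0 for p in points])

    omega_model = gpr_core.fit(features, omega_targets, fit_options)
    c0_model = gpr_core.fit(features, c0_targets, fit_options)
    return GPSurrogate(
        omega_model=omega_model,
        c0_model=c0_model,
        descriptor_config=descriptor,
        center=center,
        training_manifest=samples,
    )


def predict_energies(s: GPSurrogate, geometry: Geometry) -> EnergyPrediction:
    """Smooth surrogate energies with clamping of positive c0 predictions."""
    x = s._feature(geometry)
    omega, _ = gpr_core.predict(s.omega_model, x)
    c0, std_c0 = gpr_core.predict(s.c0_model, x, include_noise=False)
    e_lo, e_hi, clamped = two_state_closed_form(omega, c0, clamp=True)
    return EnergyPrediction(
        e_lower=e_lo,
        e_upper=e_hi,
        delta_e=e_hi - e_lo,
        omega=omega,
        c0=c0,
        std_c0=std_c0,
        clamped=clamped,
    )


_SURFACES = {
    "omega": lambda s, g: s.omega_at(g),
    "c0": lambda s, g: s.c0_at(g),
    "delta_E2": lambda s, g: -4.0 * s.c0_at(g),
}


def gradient(
    s: GPSurrogate, geometry: Geometry, which: str = "omega", step: float | None = None
) -> np.ndarray:
    """Central-difference gradient of a learned surface over flat coordinates."""
    try:
        func = _SURFACES[which]
    except KeyError:
        raise ValueError(f"unknown surface {which!r}") from None
    step = s.fd_step if step is None else step
    if step <= 0:
        raise ValueError("finite-difference step must be positive")
    flat = geometry.flat
    grad = np.empty(flat.size)
    for i in range(flat.size):
        plus = flat.copy()
        minus = flat.copy()
        plus[i] += step
        minus[i] -= step
        grad[i] = (
            func(s, geometry.with_flat(plus)) - func(s, geometry.with_flat(minus))
        ) / (2.0 * step)
    return grad


def _rigid_modes(geometry: Geometry) -> np.ndarray | None:
    """Orthonormal rigid translation/rotation directions, or None for models."""
    coords = geometry.coords
    if coords.shape[1] != 3 or coords.shape[0] < 2:
        return None
    if all(e == "X" for e in geometry.elements):
        return None
    n = coords.shape[0]
    modes = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        modes.append(t.reshape(-1))
    centered = coords - coords.mean(axis=0)
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        modes.append(np.cross(centered, e).reshape(-1))
    q, r = np.linalg.qr(np.array(modes).T)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def hessian_delta_E2(
    s: GPSurrogate, geometry: Geometry, step: float | None = None
) -> np.ndarray:
    """Symmetrized central-difference Hessian of the gap-squared surface -4*c0.

    For molecular geometries the rigid translation/rotation directions are
    projected out so their (meaningless) curvature cannot contaminate the
    branching/seam split.
    """
    step = s.fd_step_hessian if step is None else step
    flat = geometry.flat
    dim = flat.size

    def f(x: np.ndarray) -> float:
        return -4.0 * s.c0_at(geometry.with_flat(x))

    f0 = f(flat)
    hess = np.empty((dim, dim))
    for i in range(dim):
        ei = np.zeros(dim)
        ei[i] = step
        hess[i, i] = (f(flat + ei) - 2.0 * f0 + f(flat - ei)) / step**2
        for j in range(i + 1, dim):
            ej = np.zeros(dim)
            ej[j] = step
            hess[i, j] = hess[j, i] = (
                f(flat + ei + ej)
                - f(flat + ei - ej)
                - f(flat - ei + ej)
                + f(flat - ei - ej)
            ) / (4.0 * step**2)
    hess = 0.5 * (hess + hess.T)
    rigid = _rigid_modes(geometry)
    if rigid is not None:
        proj = np.eye(dim) - rigid @ rigid.T
        hess = proj @ hess @ proj
    return hess


def branching_cut(
    s: GPSurrogate,
    meci: Geometry,
    direction: np.ndarray,
    displacements: np.ndarray,
    shift: bool = True,
) -> dict:
    """Predicted energies along a branching-plane direction through a MECI.

    With ``shift`` the c0 predictions are offset by -c0(meci) before the
    closed form, which forces the origin of the cut to be exactly degenerate
    and removes the spurious cusp a small positive c0 prediction would
    otherwise paint near the apex.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    displacements = np.asarray(displacements, dtype=float)
    c0_ref = s.c0_at(meci) if shift else 0.0
    lower, upper, clamped = [], [], []
    for t in displacements:
        g = meci.with_flat(meci.flat + t * direction)
        omega = s.omega_at(g)
        c0 = s.c0_at(g) - c0_ref
        lo, hi, was_clamped = two_state_closed_form(omega, c0, clamp=True)
        lower.append(lo)
        upper.append(hi)
        clamped.append(was_clamped)
    return {
        "displacement": displacements.copy(),
        "e_lower": np.array(lower),
        "e_upper": np.array(upper),
        "clamped": np.array(clamped),
    }


def degeneracy_confidence(s: GPSurrogate, geometry: Geometry) -> DegeneracyConfidence:
    """Noise-floor consistency of the predicted splitting at ``geometry``."""
    delta_min = gpr_core.min_uncertainty(s.c0_model)
    c0 = s.c0_at(geometry)
    return DegeneracyConfidence(
        delta_min=delta_min,
        consistent_with_degeneracy=bool(-c0 <= 2.0 * delta_min),
        delta_E_bound=float(2.0 * np.sqrt(2.0 * delta_min)),
    )
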