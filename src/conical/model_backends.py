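"""Analytic model potentials with known conical intersections.

These backends stand in for an electronic-structure code: they expose the
same ``energies(geometry) -> ascending list`` contract, but their minimum
energy conical intersections (MECIs), branching planes and first-order cone
parameters are known in closed form, which makes them suitable ground truth
for parameter-recovery tests of the surrogate/optimizer pipeline.

Two potentials are provided:

* :class:`ConeModelBackend` — the first-order two-state cone
  ``E± = s_x x + s_y y ± sqrt(g² x² + h² y²)``, optionally augmented with a
  quadratic bowl in the remaining (seam) coordinates so the seam has a
  unique minimum.
* :class:`LVCModelBackend` — a two-state linear vibronic coupling model
  whose adiabatic energies are eigenvalues of a 2x2 diabatic matrix.

A deterministic noise injector emulates methods whose energies carry
reproducible, geometry-dependent irregularities: re-evaluating the same
structure returns identical energies, while energies at distinct structures
scatter with a prescribed standard deviation.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Geometry",
    "ConeModelParams",
    "LVCModelParams",
    "SurfaceSample",
    "ConeModelBackend",
    "LVCModelBackend",
    "NoisyBackend",
    "TableBackend",
    "eval_cone_model",
    "eval_lvc_model",
    "analytic_reference",
    "add_deterministic_noise",
]

_SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class Geometry:
    """A molecular or model-space geometry.

    For molecular use ``coords`` has shape ``(n_atoms, 3)`` in Å.  Model
    backends use abstract coordinates: one pseudo-"atom" row per coordinate
    triple is not required, so ``coords`` may be any finite 2-D array; the
    flattened view is what backends consume.
    """

    elements: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) == 0:
            raise ValueError("geometry needs at least one element")
        if coords.shape[0] != len(self.elements):
            raise ValueError(
                f"{coords.shape[0]} coordinate rows for {len(self.elements)} elements"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    @property
    def flat(self) -> np.ndarray:
        """Flattened coordinate vector (read-only view)."""
        return self.coords.reshape(-1)

    def with_flat(self, x: np.ndarray) -> "Geometry":
        """Return a copy with coordinates replaced by the flat vector ``x``."""
        return Geometry(self.elements, np.asarray(x, float).reshape(self.coords.shape))

    @staticmethod
    def from_flat(x: np.ndarray) -> "Geometry":
        """Wrap an abstract model-coordinate vector as a single-row geometry."""
        x = np.asarray(x, dtype=float).reshape(1, -1)
        return Geometry(("X",), x)


@dataclass(frozen=True)
class ConeModelParams:
    """First-order two-state cone parameters (model units)."""

    g: float
    h: float
    s_x: float = 0.0
    s_y: float = 0.0

    def __post_init__(self) -> None:
        if self.g < 0 or self.h < 0:
            raise ValueError("cone slopes g, h must be non-negative")


@dataclass(frozen=True)
class LVCModelParams:
    """Two-state linear vibronic coupling model.

    Diabatic matrix ``H11 = e1 + kappa1.q + q'Ωq/2``,
    ``H22 = e2 + kappa2.q + q'Ωq/2``, ``H12 = lam.q``.
    """

    dimension: int
    e1: float
    e2: float
    kappa1: np.ndarray
    kappa2: np.ndarray
    omega_diag: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        for name in ("kappa1", "kappa2", "omega_diag", "lam"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (self.dimension,):
                raise ValueError(f"{name} must have length {self.dimension}")
        if np.any(self.omega_diag <= 0):
            raise ValueError("harmonic force constants must be positive")


@dataclass(frozen=True)
class SurfaceSample:
    """A geometry with its (ascending) adiabatic energies and provenance."""

    geometry: Geometry
    energies: tuple[float, ...]
    backend_tag: str = ""
    noise_amplitude: float = 0.0

    def __post_init__(self) -> None:
        energies = tuple(float(e) for e in self.energies)
        object.__setattr__(self, "energies", energies)
        if len(energies) < 2:
            raise ValueError("a surface sample needs at least 2 states")
        if any(b < a for a, b in zip(energies, energies[1:])):
            raise ValueError("energies must be sorted ascending")

    @property
    def gap(self) -> float:
        return self.energies[1] - self.energies[0]


def eval_cone_model(
    params: ConeModelParams,
    point: np.ndarray,
    seam_coords: np.ndarray | None = None,
    seam_curvature: float | None = None,
) -> tuple[float, float]:
    """Evaluate the first-order cone at a branching-plane point.

    ``E± = s_x x + s_y y ± sqrt(g²x² + h²y²)``; if seam coordinates and a
    curvature are given, ``curvature/2 * |seam|²`` is added to both states,
    embedding a seam minimum at the seam-coordinate origin.
    """
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("non-finite branching-plane point")
    tilt = params.s_x * x + params.s_y * y
    half_gap = np.sqrt(params.g**2 * x**2 + params.h**2 * y**2)
    base = tilt
    if seam_coords is not None and seam_curvature is not None:
        z = np.asarray(seam_coords, dtype=float)
        base = base + 0.5 * float(seam_curvature) * float(z @ z)
    return base - half_gap, base + half_gap


def eval_lvc_model(params: LVCModelParams, q: np.ndarray) -> tuple[float, float]:
    """Ascending adiabatic eigenvalues of the 2x2 LVC diabatic matrix."""
    q = np.asarray(q, dtype=float)
    if q.shape != (params.dimension,):
        raise ValueError(f"coordinate vector must have length {params.dimension}")
    harmonic = 0.5 * float(q @ (params.omega_diag * q))
    h11 = params.e1 + float(params.kappa1 @ q) + harmonic
    h22 = params.e2 + float(params.kappa2 @ q) + harmonic
    h12 = float(params.lam @ q)
    mean = 0.5 * (h11 + h22)
    half = np.hypot(0.5 * (h11 - h22), h12)
    return mean - half, mean + half


class ConeModelBackend:
    """Cone-model backend over flat coordinates ``(x, y, z1, ..., zk)``.

    The first two coordinates span the branching plane, all remaining ones
    are seam coordinates carrying the optional quadratic seam term.
    """

    def __init__(
        self,
        params: ConeModelParams,
        dimension: int = 2,
        seam_curvature: float = 0.0,
    ) -> None:
        if dimension < 2:
            raise ValueError("cone model needs at least the two branching coordinates")
        self.params = params
        self.dimension = dimension
        self.seam_curvature = seam_curvature
        self.tag = "cone"

    def energies(self, geometry: Geometry) -> tuple[float, ...]:
        q = geometry.flat
        if q.size != self.dimension:
            raise ValueError(f"expected {self.dimension} coordinates, got {q.size}")
        seam = q[2:] if self.dimension > 2 else None
        curv = self.seam_curvature if self.dimension > 2 else None
        return eval_cone_model(self.params, q[:2], seam, curv)

    def sample(self, geometry: Geometry) -> SurfaceSample:
        return SurfaceSample(geometry, self.energies(geometry), backend_tag=self.tag)


class LVCModelBackend:
    """Linear-vibronic-coupling backend over flat coordinates."""

    def __init__(self, params: LVCModelParams) -> None:
        self.params = params
        self.dimension = params.dimension
        self.tag = "lvc"

    def energies(self, geometry: Geometry) -> tuple[float, ...]:
        return eval_lvc_model(self.params, geometry.flat)

    def sample(self, geometry: Geometry) -> SurfaceSample:
        return SurfaceSample(geometry, self.energies(geometry), backend_tag=self.tag)


@dataclass(frozen=True)
class AnalyticReference:
    """Ground-truth MECI data for a model backend."""

    meci_geometry: Geometry
    x_hat: np.ndarray
    y_hat: np.ndarray
    g_tilde: float
    h_tilde: float
    s_x: float
    s_y: float


def analytic_reference(backend) -> AnalyticReference:
    """Closed-form MECI, branching frame and cone parameters of a model.

    For the cone backend these follow directly from the construction.  For a
    two-state LVC model with an intersection at the origin (``e1 == e2``) the
    difference-gradient and coupling vectors at ``q = 0`` are
    ``(kappa1 - kappa2)/2`` and ``lam``; they are orthogonalized by rotation
    before norms are reported.
    """
    if isinstance(backend, ConeModelBackend):
        dim = backend.dimension
        p = backend.params
        x_hat = np.zeros(dim)
        y_hat = np.zeros(dim)
        x_hat[0] = 1.0
        y_hat[1] = 1.0
        return AnalyticReference(
            meci_geometry=Geometry.from_flat(np.zeros(dim)),
            x_hat=x_hat,
            y_hat=y_hat,
            g_tilde=p.g,
            h_tilde=p.h,
            s_x=p.s_x,
            s_y=p.s_y,
        )
    if isinstance(backend, LVCModelBackend):
        p = backend.params
        if abs(p.e1 - p.e2) > 1e-12:
            raise ValueError(
                "analytic reference implemented only for LVC models degenerate at q=0"
            )
        g_vec = 0.5 * (p.kappa1 - p.kappa2)
        h_vec = p.lam.copy()
        if np.linalg.norm(g_vec) == 0 or np.linalg.norm(h_vec) == 0:
            raise ValueError("LVC model has no first-order cone at the origin")
        # local import avoids a cycle: meci_optimizer does not import backends
        from .meci_optimizer import orthogonalize_gh

        g_t, h_t = orthogonalize_gh(g_vec, h_vec)
        if np.linalg.norm(g_t) < np.linalg.norm(h_t):
            g_t, h_t = h_t, g_t
        x_hat = g_t / np.linalg.norm(g_t)
        y_hat = h_t / np.linalg.norm(h_t)
        mean_grad = 0.5 * (p.kappa1 + p.kappa2)
        return AnalyticReference(
            meci_geometry=Geometry.from_flat(np.zeros(p.dimension)),
            x_hat=x_hat,
            y_hat=y_hat,
            g_tilde=float(np.linalg.norm(g_t)),
            h_tilde=float(np.linalg.norm(h_t)),
            s_x=float(mean_grad @ x_hat),
            s_y=float(mean_grad @ y_hat),
        )
    raise TypeError(f"no analytic reference for backend {type(backend).__name__}")


def _hash_uniform(coords: np.ndarray, state: int, key: int) -> float:
    """Reproducible uniform variate in [-1, 1) keyed on (geometry, state, key).

    Coordinates are rounded to 10 decimals so that round-off-level jitter in
    a geometry does not change its noise draw.
    """
    rounded = np.round(np.asarray(coords, dtype=float), 10) + 0.0  # kill -0.0
    payload = rounded.tobytes() + struct.pack("<qq", int(state), int(key))
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    u = struct.unpack("<Q", digest)[0] / 2.0**64  # [0, 1)
    return 2.0 * u - 1.0


def add_deterministic_noise(
    sample: SurfaceSample, amplitude: float, key: int = 0
) -> SurfaceSample:
    """Perturb each energy by a reproducible function of (geometry, state, key).

    The perturbations are zero-mean uniform variates scaled so that their
    standard deviation across distinct geometries equals ``amplitude``.
    Re-evaluating the same geometry yields identical energies — a delta
    distribution, not a shrinking-with-averaging error.  Energies are
    re-sorted after perturbation so the ascending invariant survives near
    degeneracies.
    """
    if amplitude < 0:
        raise ValueError("noise amplitude must be non-negative")
    if amplitude == 0:
        return sample
    flat = sample.geometry.flat
    noisy = [
        e + amplitude * _SQRT3 * _hash_uniform(flat, i, key)
        for i, e in enumerate(sample.energies)
    ]
    return replace(
        sample,
        energies=tuple(sorted(noisy)),
        noise_amplitude=float(amplitude),
    )


class NoisyBackend:
    """Wrap a backend with the deterministic noise injector."""

    def __init__(self, inner, amplitude: float, key: int = 0) -> None:
        if amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")
        self.inner = inner
        self.amplitude = float(amplitude)
        self.key = int(key)
        self.tag = f"{getattr(inner, 'tag', 'backend')}+noise"

    @property
    def dimension(self) -> int:
        return self.inner.dimension

    def energies(self, geometry: Geometry) -> tuple[float, ...]:
        clean = SurfaceSample(geometry, self.inner.energies(geometry))
        return add_deterministic_noise(clean, self.amplitude, self.key).energies

    def sample(self, geometry: Geometry) -> SurfaceSample:
        return SurfaceSample(
            geometry,
            self.energies(geometry),
            backend_tag=self.tag,
            noise_amplitude=self.amplitude,
        )


class TableBackend:
    """Backend serving precomputed energies keyed by geometry identity.

    Used for externally computed (e.g. ab initio) energy tables: geometries
    are matched by their rounded coordinates.
    """

    def __init__(self, tag: str = "table") -> None:
        self._table: dict[bytes, tuple[float, ...]] = {}
        self.tag = tag

    @staticmethod
    def _key(geometry: Geometry) -> bytes:
        return np.round(geometry.flat, 8).tobytes()

    def add(self, geometry: Geometry, energies) -> None:
        energies = tuple(float(e) for e in energies)
        if sorted(energies) != list(energies):
            raise ValueError("table energies must be ascending")
        self._table[self._key(geometry)] = energies

    def energies(self, geometry: Geometry) -> tuple[float, ...]:
        try:
            return self._table[self._key(geometry)]
        except KeyError:
            raise KeyError("geometry not present in the energy table") from None

    def sample(self, geometry: Geometry) -> SurfaceSample:
        return SurfaceSample(geometry, self.energies(geometry), backend_tag=self.tag)
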