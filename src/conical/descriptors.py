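"""Invariant geometry featurization for GPR inputs.

Three descriptor kinds share one contract — a fixed-length vector that is
invariant under rigid translation, rigid rotation and permutation of
identical nuclei, and continuous in the coordinates:

``soap_power_spectrum``
    A self-contained SOAP power spectrum: the Gaussian-smeared atomic
    neighbour density of each species is expanded around every atomic center
    in an orthonormalized radial basis times spherical harmonics, and the
    rotationally invariant power spectrum ``p_{nn'l} = sum_m c_nlm c*_n'lm``
    is accumulated per species pair.  Centers are either averaged (default,
    fully permutation invariant) or concatenated per atom.
``sorted_inverse_distance``
    Inverse pairwise distances grouped by unordered species pair and sorted
    within each group — a cheap fallback with the same invariances.
``raw_model_coordinates``
    The identity map on flattened coordinates, used with abstract model
    backends so that descriptor choice cannot confound surrogate tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations_with_replacement

import numpy as np
from scipy.special import sph_harm_y, spherical_in

from .model_backends import Geometry

__all__ = ["DescriptorConfig", "featurize", "descriptor_distance"]

_KINDS = ("soap_power_spectrum", "sorted_inverse_distance", "raw_model_coordinates")


@dataclass(frozen=True)
class DescriptorConfig:
    """Descriptor settings.

    ``species`` must cover every element that can appear in featurized
    geometries (SOAP kind); ``center_mode`` selects averaging over atomic
    centers (``"average"``) or per-atom concatenation (``"concatenate"``).
    """

    kind: str = "soap_power_spectrum"
    cutoff: float = 5.0
    n_radial: int = 8
    l_angular: int = 6
    gaussian_width: float = 0.5
    species: tuple[str, ...] = ()
    center_mode: str = "average"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.kind == "soap_power_spectrum" and (
            self.n_radial < 1 or self.l_angular < 1
        ):
            raise ValueError("SOAP needs n_radial >= 1 and l_angular >= 1")
        if self.center_mode not in ("average", "concatenate"):
            raise ValueError("center_mode must be 'average' or 'concatenate'")
        object.__setattr__(self, "species", tuple(sorted(set(self.species))))


def featurize(geometry: Geometry, config: DescriptorConfig) -> np.ndarray:
    """Map a geometry to its feature vector under ``config``."""
    if len(geometry.elements) == 0:
        raise ValueError("empty geometry")
    if config.kind == "raw_model_coordinates":
        return geometry.flat.copy()
    if config.kind == "sorted_inverse_distance":
        return _sorted_inverse_distance(geometry, config)
    return _soap_power_spectrum(geometry, config)


def descriptor_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two feature vectors of equal length."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"feature length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


# --- sorted inverse distances -------------------------------------------------


def _species_pairs(species: tuple[str, ...]) -> list[tuple[str, str]]:
    return list(combinations_with_replacement(sorted(species), 2))


def _sorted_inverse_distance(geometry: Geometry, config: DescriptorConfig) -> np.ndarray:
    elements = geometry.elements
    species = config.species or tuple(sorted(set(elements)))
    unknown = set(elements) - set(species)
    if unknown:
        raise ValueError(f"species not declared in config: {sorted(unknown)}")
    counts = {s: elements.count(s) for s in species}
    blocks: list[np.ndarray] = []
    coords = geometry.coords
    for s1, s2 in _species_pairs(tuple(species)):
        if s1 == s2:
            n_pairs = counts[s1] * (counts[s1] - 1) // 2
        else:
            n_pairs = counts[s1] * counts[s2]
        vals = []
        for i in range(len(elements)):
            for j in range(i + 1, len(elements)):
                pair = tuple(sorted((elements[i], elements[j])))
                if pair == (s1, s2):
                    vals.append(1.0 / np.linalg.norm(coords[i] - coords[j]))
        block = np.zeros(n_pairs)
        block[: len(vals)] = np.sort(vals)[::-1]
        blocks.append(block)
    return np.concatenate(blocks) if blocks else np.zeros(0)


# --- SOAP power spectrum ------------------------------------------------------


@lru_cache(maxsize=32)
def _radial_basis(n_radial: int, cutoff: float, n_quad: int = 64):
    """Orthonormalized Gaussian radial basis evaluated on a GL quadrature grid.

    Returns (r nodes, quadrature weights incl. r^2, basis values (n, n_quad)).
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    r = 0.5 * cutoff * (nodes + 1.0)
    w = 0.5 * cutoff * weights * r**2
    centers = np.linspace(0.0, cutoff, n_radial)
    width = cutoff / n_radial
    phi = np.exp(-0.5 * ((r[None, :] - centers[:, None]) / width) ** 2)
    overlap = (phi * w[None, :]) @ phi.T
    evals, evecs = np.linalg.eigh(overlap)
    inv_sqrt = evecs @ np.diag(evals**-0.5) @ evecs.T  # Löwdin orthonormalization
    return r, w, inv_sqrt @ phi


def _soap_center_coefficients(
    rel: np.ndarray, config: DescriptorConfig
) -> np.ndarray:
    """Expansion coefficients c[n, l, m] for neighbours at relative positions."""
    n_rad, l_max = config.n_radial, config.l_angular
    sigma2 = config.gaussian_width**2
    r_grid, w_grid, basis = _radial_basis(n_rad, config.cutoff)
    coeff = np.zeros((n_rad, l_max + 1, 2 * l_max + 1), dtype=complex)
    for pos in rel:
        dist = float(np.linalg.norm(pos))
        if dist >= config.cutoff:
            continue
        fcut = 0.5 * (1.0 + np.cos(np.pi * dist / config.cutoff))
        if dist < 1e-12:
            # neighbour on the center: only l = 0 survives
            radial = np.exp(-0.5 * r_grid**2 / sigma2)
            integral = (basis * w_grid[None, :]) @ radial
            coeff[:, 0, 0] += fcut * 4.0 * np.pi * integral * sph_harm_y(0, 0, 0.0, 0.0)
            continue
        theta = float(np.arccos(np.clip(pos[2] / dist, -1.0, 1.0)))
        phi_ang = float(np.arctan2(pos[1], pos[0]))
        gauss = np.exp(-0.5 * (r_grid**2 + dist**2) / sigma2)
        for l in range(l_max + 1):
            bessel = spherical_in(l, r_grid * dist / sigma2)
            integral = (basis * w_grid[None, :]) @ (gauss * bessel)
            for m in range(-l, l + 1):
                ylm = sph_harm_y(l, m, theta, phi_ang)
                coeff[:, l, m + l_max] += fcut * 4.0 * np.pi * np.conj(ylm) * integral
    return coeff


def _soap_power_spectrum(geometry: Geometry, config: DescriptorConfig) -> np.ndarray:
    elements = geometry.elements
    species = config.species or tuple(sorted(set(elements)))
    unknown = set(elements) - set(species)
    if unknown:
        raise ValueError(f"species not declared in config: {sorted(unknown)}")
    species = tuple(sorted(species))
    coords = geometry.coords
    n_rad, l_max = config.n_radial, config.l_angular

    per_center: list[np.ndarray] = []
    for i in range(len(elements)):
        # coefficients per species for this center
        c_by_species = {}
        for s in species:
            idx = [j for j, e in enumerate(elements) if e == s]
            rel = coords[idx] - coords[i]
            c_by_species[s] = _soap_center_coefficients(rel, config)
        blocks = []
        for s1, s2 in _species_pairs(species):
            c1, c2 = c_by_species[s1], c_by_species[s2]
            for l in range(l_max + 1):
                # p[n, n'] = sum_m c1[n,l,m] conj(c2[n',l,m]); real for real density
                p = np.real(
                    np.einsum("nm,pm->np", c1[:, l, :], np.conj(c2[:, l, :]))
                ) * np.pi * np.sqrt(8.0 / (2 * l + 1))
                if s1 == s2:
                    iu = np.triu_indices(n_rad)
                    blocks.append(p[iu])
                else:
                    blocks.append(p.reshape(-1))
        per_center.append(np.concatenate(blocks))
    stacked = np.stack(per_center)
    if config.center_mode == "average":
        return stacked.mean(axis=0)
    return stacked.reshape(-1)
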