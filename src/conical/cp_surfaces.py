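"""Average-energy / characteristic-polynomial decomposition.

Adiabatic energies ``E_1 <= ... <= E_n`` are rewritten as the average energy
``omega = mean(E)`` plus the eigenvalues of the traceless splitting matrix
``Z = diag(E_i - omega)``.  The monic characteristic polynomial of ``Z``,

    p(t) = t**n + a_{n-1} t**(n-1) + ... + a_1 t + a_0,

has smooth coefficient surfaces even where the adiabatic energies cross,
which is what makes them learnable; the energies are recovered as
eigenvalues of the Frobenius companion matrix shifted by ``omega``.  For two
states only ``omega`` and the 0th-order coefficient ``c0 = -(E2-E1)²/4``
survive, and the closed form is ``E± = omega ± sqrt(-c0)``.

Coefficients are stored lowest order first.  Because ``Z`` is traceless the
order-(n-1) coefficient is identically zero; it is implied rather than
stored, so a two-state point carries the single value ``c0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CPSurfacePoint",
    "NonPhysicalCoefficients",
    "decompose",
    "companion_reconstruct",
    "two_state_closed_form",
]


class NonPhysicalCoefficients(ValueError):
    """Coefficient set incompatible with real adiabatic energies."""


@dataclass(frozen=True)
class CPSurfacePoint:
    """Average energy and CP coefficients (orders 0..n-2) at one point.

    The order-(n-1) coefficient is zero by tracelessness and is implied.
    """

    omega: float
    coeffs: tuple[float, ...]
    n_states: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if len(self.coeffs) != self.n_states - 1:
            raise ValueError("expected one coefficient per order 0..n-2")

    @property
    def c0(self) -> float:
        return self.coeffs[0]


def decompose(energies) -> CPSurfacePoint:
    """Split energies into the average energy and CP coefficients of Z."""
    e = np.asarray(energies, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("need at least 2 energies")
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite energies")
    omega = float(e.mean())
    roots = e - omega
    # np.poly returns monic coefficients highest order first; drop the
    # leading 1 and the (round-off-only) trace coefficient of order n-1
    monic = np.poly(roots)
    coeffs = monic[::-1][:-2]
    return CPSurfacePoint(omega=omega, coeffs=tuple(coeffs), n_states=e.size)


def companion_reconstruct(
    point: CPSurfacePoint, imag_tol: float = 1e-5
) -> tuple[float, ...]:
    """Adiabatic energies from CP coefficients via the companion matrix.

    ``imag_tol`` is relative to the energy scale of the roots; residual
    imaginary parts below it are discarded, larger ones raise
    :class:`NonPhysicalCoefficients`.  The default accommodates the
    eps**(1/m) round-off splitting of an m-fold degenerate root — exact
    degeneracies must reconstruct, not raise.
    """
    n = point.n_states
    comp = np.zeros((n, n))
    comp[1:, :-1] = np.eye(n - 1)
    comp[:-1, -1] = -np.asarray(point.coeffs)  # order n-1 coefficient is 0
    roots = np.linalg.eigvals(comp)
    scale = max(np.max(np.abs(roots)), 1.0)
    if np.max(np.abs(roots.imag)) > imag_tol * scale:
        raise NonPhysicalCoefficients(
            "companion matrix has complex eigenvalues beyond tolerance: "
            f"max |Im| = {np.max(np.abs(roots.imag)):.3e}"
        )
    vals = np.sort(roots.real) + point.omega
    return tuple(float(v) for v in vals)


def two_state_closed_form(
    omega: float, c0: float, clamp: bool = False
) -> tuple[float, float, bool]:
    """Two-state energies ``omega ± sqrt(-c0)``.

    A regressed c0 surface may stray positive near a degeneracy even though
    the exact quantity is ``-(ΔE)²/4 <= 0``.  With ``clamp`` set, positive
    values are treated as zero gap and flagged; without it they raise.
    """
    clamped = False
    if c0 > 0:
        if not clamp:
            raise NonPhysicalCoefficients(
                f"positive 0th-order coefficient {c0:.3e} implies complex energies"
            )
        c0 = 0.0
        clamped = True
    half_gap = float(np.sqrt(-c0))
    return omega - half_gap, omega + half_gap, clamped
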