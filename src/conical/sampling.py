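"""Training-set generation by atom-centered Cartesian Latin hypercube sampling.

Each Cartesian coordinate of the center geometry is displaced within
``[-half_width, +half_width]`` such that for every coordinate independently
the ``n_samples`` draws are stratified: exactly one sample falls in each of
the ``n_samples`` equal-width bins.  The pairing of per-coordinate strata is
uniformly random within the seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_backends import Geometry, SurfaceSample

__all__ = ["SamplingConfig", "lhs_displacements", "pick_start_geometry"]


@dataclass(frozen=True)
class SamplingConfig:
    """Latin hypercube settings; ``half_width`` is scalar or per-coordinate."""

    n_samples: int = 200
    half_width: float | np.ndarray = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        hw = np.asarray(self.half_width, dtype=float)
        if np.any(hw < 0):
            raise ValueError("half_width must be non-negative")


def lhs_displacements(center: Geometry, config: SamplingConfig) -> list[Geometry]:
    """Latin-hypercube displaced copies of ``center``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    flat = center.flat
    dim = flat.size
    hw = np.broadcast_to(np.asarray(config.half_width, dtype=float), (dim,))
    # one stratified column per coordinate: bin permutation + in-bin jitter
    unit = np.empty((n, dim))
    for d in range(dim):
        perm = rng.permutation(n)
        unit[:, d] = (perm + rng.uniform(size=n)) / n  # in (0, 1)
    displacements = (2.0 * unit - 1.0) * hw[None, :]
    return [center.with_flat(flat + disp) for disp in displacements]


def pick_start_geometry(samples: list[SurfaceSample]) -> int:
    """Index of the training sample with the largest E2 - E1 gap.

    Ties break to the lowest index, so the choice is deterministic.
    """
    if not samples:
        raise ValueError("empty sample list")
    gaps = [s.energies[1] - s.energies[0] for s in samples]
    return int(np.argmax(gaps))
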