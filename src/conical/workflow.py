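"""Ensemble protocol, file I/O and report assembly.

Because Latin-hypercube training sets make the learned surrogate (and thus
the optimized MECI and its topography) mildly training-set dependent, the
headline protocol builds an ensemble of surrogates — each from a fresh LHS
draw around the same center — optimizes a MECI on every one, and reports the
arithmetic mean ± standard deviation of every scalar parameter together
with the learned kernel hyperparameters of both surfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import DescriptorConfig
from .gpr_core import FitOptions
from .meci_optimizer import OptimizerOptions, optimize_meci
from .model_backends import Geometry
from .sampling import SamplingConfig, pick_start_geometry
from .surrogate import build_surrogate
from .topography import branching_overlap, characterize

__all__ = [
    "EV_PER_HARTREE",
    "EnsembleReport",
    "RefinementStage",
    "refine_meci",
    "run_ensemble",
    "read_xyz",
    "write_xyz",
    "read_energy_table",
]

EV_PER_HARTREE = 27.211386245988

# scalar record keys aggregated in the ensemble summary (theta_s deliberately
# excluded: a circular quantity has no meaningful linear mean)
_SUMMARY_KEYS = (
    "delta_e",
    "omega",
    "g_tilde",
    "h_tilde",
    "s_x",
    "s_y",
    "delta_gh",
    "sigma_tilt",
    "P",
    "B",
    "r_ref",
    "omega_variance",
    "omega_length_scale",
    "omega_noise",
    "c0_variance",
    "c0_length_scale",
    "c0_noise",
)


@dataclass
class EnsembleReport:
    records: list[dict]
    failures: list[dict]
    n_surrogates: int

    @property
    def summary(self) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        for key in _SUMMARY_KEYS:
            vals = np.array(
                [r[key] for r in self.records if r.get(key) is not None], dtype=float
            )
            if vals.size:
                out[key] = (float(vals.mean()), float(vals.std()))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_surrogates": self.n_surrogates,
                "records": self.records,
                "failures": self.failures,
                "summary": {k: list(v) for k, v in self.summary.items()},
            },
            indent=1,
        )


def run_ensemble(
    backend,
    center: Geometry,
    sampling: SamplingConfig,
    descriptor: DescriptorConfig,
    n_surrogates: int,
    base_seed: int = 0,
    fit_options: FitOptions | None = None,
    optimizer_options: OptimizerOptions | None = None,
    reference_frame=None,
) -> EnsembleReport:
    """Build/optimize/characterize ``n_surrogates`` surrogates.

    Surrogate ``i`` uses seed ``base_seed + i`` for both its LHS draw and
    its MLE restarts; each optimization starts from the largest-gap geometry
    of its own training set.  Individual failures are recorded and skipped
    rather than aborting the ensemble.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    records: list[dict] = []
    failures: list[dict] = []
    for i in range(n_surrogates):
        seed = base_seed + i
        try:
            records.append(
                _run_single(
                    backend,
                    center,
                    sampling,
                    descriptor,
                    seed,
                    fit_options,
                    optimizer_options,
                    reference_frame,
                )
            )
        except Exception as exc:
            failures.append({"seed": seed, "error": f"{type(exc).__name__}: {exc}"})
    return EnsembleReport(records=records, failures=failures, n_surrogates=n_surrogates)


def _run_single(
    backend,
    center,
    sampling,
    descriptor,
    seed,
    fit_options,
    optimizer_options,
    reference_frame,
) -> dict:
    samp = SamplingConfig(
        n_samples=sampling.n_samples, half_width=sampling.half_width, seed=seed
    )
    base_fit = fit_options or FitOptions()
    fit = FitOptions(
        restarts=base_fit.restarts,
        seed=seed,
        variance_bounds=base_fit.variance_bounds,
        length_scale_bounds=base_fit.length_scale_bounds,
        noise_bounds=base_fit.noise_bounds,
        fix_noise=base_fit.fix_noise,
    )
    surr = build_surrogate(backend, center, samp, descriptor, fit)
    start_idx = pick_start_geometry(surr.training_manifest)
    start = surr.training_manifest[start_idx].geometry
    opt = optimizer_options or OptimizerOptions()
    if opt.bounds is None:
        # keep iterates inside the sampled region (plus a small margin):
        # the static surrogate is meaningless beyond its training box
        hw = np.broadcast_to(
            np.asarray(samp.half_width, dtype=float), center.flat.shape
        )
        opt = replace(opt, bounds=(center.flat - 1.2 * hw, center.flat + 1.2 * hw))
    result = optimize_meci(surr, start, opt)
    topo = characterize(surr, result.geometry)
    record = {
        "seed": seed,
        "start_index": start_idx,
        "iterations": result.iterations,
        "converged": result.converged,
        "stall_reason": result.stall_reason,
        "delta_e": result.delta_e,
        "omega": result.omega,
        "meci_coords": result.geometry.flat.tolist(),
        "delta_min": result.confidence.delta_min,
        "delta_E_bound": result.confidence.delta_E_bound,
        "consistent_with_degeneracy": result.confidence.consistent_with_degeneracy,
        "g_tilde": topo.g_tilde,
        "h_tilde": topo.h_tilde,
        "s_x": topo.s_x,
        "s_y": topo.s_y,
        "delta_gh": topo.delta_gh,
        "sigma_tilt": topo.sigma_tilt,
        "theta_s": topo.theta_s,
        "P": topo.P,
        "B": topo.B,
        "labels": list(topo.labels),
        "omega_variance": surr.omega_model.params.variance,
        "omega_length_scale": surr.omega_model.params.length_scale,
        "omega_noise": surr.omega_model.params.noise,
        "omega_bound_hits": list(surr.omega_model.bound_hits),
        "c0_variance": surr.c0_model.params.variance,
        "c0_length_scale": surr.c0_model.params.length_scale,
        "c0_noise": surr.c0_model.params.noise,
        "c0_bound_hits": list(surr.c0_model.bound_hits),
        "r_ref": (
            branching_overlap(result.frame, reference_frame)
            if reference_frame is not None
            else None
        ),
    }
    return record


# --- staged refinement --------------------------------------------------------


@dataclass(frozen=True)
class RefinementStage:
    """One build-and-optimize pass: sampling box and optimizer step scale."""

    half_width: float
    n_samples: int = 160
    step_size: float | None = None  # default half_width / 5
    grad_tol: float = 1e-9
    max_iter: int = 300


def refine_meci(
    backend,
    start: Geometry,
    descriptor: DescriptorConfig,
    stages: tuple[RefinementStage, ...],
    base_seed: int = 0,
    fit_options: FitOptions | None = None,
):
    """Iteratively re-center the sampling box on the current best MECI.

    A single static surrogate leaves the optimized MECI limited by the GP
    error over its (wide) box; re-sampling tightly around the coarse result
    and re-optimizing — the "start from geometries close to the MECI"
    protocol — sharpens the recovery by orders of magnitude.  Returns the
    final (surrogate, MECIResult) pair.
    """
    if not stages:
        raise ValueError("need at least one refinement stage")
    base_fit = fit_options or FitOptions()
    geometry = start
    surr = result = None
    for i, stage in enumerate(stages):
        center = geometry
        samp = SamplingConfig(
            n_samples=stage.n_samples,
            half_width=stage.half_width,
            seed=base_seed + 1009 * i,
        )
        fit = replace(base_fit, seed=base_seed + 1009 * i)
        surr = build_surrogate(backend, center, samp, descriptor, fit)
        hw = np.broadcast_to(
            np.asarray(stage.half_width, dtype=float), center.flat.shape
        )
        opt = OptimizerOptions(
            step_size=stage.step_size or stage.half_width / 5.0,
            grad_tol=stage.grad_tol,
            max_iter=stage.max_iter,
            bounds=(center.flat - 1.2 * hw, center.flat + 1.2 * hw),
        )
        result = optimize_meci(surr, geometry, opt)
        geometry = result.geometry
    return surr, result


# --- XYZ I/O ------------------------------------------------------------------


class XYZParseError(ValueError):
    pass


def read_xyz(path) -> list[Geometry]:
    """Read single- or multi-frame XYZ."""
    lines = Path(path).read_text().splitlines()
    geometries: list[Geometry] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(f"line {i + 1}: expected atom count") from None
        if i + 1 + n_atoms >= len(lines) + 1 and n_atoms > 0:
            raise XYZParseError(f"line {i + 1}: truncated frame")
        elements = []
        coords = []
        for k in range(n_atoms):
            ln = i + 2 + k
            if ln >= len(lines):
                raise XYZParseError(f"line {ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {ln + 1}: expected 'element x y z'")
            elements.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:4]])
            except ValueError:
                raise XYZParseError(f"line {ln + 1}: malformed coordinate") from None
        geometries.append(Geometry(elements, np.array(coords)))
        i += 2 + n_atoms
    return geometries


def write_xyz(geometries, path, comments=None) -> None:
    """Write geometries as multi-frame XYZ with 10-decimal coordinates."""
    if isinstance(geometries, Geometry):
        geometries = [geometries]
    out = []
    for k, geom in enumerate(geometries):
        comment = comments[k] if comments else f"frame {k}"
        out.append(str(len(geom.elements)))
        out.append(str(comment))
        for el, row in zip(geom.elements, geom.coords):
            out.append(f"{el} {row[0]:.10f} {row[1]:.10f} {row[2] if row.size > 2 else 0.0:.10f}")
    Path(path).write_text("\n".join(out) + "\n")


# --- energy tables ------------------------------------------------------------

_UNIT_FACTORS_TO_EV = {"hartree": EV_PER_HARTREE, "ev": 1.0}


def read_energy_table(path) -> dict[str, tuple[float, ...]]:
    """Read a per-geometry energy table (CSV or JSON) into eV.

    CSV needs a leading ``# units: <hartree|ev>`` line and a header
    ``id,E1,E2[,...]``; JSON needs ``{"units": ..., "energies": {id: [...]}}``.
    Rows must be ascending and ids unique.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        units = doc.get("units")
        table = {str(k): tuple(map(float, v)) for k, v in doc["energies"].items()}
    else:
        units = None
        for ln in path.read_text().splitlines():
            if not ln.startswith("#"):
                break
            if "units" in ln.lower():
                units = ln.split(":", 1)[1].strip().lower()
        df = pd.read_csv(path, comment="#")
        if "id" not in df.columns:
            raise ValueError("energy table needs an 'id' column")
        if df["id"].duplicated().any():
            raise ValueError("duplicate geometry ids in energy table")
        e_cols = [c for c in df.columns if c != "id"]
        table = {
            str(row["id"]): tuple(float(row[c]) for c in e_cols)
            for _, row in df.iterrows()
        }
    if units is None:
        raise ValueError("energy table must declare units ('# units: hartree|ev')")
    units = str(units).lower()
    if units not in _UNIT_FACTORS_TO_EV:
        raise ValueError(f"unknown energy unit {units!r}")
    factor = _UNIT_FACTORS_TO_EV[units]
    arities = {len(v) for v in table.values()}
    if len(arities) > 1:
        raise ValueError("inconsistent number of states across rows")
    out = {}
    for key, energies in table.items():
        if list(energies) != sorted(energies):
            raise ValueError(f"energies for id {key!r} are not ascending")
        out[key] = tuple(e * factor for e in energies)
    return out
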