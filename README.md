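# conical

Smooth Gaussian-process surrogate representations of intersecting
excited-state potential energy surfaces, with direct optimization and
first-order characterization of minimum-energy conical intersections
(MECIs).

Adiabatic energies have derivative discontinuities along seams of
electronic degeneracy and are therefore hostile to regression.  `conical`
instead learns two surfaces that stay smooth through intersections — the
average energy `omega = (E1 + E2)/2` and the 0th-order characteristic-
polynomial coefficient of the traceless splitting matrix,
`c0 = -(E2 - E1)^2 / 4` — with an RBF plus white-noise kernel whose noise
hyperparameter absorbs reproducible ("deterministic") energy irregularities
of selected-CI electronic-structure methods.  Energies are recovered via
the two-state closed form `E± = omega ± sqrt(-c0)` (positive `c0`
predictions are clamped to zero gap), MECIs are found by a first-order
direct method combining a gap-closing component with a seam-projected
average-energy descent, and the optimized intersection is characterized by
the cone parameters (g̃, h̃, s_x, s_y), composite peaked/sloped (P) and
bifurcating/single-path (B) classifiers, and branching-plane overlaps
r_IJ between methods.

Because the learned noise puts a strictly positive floor on the predictive
uncertainty, degeneracy can only be resolved down to
`ΔE ≤ 2*sqrt(2*δ_min)` where `δ_min` is the minimum predictive standard
deviation of the `c0` model over its training set; the package reports this
bound and a degeneracy-consistency flag with every optimization.

## Layout

| module | contents |
| --- | --- |
| `conical.model_backends` | analytic cone / linear-vibronic-coupling test potentials with known MECIs, deterministic noise injector, energy-table backend |
| `conical.cp_surfaces` | average-energy / characteristic-polynomial decomposition, companion-matrix reconstruction, two-state closed form |
| `conical.descriptors` | SOAP power spectrum (self-contained), sorted inverse distances, raw model coordinates |
| `conical.sampling` | atom-centered Cartesian Latin-hypercube training sets, start-geometry selection |
| `conical.gpr_core` | RBF + white-noise GP regression, multi-start MLE, noise-floor diagnostic |
| `conical.surrogate` | paired omega/c0 surrogates: energies, finite-difference derivatives, degeneracy confidence |
| `conical.meci_optimizer` | branching frames, seam projector, direct MECI optimization |
| `conical.topography` | g̃/h̃/tilt extraction, P/B composites, numeric classification oracle, r_IJ |
| `conical.workflow` | ensemble-of-surrogates protocol, staged refinement, XYZ / energy-table I/O |
| `conical.cli` | `conical` command-line interface |

## Quick start (Python)

```python
import numpy as np
from conical.model_backends import ConeModelBackend, ConeModelParams, Geometry
from conical.descriptors import DescriptorConfig
from conical.sampling import SamplingConfig
from conical.gpr_core import FitOptions
from conical.surrogate import build_surrogate
from conical.meci_optimizer import optimize_meci
from conical.topography import characterize

backend = ConeModelBackend(
    ConeModelParams(g=0.2, h=0.1, s_x=0.05, s_y=0.02),
    dimension=3, seam_curvature=0.3,
)
surrogate = build_surrogate(
    backend,
    center=Geometry.from_flat(np.zeros(3)),
    sampling=SamplingConfig(n_samples=120, half_width=0.5, seed=0),
    descriptor=DescriptorConfig(kind="raw_model_coordinates"),
    fit_options=FitOptions(restarts=8, seed=0),
)
result = optimize_meci(surrogate, Geometry.from_flat([0.3, 0.2, 0.4]))
print(result.geometry.flat, result.delta_e, result.confidence)
print(characterize(surrogate, result.geometry))
```

For molecular geometries use `DescriptorConfig(kind="soap_power_spectrum",
species=(...))` (or the `sorted_inverse_distance` fallback), read frames
with `conical.workflow.read_xyz`, and serve externally computed energies
through `conical.model_backends.TableBackend` /
`conical.workflow.read_energy_table`.

## CLI

```sh
conical sample       --config model.cfg --n 100 --out samples.csv
conical fit          --config model.cfg --n 120 --half-width 0.5 --out bundle/
conical optimize     --bundle bundle/ --start 0.3,0.2,0.4 --out meci.json
conical characterize --bundle bundle/ --at 0,0,0 --out topo.json
conical compare      --frame-i a.json --frame-j b.json
conical ensemble     --config noisy.cfg --n-surrogates 10 --out report.json
```

`model.cfg` is plain key-value text (see `conical cli --help` or the module
docstring for the keys).  Exit codes: 0 success, 2 validation error,
3 convergence failure.

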