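"""Gaussian-process regression with an RBF plus white-noise kernel.

The kernel between training indices i, j is

    k(x_i, x_j) = sigma2 * exp(-d(x_i, x_j)^2 / (2 l^2)) + noise2 * delta_ij,

where the white-noise delta acts on *training-index identity*, not on value
identity: duplicated geometries remain informative and keep the Gram matrix
full rank.  Hyperparameters are estimated by multi-start maximum marginal
likelihood on standardized targets.

The distinguishing diagnostic of this module is the noise floor: with a
noiseless kernel the predictive variance at a training point collapses to
(jitter-level) zero, so degeneracies can be resolved arbitrarily well by
adding data; with white noise the latent predictive variance at any point —
training points included — stays above a strictly positive floor.
:func:`min_uncertainty` reports that floor, which downstream bounds the
resolvable energy gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "KernelParams",
    "GPModel",
    "FitOptions",
    "kernel_eval",
    "log_marginal_likelihood",
    "fit",
    "predict",
    "min_uncertainty",
]

JITTER = 1e-10


@dataclass(frozen=True)
class KernelParams:
    """RBF variance/length-scale and white-noise variance (standardized units)."""

    variance: float
    length_scale: float
    noise: float

    def __post_init__(self) -> None:
        if self.variance <= 0 or self.length_scale <= 0 or self.noise <= 0:
            raise ValueError("kernel hyperparameters must be positive")


def kernel_eval(
    a: np.ndarray, b: np.ndarray, params: KernelParams, same_index: bool = False
) -> float:
    """Single kernel entry; the white-noise term fires only on ``same_index``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite kernel inputs")
    d2 = float(np.sum((a - b) ** 2))
    val = params.variance * np.exp(-0.5 * d2 / params.length_scale**2)
    if same_index:
        val += params.noise
    return float(val)


def _rbf_gram(x1: np.ndarray, x2: np.ndarray, params: KernelParams) -> np.ndarray:
    d2 = cdist(x1, x2, "sqeuclidean")
    return params.variance * np.exp(-0.5 * d2 / params.length_scale**2)


def _train_gram(x: np.ndarray, params: KernelParams) -> np.ndarray:
    k = _rbf_gram(x, x, params)
    k[np.diag_indices_from(k)] += params.noise + JITTER
    return k


def log_marginal_likelihood(
    inputs: np.ndarray, targets: np.ndarray, params: KernelParams
) -> float:
    """Gaussian log marginal likelihood of ``targets`` under the kernel."""
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(targets, dtype=float).reshape(-1)
    if x.shape[0] != y.size or y.size < 1:
        raise ValueError("need one target per input point")
    k = _train_gram(x, params)
    try:
        factor = cho_factor(k, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("Gram matrix singular beyond jitter") from exc
    alpha = cho_solve(factor, y)
    log_det = 2.0 * np.sum(np.log(np.diag(factor[0])))
    return float(-0.5 * y @ alpha - 0.5 * log_det - 0.5 * y.size * np.log(2 * np.pi))


@dataclass
class GPModel:
    """A fitted GP: training data, standardization, hyperparameters, solve state."""

    train_inputs: np.ndarray
    train_targets_raw: np.ndarray
    standardization: tuple[float, float]
    params: KernelParams
    _cho: tuple | None = None
    _alpha: np.ndarray | None = None
    bound_hits: tuple[str, ...] = ()

    @property
    def train_targets(self) -> np.ndarray:
        mean, std = self.standardization
        return (self.train_targets_raw - mean) / std

    def ensure_solve_state(self) -> None:
        if self._alpha is None:
            k = _train_gram(self.train_inputs, self.params)
            self._cho = cho_factor(k, lower=True)
            self._alpha = cho_solve(self._cho, self.train_targets)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_inputs": self.train_inputs.tolist(),
                "train_targets_raw": self.train_targets_raw.tolist(),
                "standardization": list(self.standardization),
                "params": {
                    "variance": self.params.variance,
                    "length_scale": self.params.length_scale,
                    "noise": self.params.noise,
                },
                "bound_hits": list(self.bound_hits),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GPModel":
        doc = json.loads(text)
        return cls(
            train_inputs=np.asarray(doc["train_inputs"], dtype=float),
            train_targets_raw=np.asarray(doc["train_targets_raw"], dtype=float),
            standardization=tuple(doc["standardization"]),
            params=KernelParams(**doc["params"]),
            bound_hits=tuple(doc.get("bound_hits", ())),
        )


@dataclass(frozen=True)
class FitOptions:
    """MLE settings: restarts, RNG seed, optional (log-space) bound overrides."""

    restarts: int = 8
    seed: int = 0
    variance_bounds: tuple[float, float] = (1e-6, 1e6)
    length_scale_bounds: tuple[float, float] | None = None  # default: media-scaled
    noise_bounds: tuple[float, float] = (1e-12, 1.0)
    fix_noise: float | None = None  # pin noise (e.g. jitter floor) instead of fitting


class FittingError(RuntimeError):
    """All MLE restarts failed."""


def fit(
    inputs: np.ndarray,
    targets: np.ndarray,
    options: FitOptions | None = None,
) -> GPModel:
    """Maximum-marginal-likelihood fit on standardized targets.

    Multi-start L-BFGS-B in log-hyperparameter space; length-scale bounds
    default to ``[1e-3, 1e3]`` times the median pairwise input distance.
    Hyperparameters that land on a bound are recorded in ``bound_hits`` so
    pinned optima are observable.
    """
    options = options or FitOptions()
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    y_raw = np.asarray(targets, dtype=float).reshape(-1)
    if x.shape[0] != y_raw.size:
        raise ValueError("need one target per input point")

    mean = float(y_raw.mean())
    std = float(y_raw.std())
    if std <= 0 or y_raw.size < 2:
        std = 1.0  # degenerate-spread fallback: center only
    y = (y_raw - mean) / std

    d2 = cdist(x, x, "sqeuclidean")
    off_diag = d2[np.triu_indices_from(d2, k=1)]
    median_dist = float(np.sqrt(np.median(off_diag))) if off_diag.size else 1.0
    if median_dist <= 0:
        median_dist = 1.0
    ls_bounds = options.length_scale_bounds or (
        1e-3 * median_dist,
        1e3 * median_dist,
    )

    fit_noise = options.fix_noise is None
    log_bounds = [np.log(options.variance_bounds), np.log(ls_bounds)]
    if fit_noise:
        log_bounds.append(np.log(options.noise_bounds))

    def unpack(theta: np.ndarray) -> KernelParams:
        vals = np.exp(theta)
        noise = vals[2] if fit_noise else options.fix_noise
        return KernelParams(vals[0], vals[1], float(noise))

    def objective(theta: np.ndarray) -> float:
        try:
            return -log_marginal_likelihood(x, y, unpack(theta))
        except np.linalg.LinAlgError:
            return 1e12

    rng = np.random.default_rng(options.seed)
    starts = [np.array([np.log(1.0), np.log(median_dist)] + ([np.log(1e-4)] if fit_noise else []))]
    for _ in range(max(options.restarts - 1, 0)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in log_bounds]))

    best = None
    failures = []
    for theta0 in starts:
        try:
            res = minimize(
                objective, theta0, method="L-BFGS-B", bounds=log_bounds
            )
        except Exception as exc:  # pragma: no cover - optimizer blowups
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            failures.append("non-finite objective")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FittingError(f"all MLE restarts failed: {failures}")

    params = unpack(best.x)
    hits = []
    for name, value, (lo, hi) in zip(
        ("variance", "length_scale", "noise") if fit_noise else ("variance", "length_scale"),
        np.exp(best.x),
        [np.exp(np.asarray(b)) for b in log_bounds],
    ):
        if value <= lo * 1.001:
            hits.append(f"{name}:lower")
        elif value >= hi * 0.999:
            hits.append(f"{name}:upper")

    model = GPModel(
        train_inputs=x,
        train_targets_raw=y_raw,
        standardization=(mean, std),
        params=params,
        bound_hits=tuple(hits),
    )
    model.ensure_solve_state()
    return model


def predict(
    model: GPModel, x: np.ndarray, include_noise: bool = True
) -> tuple[float, float]:
    """Posterior mean and standard deviation at ``x``, de-standardized.

    ``include_noise`` adds the white-noise variance to the predictive
    variance (i.e. predicts the noisy observation rather than the latent
    surface); the latent variance is what the degeneracy floor uses.
    """
    model.ensure_solve_state()
    xq = np.asarray(x, dtype=float).reshape(1, -1)
    k_star = _rbf_gram(xq, model.train_inputs, model.params)[0]
    mean_std, std_scale = model.standardization
    mean = float(k_star @ model._alpha) * std_scale + mean_std
    v = cho_solve(model._cho, k_star)
    var = model.params.variance - float(k_star @ v)
    if include_noise:
        var += model.params.noise
    var = max(var, 0.0)
    return mean, float(np.sqrt(var)) * std_scale


def min_uncertainty(model: GPModel) -> float:
    """Minimum latent predictive standard deviation over the training inputs.

    This is the model's resolution floor: (near) zero when the noise is at
    the jitter level, strictly positive otherwise.  Reported in raw target
    units (de-standardized).
    """
    model.ensure_solve_state()
    k_star = _rbf_gram(model.train_inputs, model.train_inputs, model.params)
    v = cho_solve(model._cho, k_star.T)
    var = model.params.variance - np.einsum("ij,ji->i", k_star, v)
    var = np.maximum(var, 0.0)
    return float(np.sqrt(var.min())) * model.standardization[1]
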