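import numpy as np
import pytest

from conical.meci_optimizer import (
    BranchingFrame,
    DegenerateRotation,
    NoConeDetected,
    OptimizerOptions,
    branching_frame,
    direct_step,
    optimize_meci,
    orthogonalize_gh,
    seam_projector,
)
from conical.model_backends import Geometry
from conical.surrogate import hessian_delta_E2
from tests.conftest import CONE_G, CONE_H


def make_frame(dim=3):
    x = np.zeros(dim)
    y = np.zeros(dim)
    x[0] = 1.0
    y[1] = 1.0
    return BranchingFrame(x_hat=x, y_hat=y, eigenvalues=(0.32, 0.08))


class TestOrthogonalize:
    def test_orthogonal_inputs_unchanged(self):
        g = 2.0 * np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        h = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        gt, ht = orthogonalize_gh(g, h)
        assert gt == pytest.approx(g)
        assert ht == pytest.approx(h)

    def test_generic_pair(self):
        g = np.array([1.0, 0.2, 0.0])
        h = np.array([0.2, 1.0, 0.0])
        gt, ht = orthogonalize_gh(g, h)
        assert abs(gt @ ht) < 1e-12
        # span preserved: projector onto span{g,h} equals projector onto span{gt,ht}
        def projector(a, b):
            basis = np.linalg.qr(np.column_stack([a, b]))[0]
            return basis @ basis.T

        assert projector(g, h) == pytest.approx(projector(gt, ht), abs=1e-12)

    def test_rotation_angle_formula(self, rng):
        for _ in range(20):
            g, h = rng.normal(size=(2, 4))
            gt, ht = orthogonalize_gh(g, h)
            assert abs(gt @ ht) < 1e-10

    def test_parallel_equal_norm_degenerate(self):
        g = np.array([1.0, 2.0])
        with pytest.raises(DegenerateRotation):
            orthogonalize_gh(g, g.copy())

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            orthogonalize_gh(np.zeros(2), np.ones(2))


class TestBranchingFrame:
    def test_diagonal_hessian(self):
        frame = branching_frame(np.diag([0.32, 0.08, 0.0]))
        assert frame.x_hat == pytest.approx([1, 0, 0])
        assert frame.y_hat == pytest.approx([0, 1, 0])
        assert frame.eigenvalues == pytest.approx((0.32, 0.08))
        assert frame.seam_eigenvalue == pytest.approx(0.0)

    def test_rotation_equivariance(self, rng):
        base = np.diag([0.32, 0.08, 0.0, 0.0])
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        rotated = q @ base @ q.T
        frame = branching_frame(rotated)
        # eigenvectors match rotated axes up to sign
        assert abs(frame.x_hat @ (q[:, 0])) == pytest.approx(1.0, abs=1e-10)
        assert abs(frame.y_hat @ (q[:, 1])) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_leading_pair_spans_plane(self):
        frame = branching_frame(np.diag([0.2, 0.2, 0.0]))
        span = np.column_stack([frame.x_hat, frame.y_hat])
        proj = span @ span.T
        assert proj == pytest.approx(np.diag([1.0, 1.0, 0.0]), abs=1e-10)

    def test_no_cone_rejected(self):
        with pytest.raises(NoConeDetected):
            branching_frame(np.diag([-0.1, -0.2, 0.0]))

    def test_sign_determinism(self):
        frame = branching_frame(np.diag([0.3, 0.1, 0.0]))
        assert frame.x_hat[0] > 0
        assert frame.y_hat[1] > 0

    def test_frame_invariants_enforced(self):
        with pytest.raises(ValueError):
            BranchingFrame(np.array([1.0, 0]), np.array([2.0, 0]), (1.0, 0.5))
        with pytest.raises(ValueError):
            BranchingFrame(np.array([1.0, 0]), np.array([0, 1.0]), (0.5, 1.0))


class TestSeamProjector:
    def test_three_dim(self):
        p = seam_projector(make_frame())
        assert p == pytest.approx(np.diag([0.0, 0.0, 1.0]))

    def test_projector_identities(self, rng):
        for _ in range(10):
            m = rng.normal(size=(5, 5))
            frame = branching_frame(m @ m.T + 5 * np.eye(5))
            p = seam_projector(frame)
            assert p @ p == pytest.approx(p, abs=1e-12)
            assert p @ frame.x_hat == pytest.approx(np.zeros(5), abs=1e-12)
            assert p @ frame.y_hat == pytest.approx(np.zeros(5), abs=1e-12)
            assert np.trace(p) == pytest.approx(3.0, abs=1e-10)

    def test_fixes_orthogonal_vectors(self):
        p = seam_projector(make_frame(4))
        v = np.array([0.0, 0.0, 0.7, -0.3])
        assert p @ v == pytest.approx(v)


class TestDirectStep:
    def test_at_degeneracy_only_seam_term(self, clean_surrogate):
        geom = Geometry.from_flat([0.0, 0.0, 0.3])
        frame = branching_frame(hessian_delta_E2(clean_surrogate, geom))
        d = direct_step(clean_surrogate, geom, frame)
        # at the (near-)degenerate seam the step is dominated by the
        # projected omega gradient ~ c2 * curvature * z
        assert d[2] == pytest.approx(0.9 * 0.3 * 0.3, rel=0.1)
        assert abs(d[0]) < 0.05 * abs(d[2])

    def test_off_origin_gap_term_along_gap_gradient(self, clean_surrogate):
        geom = Geometry.from_flat([0.2, 0.0, 0.0])
        frame = branching_frame(hessian_delta_E2(clean_surrogate, geom))
        d = direct_step(clean_surrogate, geom, frame, c1=0.2, c2=0.0)
        direction = d / np.linalg.norm(d)
        assert abs(direction[0]) > 0.99  # gap grows along +x there
        gap = clean_surrogate.delta_e_at(geom)
        assert np.linalg.norm(d) == pytest.approx(0.2 * 2 * gap, rel=1e-6)

    def test_descent_direction_on_seam_model(self, clean_surrogate):
        geom = Geometry.from_flat([0.3, 0.2, 0.4])
        frame = branching_frame(hessian_delta_E2(clean_surrogate, geom))
        d = direct_step(clean_surrogate, geom, frame)
        # analytic downhill: gap decreases toward origin, seam term along -z
        before = clean_surrogate.delta_e_at(geom) ** 2 + clean_surrogate.omega_at(geom)
        after_geom = Geometry.from_flat(geom.flat - 0.05 * d)
        after = (
            clean_surrogate.delta_e_at(after_geom) ** 2
            + clean_surrogate.omega_at(after_geom)
        )
        assert after < before


class TestOptimize:
    def test_noiseless_recovers_origin(self, clean_surrogate):
        res = optimize_meci(
            clean_surrogate,
            Geometry.from_flat([0.3, 0.2, 0.4]),
            OptimizerOptions(max_iter=300),
        )
        assert np.linalg.norm(res.geometry.flat) < 1e-3
        assert res.delta_e < 1e-3
        # recovered branching plane vs analytic (e1, e2)
        plane = np.column_stack([res.frame.x_hat, res.frame.y_hat])
        proj = plane @ plane.T
        assert proj[:2, :2] == pytest.approx(np.eye(2), abs=0.05)

    def test_start_at_meci_fixed_point(self, clean_surrogate, origin3):
        res = optimize_meci(
            clean_surrogate, origin3, OptimizerOptions(grad_tol=1e-2)
        )
        assert res.iterations <= 2
        assert np.linalg.norm(res.geometry.flat) < 0.05

    def test_noisy_respects_noise_floor_bound(self, noisy_surrogate):
        res = optimize_meci(
            noisy_surrogate,
            Geometry.from_flat([0.3, 0.2, 0.4]),
            OptimizerOptions(max_iter=200),
        )
        assert res.delta_e <= res.confidence.delta_E_bound
        assert res.confidence.consistent_with_degeneracy

    def test_max_iter_reported(self, clean_surrogate):
        res = optimize_meci(
            clean_surrogate,
            Geometry.from_flat([0.3, 0.2, 0.4]),
            OptimizerOptions(max_iter=1, grad_tol=1e-12),
        )
        assert not res.converged
        assert res.stall_reason in ("max_iter", "noise_floor", "clamp_stall")

    def test_trace_recorded(self, clean_surrogate):
        res = optimize_meci(
            clean_surrogate,
            Geometry.from_flat([0.2, 0.1, 0.2]),
            OptimizerOptions(max_iter=50),
        )
        assert len(res.trace) == res.iterations
        assert res.trace[0][1] >= 0  # gap column non-negative

    def test_seam_omega_non_increasing(self, clean_surrogate):
        """Seam-projected average energy decreases over accepted iterations.

        On this model omega restricted to the seam is the bowl k/2 z^2, so
        |z| must shrink monotonically (within line-search tolerance).
        """
        res = optimize_meci(
            clean_surrogate,
            Geometry.from_flat([0.1, 0.1, 0.45]),
            OptimizerOptions(max_iter=100),
        )
        assert abs(res.geometry.flat[2]) < 0.01

    def test_bounds_respected(self, noisy_surrogate):
        lo = np.full(3, -0.5)
        hi = np.full(3, 0.5)
        res = optimize_meci(
            noisy_surrogate,
            Geometry.from_flat([0.3, 0.2, 0.4]),
            OptimizerOptions(max_iter=100, bounds=(lo, hi)),
        )
        assert np.all(res.geometry.flat >= lo)
        assert np.all(res.geometry.flat <= hi)


class TestEnsembleSpread:
    def test_spread_shrinks_with_noise(self, cone_backend, origin3, raw_descriptor):
        """MECI scatter across training sets shrinks as noise decreases."""
        from conical.gpr_core import FitOptions
        from conical.model_backends import NoisyBackend
        from conical.sampling import SamplingConfig
        from conical.surrogate import build_surrogate

        def scatter(amplitude):
            finals = []
            for seed in range(4):
                backend = NoisyBackend(cone_backend, amplitude, key=seed)
                surr = build_surrogate(
                    backend,
                    origin3,
                    SamplingConfig(n_samples=60, half_width=0.3, seed=seed),
                    raw_descriptor,
                    FitOptions(restarts=4, seed=seed),
                )
                res = optimize_meci(
                    surr,
                    Geometry.from_flat([0.2, 0.15, 0.2]),
                    OptimizerOptions(
                        max_iter=60,
                        bounds=(np.full(3, -0.4), np.full(3, 0.4)),
                    ),
                )
                finals.append(res.geometry.flat)
            return float(np.mean(np.std(np.array(finals), axis=0)))

        assert scatter(1e-3) > scatter(1e-5)
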