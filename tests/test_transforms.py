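"""Transform evaluation, Jacobians/Hessians, field statistics, persistence."""

import json

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from jetmap.synthetic import random_bump_transform
from jetmap.transforms import (
    AffineTransform,
    AnalyticTransform,
    CompositeTransform,
    DisplacementField,
    OutOfDomainError,
    field_statistics,
    identity,
    load_transform,
    validate_diffeomorphism,
)


def square_x_transform():
    """phi(x, y, z) = (x^2, y, z) with closed-form derivatives."""
    def f(p):
        return np.array([p[0] ** 2, p[1], p[2]])
    return AnalyticTransform(f)


def constant_field(v, origin=(0, 0, 0), spacing=(10, 10, 10), shape=(3, 3, 3)):
    values = np.tile(np.asarray(v, float), (*shape, 1))
    return DisplacementField(origin, spacing, values)


class TestEvaluate:
    def test_identity(self, rng):
        x = rng.normal(size=3)
        np.testing.assert_allclose(identity().evaluate(x), x)

    def test_affine_arithmetic(self):
        t = AffineTransform(2 * np.eye(3), [1, 0, 0])
        np.testing.assert_allclose(t.evaluate([1, 1, 1]), [3, 2, 2])

    def test_constant_field_everywhere(self, rng):
        v = [1.5, -2.0, 0.5]
        f = constant_field(v)
        for x in rng.uniform(0, 20, (5, 3)):  # including between grid nodes
            np.testing.assert_allclose(f.evaluate(x), x + v)

    def test_out_of_domain_raises_unless_padded(self):
        f = constant_field([1, 0, 0])
        with pytest.raises(OutOfDomainError):
            f.evaluate(np.array([50.0, 0, 0]))
        padded = DisplacementField(f.origin, f.spacing, f.values, padding=True)
        np.testing.assert_allclose(padded.evaluate(np.array([50.0, 0, 0])), [50, 0, 0])


class TestJacobian:
    def test_identity_jacobian(self):
        np.testing.assert_allclose(identity().jacobian(np.zeros(3)), np.eye(3))

    def test_analytic_square(self):
        J = square_x_transform().jacobian(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(J, np.diag([2.0, 1.0, 1.0]), atol=1e-7)

    def test_affine_fd_oracle(self, rng):
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        t = AffineTransform(A, rng.normal(size=3))
        fd = AnalyticTransform(t.evaluate).jacobian(rng.normal(size=3))
        np.testing.assert_allclose(fd, A, atol=1e-8)

    @pytest.mark.parametrize("kind", ["affine", "bump", "field"])
    def test_fd_consistency_random_points(self, rng, kind):
        """Analytic/interpolant Jacobians agree with central differences."""
        if kind == "affine":
            t = AffineTransform(np.eye(3) + 0.1 * rng.normal(size=(3, 3)),
                                rng.normal(size=3))
        elif kind == "bump":
            t = random_bump_transform(rng, box=50.0)
        else:
            t = DisplacementField((0, 0, 0), (10, 10, 10),
                                  rng.normal(size=(4, 4, 4, 3)))
        pts = rng.uniform(2, 28, (100, 3)) if kind == "field" else \
            rng.uniform(-40, 40, (100, 3))
        for x in pts:
            J = t.jacobian(x)
            fd = AnalyticTransform(t.evaluate).jacobian(x)
            np.testing.assert_allclose(J, fd, rtol=1e-4, atol=1e-5)

    def test_field_jacobian_exact_in_cell(self, rng):
        # within a cell the interpolant is trilinear; its gradient is exact,
        # so FD with any small step reproduces it to machine-level accuracy
        f = DisplacementField((0, 0, 0), (10, 10, 10), rng.normal(size=(3, 3, 3, 3)))
        x = np.array([3.7, 12.1, 5.9])
        fd = AnalyticTransform(f.evaluate).jacobian(x)
        np.testing.assert_allclose(f.jacobian(x), fd, atol=1e-9)


class TestHessian:
    def test_affine_zero(self, rng):
        t = AffineTransform(rng.normal(size=(3, 3)) + 3 * np.eye(3), np.zeros(3))
        np.testing.assert_allclose(t.hessian(rng.normal(size=3)), 0)

    def test_square_single_entry(self, rng):
        H = square_x_transform().hessian(rng.normal(size=3))
        expected = np.zeros((3, 3, 3))
        expected[0, 0, 0] = 2.0
        np.testing.assert_allclose(H, expected, atol=1e-5)

    def test_bump_hessian_fd_oracle(self, rng):
        t = random_bump_transform(rng, box=50.0)
        x = rng.uniform(-30, 30, 3)
        fd = AnalyticTransform(t.evaluate).hessian(x)
        np.testing.assert_allclose(t.hessian(x), fd, atol=1e-5)

    def test_field_hessian_mixed_partials(self, rng):
        f = DisplacementField((0, 0, 0), (10, 10, 10), rng.normal(size=(3, 3, 3, 3)))
        x = np.array([4.2, 6.3, 3.1])
        H = f.hessian(x)
        # symmetric and zero on the diagonal of the last two indices
        np.testing.assert_allclose(H, np.transpose(H, (0, 2, 1)))
        np.testing.assert_allclose(H[:, [0, 1, 2], [0, 1, 2]], 0)
        fd = AnalyticTransform(f.evaluate).hessian(x)
        np.testing.assert_allclose(H, fd, atol=1e-6)


class TestTrilinear:
    def test_reproduces_node_values(self, rng):
        f = DisplacementField((0, 0, 0), (5, 5, 5), rng.normal(size=(4, 3, 5, 3)))
        pts = f.grid_points()
        np.testing.assert_allclose(f.displacement(pts),
                                   f.values.reshape(-1, 3), atol=1e-12)

    def test_matches_scipy_interpolator(self, rng):
        values = rng.normal(size=(4, 5, 3, 3))
        f = DisplacementField((1, 2, 3), (5, 4, 6), values)
        axes = [1 + 5 * np.arange(4), 2 + 4 * np.arange(5), 3 + 6 * np.arange(3)]
        ref = RegularGridInterpolator(axes, values)
        pts = rng.uniform([1, 2, 3], [16, 18, 15], (50, 3))
        np.testing.assert_allclose(f.displacement(pts), ref(pts), atol=1e-12)

    def test_linear_along_axis(self, rng):
        f = DisplacementField((0, 0, 0), (10, 10, 10), rng.normal(size=(3, 3, 3, 3)))
        a = f.displacement(np.array([2.0, 5.0, 5.0]))
        b = f.displacement(np.array([8.0, 5.0, 5.0]))
        mid = f.displacement(np.array([5.0, 5.0, 5.0]))
        np.testing.assert_allclose(mid, 0.5 * (a + b), atol=1e-12)


class TestComposition:
    def test_evaluate_and_chain_rule(self, rng):
        a = random_bump_transform(rng, box=50.0)
        b = AffineTransform(np.eye(3) + 0.2 * rng.normal(size=(3, 3)),
                            rng.normal(size=3))
        comp = CompositeTransform([a, b])
        x = rng.uniform(-30, 30, 3)
        np.testing.assert_allclose(comp.evaluate(x), b.evaluate(a.evaluate(x)))
        np.testing.assert_allclose(comp.jacobian(x),
                                   b.jacobian(a.evaluate(x)) @ a.jacobian(x))
        fd = AnalyticTransform(comp.evaluate).jacobian(x)
        np.testing.assert_allclose(comp.jacobian(x), fd, rtol=1e-4, atol=1e-6)

    def test_composite_hessian_fd_oracle(self, rng):
        a = random_bump_transform(rng, box=40.0, amplitude=10.0)
        b = random_bump_transform(rng, box=40.0, amplitude=10.0)
        comp = CompositeTransform([a, b])
        x = rng.uniform(-20, 20, 3)
        fd = AnalyticTransform(comp.evaluate).hessian(x)
        np.testing.assert_allclose(comp.hessian(x), fd, atol=1e-4)


class TestValidateDiffeomorphism:
    def test_identity_passes(self):
        f = constant_field([0, 0, 0])
        rep = validate_diffeomorphism(f)
        assert rep.passed
        assert rep.min_jacobian_det == pytest.approx(1.0)
        assert rep.sup_displacement_gradient == pytest.approx(0.0)

    def test_steep_bump_flagged(self):
        # amplitude/sigma chosen so a/(sigma*sqrt(e)) > 1: max |grad u| >= 1
        sigma, amp = 10.0, 30.0
        pts = np.linspace(-40, 40, 9)
        mesh = np.meshgrid(pts, pts, pts, indexing="ij")
        r2 = sum(m**2 for m in mesh)
        u = np.zeros((9, 9, 9, 3))
        u[..., 0] = amp * np.exp(-r2 / (2 * sigma**2))
        f = DisplacementField((-40, -40, -40), (10, 10, 10), u)
        rep = validate_diffeomorphism(f, n_per_axis=17)
        assert not rep.passed

    def test_orientation_reversal_flagged(self):
        t = AffineTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))
        rep = validate_diffeomorphism(t, lower=(-1, -1, -1), upper=(1, 1, 1))
        assert not rep.passed and rep.min_jacobian_det < 0


class TestFieldStatistics:
    def test_identity_field(self):
        df, summary = field_statistics(constant_field([0, 0, 0]))
        assert np.allclose(df["displacement_magnitude"], 0)
        assert np.allclose(df["log_jacobian_det"], 0)
        assert np.allclose(df["jacobian_minus_identity_norm"], 0)

    def test_pure_translation(self):
        v = [3.0, 4.0, 0.0]
        df, _ = field_statistics(constant_field(v))
        assert np.allclose(df["displacement_magnitude"], 5.0)
        assert np.allclose(df["log_jacobian_det"], 0, atol=1e-12)
        assert np.allclose(df["tangent_displacement"], 0, atol=1e-12)

    def test_linear_expansion(self):
        # u(x) = 0.1 x -> Dphi = 1.1 I, log det = 3 ln 1.1
        origin, spacing, shape = (0, 0, 0), (10, 10, 10), (3, 3, 3)
        axes = [10 * np.arange(3)] * 3
        mesh = np.meshgrid(*axes, indexing="ij")
        u = 0.1 * np.stack(mesh, axis=-1)
        df, summary = field_statistics(DisplacementField(origin, spacing, u))
        np.testing.assert_allclose(df["log_jacobian_det"], 3 * np.log(1.1), atol=1e-10)
        np.testing.assert_allclose(df["jacobian_norm"], 1.1, atol=1e-10)
        v = np.ones(3)
        np.testing.assert_allclose(df["tangent_displacement"],
                                   0.1 * np.linalg.norm(v), atol=1e-10)


class TestPersistence:
    def test_hdf5_round_trip(self, rng, tmp_path):
        f = DisplacementField((1, 2, 3), (5, 5, 5), rng.normal(size=(3, 4, 5, 3)))
        p = tmp_path / "field.h5"
        f.to_hdf5(p)
        g = DisplacementField.from_hdf5(p)
        np.testing.assert_allclose(g.values, f.values)
        np.testing.assert_allclose(g.origin, f.origin)

    def test_json_affine_load(self, tmp_path):
        p = tmp_path / "affine.json"
        mat = [1, 2, 0, 0, 3, 0, 0, 0, 4]
        p.write_text(json.dumps(dict(matrix=mat, offset=[1, 2, 3])))
        t = load_transform(p)
        assert isinstance(t, AffineTransform)
        np.testing.assert_allclose(t.matrix, np.asarray(mat).reshape(3, 3))

    def test_json_field_and_nonlinear_only(self, rng, tmp_path):
        f = DisplacementField((0, 0, 0), (10, 10, 10), rng.normal(size=(3, 3, 3, 3)))
        fp = tmp_path / "field.json"
        f.to_json(fp)
        comp_p = tmp_path / "comp.json"
        comp_p.write_text(json.dumps(dict(
            affine=dict(matrix=(2 * np.eye(3)).ravel().tolist(), offset=[0, 0, 0]),
            field=json.loads(fp.read_text()),
        )))
        comp = load_transform(comp_p)
        assert isinstance(comp, CompositeTransform)
        nl = load_transform(comp_p, nonlinear_only=True)
        assert isinstance(nl, DisplacementField)
        x = np.array([5.0, 5.0, 5.0])
        np.testing.assert_allclose(comp.evaluate(x), 2 * nl.evaluate(x))
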