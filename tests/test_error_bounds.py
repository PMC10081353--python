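"""Mapping-error bounds and the discrete Frechet distance."""

import math

import numpy as np
import pytest

from conftest import bumps_along, random_polyline
from jetmap.error_bounds import (
    AffineLengthBound,
    affine_bound_in_length,
    bound_c1,
    bound_piecewise_linear,
    bound_smooth_orders,
    discrete_frechet,
)
from jetmap.jet_mapping import (
    apply_jet_action,
    dense_params,
    jet_extension_from_curve,
    max_deviation,
    spline_from_jets,
)
from jetmap.swc_io import arc_length_parameterize, downsample_branch
from jetmap.synthetic import CurveSpec, GaussianBumpTransform, make_curve
from jetmap.transforms import AffineTransform, identity


def frechet_bruteforce(P, Q):
    """Minimax over all monotone couplings, by exhaustive path enumeration."""
    n, m = len(P), len(Q)
    d = np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=2)
    best = math.inf
    stack = [((0, 0), d[0, 0])]
    while stack:
        (i, j), cost = stack.pop()
        if cost >= best:
            continue
        if (i, j) == (n - 1, m - 1):
            best = cost
            continue
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ii, jj = i + di, j + dj
            if ii < n and jj < m:
                stack.append(((ii, jj), max(cost, d[ii, jj])))
    return best


class TestDiscreteFrechet:
    def test_identical_polylines_zero(self, rng):
        br = random_polyline(rng)
        assert discrete_frechet(br, br).distance == 0.0

    def test_uniform_translation(self):
        P = np.array([[0, 0, 0], [1, 0, 0.0]])
        assert discrete_frechet(P, P + [0, 1, 0]).distance == pytest.approx(1.0)

    def test_symmetry(self, rng):
        P, Q = rng.normal(size=(9, 3)), rng.normal(size=(13, 3))
        assert discrete_frechet(P, Q).distance == pytest.approx(
            discrete_frechet(Q, P).distance)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(int(rng.integers(2, 8)), 3))
        Q = rng.normal(size=(int(rng.integers(2, 8)), 3))
        assert discrete_frechet(P, Q).distance == pytest.approx(
            frechet_bruteforce(P, Q))

    def test_coupling_is_monotone_and_achieves_distance(self, rng):
        P, Q = rng.normal(size=(6, 3)), rng.normal(size=(9, 3))
        res = discrete_frechet(P, Q, return_coupling=True)
        steps = np.diff(np.array(res.coupling), axis=0)
        assert np.all(steps >= 0) and np.all(steps.sum(axis=1) >= 1)
        realized = max(np.linalg.norm(P[i] - Q[j]) for i, j in res.coupling)
        assert realized == pytest.approx(res.distance)

    def test_never_decreases_under_subsampling(self, rng):
        """Consistent with upper-bounding continuous Frechet distance."""
        for _ in range(10):
            br = random_polyline(rng, n_knots=20)
            sub = downsample_branch(br, 3)
            full = discrete_frechet(br, br).distance
            phi = bumps_along(br.knots, seed=int(rng.integers(1000)))
            from jetmap.jet_mapping import map_dense_reference
            truth = map_dense_reference(br, phi, spacing=2.0)
            d_full = discrete_frechet(br.knots, truth.knots).distance
            d_sub = discrete_frechet(sub.knots, truth.knots).distance
            assert d_sub >= d_full - 1e-12
            assert full == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discrete_frechet(np.empty((0, 3)), np.zeros((2, 3)))


class TestZerothOrderBounds:
    def test_identity_c1_bound(self):
        br = arc_length_parameterize(np.array([[0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]]))
        rep = bound_c1(br, identity())
        assert rep.overall == pytest.approx(math.sqrt(3) * 2.0)

    def test_uniform_scaling_c1_bound(self):
        br = arc_length_parameterize(np.array([[0, 0, 0], [2.0, 0, 0]]))
        rep = bound_c1(br, AffineTransform(3.0 * np.eye(3), np.zeros(3)))
        assert rep.overall == pytest.approx(math.sqrt(3) * 2.0 * 3.0)

    def test_identity_piecewise_linear_bound_zero(self, rng):
        rep = bound_piecewise_linear(random_polyline(rng), identity())
        assert rep.overall == pytest.approx(0.0, abs=1e-12)

    def test_translation_piecewise_linear_bound_zero(self, rng):
        t = AffineTransform(np.eye(3), [5.0, -3.0, 2.0])
        rep = bound_piecewise_linear(random_polyline(rng), t)
        assert rep.overall == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_bounds_dominate_observed_error(self, seed):
        rng = np.random.default_rng(seed)
        br = random_polyline(rng, n_knots=int(rng.integers(4, 15)))
        phi = bumps_along(br.knots, seed=seed + 1000,
                          amplitude=float(rng.uniform(5, 25)),
                          sigma=float(rng.uniform(50, 120)))
        observed = max_deviation(br, phi, order=0, spacing=0.5)
        assert observed <= bound_c1(br, phi).overall + 1e-9
        assert observed <= bound_piecewise_linear(br, phi).overall + 1e-9

    def test_bound_vanishes_with_amplitude(self, rng):
        """As the bump amplitude shrinks to zero the bound does too,
        monotonically."""
        br = random_polyline(rng, n_knots=8)
        base = bumps_along(br.knots, seed=3, amplitude=20.0)
        vals = []
        for scale in [1.0, 0.5, 0.25, 0.1, 0.0]:
            phi = GaussianBumpTransform(base.centers, base.directions,
                                        base.amplitudes * scale, base.sigmas)
            vals.append(bound_piecewise_linear(br, phi).overall)
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.0, abs=1e-12)


class TestSmoothOrderBounds:
    def test_cubic_coordinates_zero_quartic_bound(self):
        """Affine image of a cubic-in-t curve: M4 = 0 up to roundoff, the
        first-order bound collapses, and analytic-jet Hermite mapping is
        exact."""
        def pos(t):
            t = np.atleast_1d(t)
            return np.stack([t, t**2 / 100, t**3 / 10000], axis=1)

        def deriv(t, k):
            t = np.atleast_1d(t)
            if k == 1:
                return np.stack([np.ones_like(t), t / 50, 3 * t**2 / 10000], axis=1)
            return np.stack([np.zeros_like(t), np.full_like(t, 1 / 50),
                             6 * t / 10000], axis=1)

        params = np.linspace(0, 100, 6)
        phi = AffineTransform(np.eye(3) * 1.5, np.ones(3))
        rep0, rep1 = bound_smooth_orders(pos, params, phi)
        assert rep1.overall < 1e-4
        jets = apply_jet_action(
            jet_extension_from_curve(pos, params, 1, deriv), phi)
        g1 = spline_from_jets(jets)
        tt = dense_params(params, 0.5)
        truth = phi.map_points(pos(tt))
        assert np.max(np.linalg.norm(g1.evaluate(tt) - truth, axis=1)) < 1e-8

    def test_straight_identity_all_zero(self):
        def pos(t):
            t = np.atleast_1d(t)
            return np.stack([t, np.zeros_like(t), np.zeros_like(t)], axis=1)

        rep0, rep1 = bound_smooth_orders(pos, np.linspace(0, 50, 4), identity())
        assert rep0.overall < 1e-6 and rep1.overall < 1e-9

    @pytest.mark.parametrize("delta", [0.5, 1.0, 2.0])
    def test_bounds_dominate_on_circular_helix(self, delta):
        """f(t) = (sin t, cos t, t): both bounds dominate observed error."""
        def pos(t):
            t = np.atleast_1d(t)
            return np.stack([np.sin(t), np.cos(t), t], axis=1)

        def deriv(t, k):
            t = np.atleast_1d(t)
            if k == 1:
                return np.stack([np.cos(t), -np.sin(t), np.ones_like(t)], axis=1)
            return np.stack([-np.sin(t), -np.cos(t), np.zeros_like(t)], axis=1)

        params = np.arange(0.0, 10.0 + delta / 2, delta)
        rep0, rep1 = bound_smooth_orders(pos, params, identity())
        tt = dense_params(params, 0.02)
        truth = pos(tt)
        g0 = spline_from_jets(jet_extension_from_curve(pos, params, 0))
        g1 = spline_from_jets(jet_extension_from_curve(pos, params, 1, deriv))
        err0 = np.max(np.linalg.norm(g0.evaluate(tt) - truth, axis=1))
        err1 = np.max(np.linalg.norm(g1.evaluate(tt) - truth, axis=1))
        assert err0 <= rep0.overall + 1e-9
        assert err1 <= rep1.overall + 1e-9
        assert rep1.overall <= rep0.overall

    def test_first_order_bound_always_tighter(self, rng):
        curve = make_curve(CurveSpec(length=150, amplitude=15, seed=17))
        phi = bumps_along(curve.position(np.linspace(0, 150, 10)), seed=33)
        rep0, rep1 = bound_smooth_orders(curve.position,
                                         np.linspace(0, 150, 9), phi)
        assert rep1.overall <= rep0.overall


class TestAffineLengthBound:
    def test_identity_gives_zero_and_unbounded_length(self):
        br = affine_bound_in_length(identity(), lower=(-10,) * 3, upper=(10,) * 3)
        assert br.slope == pytest.approx(0.0, abs=1e-10)
        assert br.intercept == pytest.approx(0.0, abs=1e-10)
        assert br.max_length(1.0) == math.inf

    def test_published_constants_worked_examples(self):
        b = AffineLengthBound(slope=0.011, intercept=0.022)
        assert b.bound(10) == pytest.approx(0.132)
        assert b.bound(1000) == pytest.approx(11.022)
        assert b.max_length(1.0) == 88

    def test_single_segment_bound_consistency(self, rng):
        """a*L + b dominates the piecewise-linear bound of any straight
        segment of length L inside the sampled domain."""
        phi = bumps_along(rng.uniform(-100, 100, (5, 3)), seed=77)
        ab = affine_bound_in_length(phi, lower=(-150,) * 3, upper=(150,) * 3,
                                    n_per_axis=12)
        for _ in range(20):
            p0 = rng.uniform(-80, 80, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            L = float(rng.uniform(5, 100))
            seg = arc_length_parameterize(np.array([p0, p0 + L * d]))
            rep = bound_piecewise_linear(seg, phi)
            assert rep.overall <= ab.bound(L) + 1e-9
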