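"""Synthetic curves and deformation fields with known smoothness guarantees.

The generators emulate the experimental regime of traced neurons mapped
through a brain-to-atlas registration: curves millimeters long with knots
spaced at the tens-of-microns scale, and nonlinear deformation fields that
vary at the hundreds-of-microns scale (registration resolution), with
displacement magnitudes of tens of microns.  Deformations are built as
``phi(x) = x + u(x)`` from Gaussian bumps whose gradient admits the closed
form ``sup |Du| = amplitude / (sigma sqrt(e))`` per bump, so specs are
rejected unless the summed bound is < 1 — a sufficient condition for
``phi`` to be a diffeomorphism.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .swc_io import PolylineBranch, arc_length_parameterize
from .transforms import DisplacementField, Transform

__all__ = [
    "AnalyticCurve",
    "CurveSpec",
    "FieldSpec",
    "GaussianBumpTransform",
    "make_curve",
    "sample_knots",
    "make_field",
    "make_bump_transform",
    "random_bump_transform",
]


@dataclass
class AnalyticCurve:
    """A smooth curve with evaluable position and first two derivatives.

    Callables are vectorized: ``(m,)`` parameters in, ``(m, 3)`` out.  The
    parameter is not necessarily arc length.
    """

    position: callable
    d1: callable
    d2: callable
    domain: tuple[float, float]

    def derivative(self, t: np.ndarray, order: int = 1) -> np.ndarray:
        if order == 1:
            return self.d1(t)
        if order == 2:
            return self.d2(t)
        raise ValueError("derivatives available up to order 2")

    def min_speed(self, n: int = 2000) -> float:
        t = np.linspace(*self.domain, n)
        return float(np.min(np.linalg.norm(self.d1(t), axis=1)))

    def arc_length(self, n: int = 4001) -> float:
        t = np.linspace(*self.domain, n)
        speed = np.linalg.norm(self.d1(t), axis=1)
        return float(np.trapezoid(speed, t))


@dataclass
class CurveSpec:
    """Parameters of a synthetic curve family.

    ``length`` is the parameter-domain length in microns (approximately arc
    length, since all families keep speed near 1).  ``amplitude`` scales
    the transverse excursions and ``n_harmonics`` the Fourier content of
    the ``random_fourier`` family, whose coefficients decay as ``1/m^2`` so
    the curve is smooth with bounded derivatives.
    """

    family: str = "random_fourier"
    length: float = 2000.0
    amplitude: float = 60.0
    frequency: float = 1.0
    n_harmonics: int = 4
    seed: int = 0


def make_curve(spec: CurveSpec) -> AnalyticCurve:
    """Build a regular analytic curve from a spec (deterministic per seed)."""
    L = float(spec.length)
    if L <= 0:
        raise ValueError("curve length must be positive")
    rng = np.random.default_rng(spec.seed)

    if spec.family == "straight":
        direction = _random_unit(rng)
        origin = rng.uniform(-10, 10, 3)
        curve = AnalyticCurve(
            position=lambda t: origin + np.outer(np.atleast_1d(t), direction),
            d1=lambda t: np.tile(direction, (np.atleast_1d(t).size, 1)),
            d2=lambda t: np.zeros((np.atleast_1d(t).size, 3)),
            domain=(0.0, L),
        )
    elif spec.family == "helix":
        r = spec.amplitude
        pitch = spec.frequency * r  # rise per radian
        scale = math.hypot(r, pitch)  # makes |c'| = 1
        w = 1.0 / scale

        def pos(t):
            t = np.atleast_1d(t)
            return np.stack([r * np.cos(w * t), r * np.sin(w * t), pitch * w * t], axis=1)

        def d1(t):
            t = np.atleast_1d(t)
            return np.stack([-r * w * np.sin(w * t), r * w * np.cos(w * t),
                             np.full(t.size, pitch * w)], axis=1)

        def d2(t):
            t = np.atleast_1d(t)
            return np.stack([-r * w**2 * np.cos(w * t), -r * w**2 * np.sin(w * t),
                             np.zeros(t.size)], axis=1)

        curve = AnalyticCurve(pos, d1, d2, (0.0, L))
    elif spec.family == "sinusoid":
        a = spec.amplitude
        k = 2 * math.pi * spec.frequency / L

        def pos(t):
            t = np.atleast_1d(t)
            return np.stack([t, a * np.sin(k * t), a * 0.5 * np.cos(k * t)], axis=1)

        def d1(t):
            t = np.atleast_1d(t)
            return np.stack([np.ones(t.size), a * k * np.cos(k * t),
                             -a * 0.5 * k * np.sin(k * t)], axis=1)

        def d2(t):
            t = np.atleast_1d(t)
            return np.stack([np.zeros(t.size), -a * k**2 * np.sin(k * t),
                             -a * 0.5 * k**2 * np.cos(k * t)], axis=1)

        curve = AnalyticCurve(pos, d1, d2, (0.0, L))
    elif spec.family == "random_fourier":
        M = spec.n_harmonics
        base = _random_unit(rng)
        origin = rng.uniform(-10, 10, 3)
        # coefficients decay as 1/m^2 => C-infinity with bounded derivatives
        amps = spec.amplitude / np.arange(1, M + 1) ** 2
        A = rng.normal(size=(M, 3)) * amps[:, None] / math.sqrt(3)
        B = rng.normal(size=(M, 3)) * amps[:, None] / math.sqrt(3)
        ks = 2 * math.pi * np.arange(1, M + 1) / L

        def pos(t):
            t = np.atleast_1d(t)
            ph = np.outer(t, ks)  # (m, M)
            return origin + np.outer(t, base) + np.sin(ph) @ A + np.cos(ph) @ B

        def d1(t):
            t = np.atleast_1d(t)
            ph = np.outer(t, ks)
            return base + (np.cos(ph) * ks) @ A - (np.sin(ph) * ks) @ B

        def d2(t):
            t = np.atleast_1d(t)
            ph = np.outer(t, ks)
            return -(np.sin(ph) * ks**2) @ A - (np.cos(ph) * ks**2) @ B

        curve = AnalyticCurve(pos, d1, d2, (0.0, L))
    else:
        raise ValueError(f"unknown curve family {spec.family!r}")

    if curve.min_speed() < 0.05:
        raise ValueError(
            f"curve spec {spec} produces a non-regular curve (min |c'| < 0.05); "
            "reduce amplitude or harmonics"
        )
    return curve


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def sample_knots(curve: AnalyticCurve, period: float, n_fine: int = 4001) -> PolylineBranch:
    """Sample a curve at approximately uniform arc-length steps.

    Arc length is accumulated by fine trapezoidal quadrature of the speed
    and inverted numerically; the endpoint is always included.  A period
    larger than the curve length yields the two endpoints.
    """
    if period <= 0:
        raise ValueError("sampling period must be positive")
    t0, t1 = curve.domain
    t = np.linspace(t0, t1, n_fine)
    speed = np.linalg.norm(curve.d1(t), axis=1)
    s = cumulative_trapezoid(speed, t, initial=0.0)
    total = s[-1]
    n_seg = max(1, int(round(total / period)))
    targets = np.linspace(0.0, total, n_seg + 1)
    t_knots = np.interp(targets, s, t)
    return arc_length_parameterize(curve.position(t_knots))


class GaussianBumpTransform(Transform):
    """``phi(x) = x + sum_i a_i d_i exp(-|x - c_i|^2 / (2 sigma_i^2))``.

    A smooth (C-infinity) displacement built from Gaussian bumps with
    closed-form Jacobian and Hessian.  Each bump's displacement gradient is
    bounded by ``|a_i| / (sigma_i sqrt(e))``; construction fails unless the
    bounds sum below 1, which guarantees ``phi`` is a diffeomorphism of
    R^3.
    """

    def __init__(self, centers: np.ndarray, directions: np.ndarray,
                 amplitudes: np.ndarray, sigmas: np.ndarray):
        self.centers = np.atleast_2d(np.asarray(centers, float))
        self.directions = np.atleast_2d(np.asarray(directions, float))
        norms = np.linalg.norm(self.directions, axis=1, keepdims=True)
        self.directions = self.directions / norms
        self.amplitudes = np.atleast_1d(np.asarray(amplitudes, float))
        self.sigmas = np.atleast_1d(np.asarray(sigmas, float))
        bound = self.gradient_bound()
        if bound >= 1.0:
            raise ValueError(
                f"sum of per-bump gradient bounds is {bound:.3f} >= 1; "
                "the map is not guaranteed to be a diffeomorphism"
            )

    def gradient_bound(self) -> float:
        """Closed-form bound on ``sup |Du|`` (sum over bumps of a/(sigma*sqrt(e)))."""
        return float(np.sum(np.abs(self.amplitudes) / (self.sigmas * math.sqrt(math.e))))

    def displacement(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        u = np.zeros_like(pts)
        for c, d, a, s in zip(self.centers, self.directions, self.amplitudes, self.sigmas):
            r2 = np.sum((pts - c) ** 2, axis=1)
            u += a * np.exp(-r2 / (2 * s * s))[:, None] * d
        return u

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return x + self.displacement(x)[0] if x.ndim == 1 else x + self.displacement(x)

    def map_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts + self.displacement(pts)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        return self.jacobian_many(np.atleast_2d(x))[0]

    def jacobian_many(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        J = np.broadcast_to(np.eye(3), (pts.shape[0], 3, 3)).copy()
        for c, d, a, s in zip(self.centers, self.directions, self.amplitudes, self.sigmas):
            diff = pts - c
            g = a * np.exp(-np.sum(diff**2, axis=1) / (2 * s * s))
            # Du = d (grad g)^T with grad g = -(diff / s^2) g
            J += np.einsum("i,nj,n->nij", d, -diff / (s * s), g)
        return J

    def hessian(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float).reshape(3)
        H = np.zeros((3, 3, 3))
        for c, d, a, s in zip(self.centers, self.directions, self.amplitudes, self.sigmas):
            diff = x - c
            g = a * math.exp(-float(np.sum(diff**2)) / (2 * s * s))
            # d2g/dxp dxq = g * (diff_p diff_q / s^4 - delta_pq / s^2)
            hpq = g * (np.outer(diff, diff) / s**4 - np.eye(3) / s**2)
            H += d[:, None, None] * hpq[None, :, :]
        return H


@dataclass
class FieldSpec:
    """Parameters of a synthetic gridded deformation field.

    Defaults mirror the registration regime: a regular grid with 100-micron
    spacing and displacements of tens of microns varying at the
    hundreds-of-microns scale.
    """

    family: str = "gaussian_bump"
    amplitude: float = 30.0  # microns, per bump
    sigma: float = 150.0  # microns, bump length scale
    n_bumps: int = 3
    origin: tuple[float, float, float] = (-200.0, -200.0, -200.0)
    spacing: tuple[float, float, float] = (100.0, 100.0, 100.0)
    shape: tuple[int, int, int] = (8, 8, 8)
    seed: int = 0

    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)


def make_bump_transform(spec: FieldSpec) -> GaussianBumpTransform:
    """The smooth (analytic) transform a gridded field spec samples from."""
    if spec.family != "gaussian_bump":
        raise ValueError("analytic counterpart exists only for gaussian_bump fields")
    rng = np.random.default_rng(spec.seed)
    lo = np.asarray(spec.origin, float)
    hi = spec.upper()
    centers = rng.uniform(lo, hi, size=(spec.n_bumps, 3))
    directions = rng.normal(size=(spec.n_bumps, 3))
    amplitudes = np.full(spec.n_bumps, spec.amplitude)
    sigmas = np.full(spec.n_bumps, spec.sigma)
    return GaussianBumpTransform(centers, directions, amplitudes, sigmas)


def random_bump_transform(
    rng: np.random.Generator,
    n_bumps: int = 3,
    amplitude: float = 20.0,
    sigma: float = 100.0,
    box: float = 500.0,
    near: np.ndarray | None = None,
) -> GaussianBumpTransform:
    """A random guaranteed-diffeomorphic smooth transform (for test suites).

    With ``near`` (an (m, 3) point set, e.g. a curve's knots) bump centers
    are scattered around those points instead of uniformly in the box, so
    the deformation actually overlaps the structure being mapped — as a
    brain registration overlaps the neurons it deforms.
    """
    if near is not None:
        anchors = np.atleast_2d(near)[rng.integers(0, len(near), n_bumps)]
        centers = anchors + rng.normal(scale=sigma / 2, size=(n_bumps, 3))
    else:
        centers = rng.uniform(-box, box, size=(n_bumps, 3))
    directions = rng.normal(size=(n_bumps, 3))
    amplitudes = rng.uniform(0.3, 1.0, n_bumps) * amplitude
    sigmas = rng.uniform(0.7, 1.3, n_bumps) * sigma
    return GaussianBumpTransform(centers, directions, amplitudes, sigmas)


def grid_transform(
    transform: Transform,
    lower: Sequence[float],
    upper: Sequence[float],
    spacing: float = 100.0,
) -> DisplacementField:
    """Sample ``phi(x) - x`` of any transform onto a regular grid.

    Emulates how registration pipelines ship their nonlinear component: a
    displacement field on a regular grid (default 100-micron spacing),
    trilinearly interpolated in between.
    """
    lo = np.asarray(lower, float)
    hi = np.asarray(upper, float)
    shape = np.maximum(2, np.ceil((hi - lo) / spacing).astype(int) + 1)
    axes = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    u = transform.map_points(pts) - pts
    return DisplacementField(lo, np.full(3, float(spacing)), u.reshape(*shape, 3))


def registration_regime_case(
    seed: int,
    curve_length: float = 3000.0,
    knot_period: float = 15.0,
    grid_spacing: float = 100.0,
    amplitude: float = 40.0,
    sigma: float = 300.0,
    n_bumps: int = 4,
) -> tuple[PolylineBranch, DisplacementField, GaussianBumpTransform]:
    """One synthetic branch + gridded registration-scale deformation.

    The regime mirrors the real-data experiment: a millimeters-long branch
    with knots every ~15 microns, deformed by a smooth field with
    displacements of tens of microns varying at the hundreds-of-microns
    scale, shipped as a displacement grid with 100-micron spacing.
    Returns (branch, gridded field, underlying smooth transform).
    """
    rng = np.random.default_rng(seed)
    curve = make_curve(CurveSpec(family="random_fourier", length=curve_length,
                                 amplitude=60.0, seed=seed))
    branch = sample_knots(curve, knot_period)
    smooth = random_bump_transform(rng, n_bumps=n_bumps, amplitude=amplitude,
                                   sigma=sigma, near=branch.knots)
    margin = 3 * sigma
    lo = branch.knots.min(axis=0) - margin
    hi = branch.knots.max(axis=0) + margin
    field = grid_transform(smooth, lo, hi, spacing=grid_spacing)
    return branch, field, smooth


def make_field(spec: FieldSpec) -> DisplacementField:
    """Sample a spec's displacement onto its grid as a DisplacementField.

    The trilinear interpolant inherits the smooth field's gradient bound
    axis-by-axis (divided differences of samples are bounded by the
    continuum gradient), so the gridded map stays a diffeomorphism.
    """
    lo = np.asarray(spec.origin, float)
    spacing = np.asarray(spec.spacing, float)
    shape = tuple(int(s) for s in spec.shape)
    axes = [lo[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)

    if spec.family == "gaussian_bump":
        if spec.amplitude == 0:
            u = np.zeros_like(pts)
        else:
            u = make_bump_transform(spec).displacement(pts)
    elif spec.family == "sinusoidal":
        # u = a * d * sin(2 pi x . k / wavelength); |Du| <= a * 2 pi / wavelength
        rng = np.random.default_rng(spec.seed)
        wavelength = 2 * math.pi * spec.sigma
        if abs(spec.amplitude) * 2 * math.pi / wavelength >= 1:
            raise ValueError("sinusoidal spec violates the sup|Du| < 1 condition")
        d = _random_unit(rng)
        k = _random_unit(rng)
        phase = pts @ k * (2 * math.pi / wavelength)
        u = spec.amplitude * np.sin(phase)[:, None] * d
    elif spec.family == "polynomial_affine_perturbation":
        # u = eps * B x with |eps * B| < 1
        rng = np.random.default_rng(spec.seed)
        B = rng.normal(size=(3, 3))
        B *= spec.amplitude / (np.linalg.norm(B, 2) * spec.sigma)
        if np.linalg.norm(B, 2) >= 1:
            raise ValueError("perturbation spec violates the sup|Du| < 1 condition")
        u = pts @ B.T
    else:
        raise ValueError(f"unknown field family {spec.family!r}")

    values = u.reshape(*shape, 3)
    return DisplacementField(lo, spacing, values)
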