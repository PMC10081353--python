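"""Jet extension of sampled curves and the induced action of diffeomorphisms.

A discretely sampled curve ``(t_i, x_i)`` only records positions, so
mapping it through a nonlinear transformation ``phi`` by moving the knots
("zeroth order mapping") ignores how ``phi`` bends the segments in
between.  Extending each sample to a *jet* — position plus the first ``k``
derivatives of the underlying curve — lets the transformation act on the
derivatives too:

* ``k = 0``:  ``x0 -> phi(x0)``
* ``k = 1``:  additionally ``x1 -> Dphi(x0) x1``
* ``k = 2``:  additionally ``x2 -> Dphi(x0) x2 + D2phi(x0)[x1, x1]``

This is a group action: the identity fixes every jet and composing
transformations equals acting successively.  The mapped jet sequence is
interpolated by a spline of order ``2k + 1`` over the *original* knot
parameters: a first-order (piecewise-linear) spline for ``k = 0`` and a
piecewise cubic Hermite spline for ``k = 1`` (which is generally not
differentiable at the knots, since one-sided derivatives differ there).

Derivatives of a polyline are estimated as one-sided chord slopes, exactly
the one-sided derivatives of the piecewise-linear interpolant; for
arc-length parameterized polylines they are unit vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .swc_io import PolylineBranch, arc_length_parameterize
from .transforms import Transform

__all__ = [
    "JetSequence",
    "MappedCurve",
    "jet_extension_from_polyline",
    "jet_extension_from_curve",
    "apply_jet_action",
    "spline_from_jets",
    "map_zeroth",
    "map_first",
    "map_dense_reference",
    "sample_curve",
    "dense_params",
    "max_deviation",
]


@dataclass
class JetSequence:
    """Time-stamped jet samples ``(t_i, x0_i[, x1_i[, x2_i]])``.

    One-sided derivative provenance is kept explicitly: ``x1_left[i]`` /
    ``x1_right[i]`` are the left/right derivative at ``t_i`` (rows of NaN
    where the side does not exist, i.e. left at the first knot and right at
    the last).  Two-sided (analytic) jets store the same vector on both
    sides.
    """

    order: int
    t: np.ndarray  # (n,)
    x0: np.ndarray  # (n, 3)
    x1_left: np.ndarray | None = None
    x1_right: np.ndarray | None = None
    x2_left: np.ndarray | None = None
    x2_right: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x0 = np.asarray(self.x0, dtype=float)
        if np.any(np.diff(self.t) < 0):
            raise ValueError("jet timestamps must be non-decreasing")
        if self.order >= 1 and (self.x1_left is None or self.x1_right is None):
            raise ValueError("order >= 1 requires first-derivative samples")
        if self.order >= 2 and (self.x2_left is None or self.x2_right is None):
            raise ValueError("order >= 2 requires second-derivative samples")

    @property
    def n(self) -> int:
        return self.t.shape[0]


@dataclass
class MappedCurve:
    """Piecewise-polynomial spline of order ``2k + 1`` over original params.

    For ``order == 0`` this is the first-order spline through ``knots``;
    for ``order == 1`` each segment is a cubic matching the mapped position
    at both ends, the mapped *right* derivative at its left knot and the
    mapped *left* derivative at its right knot.  Position is continuous
    across knots; derivatives need not be.
    """

    order: int
    params: np.ndarray  # (n,)
    knots: np.ndarray  # (n, 3) positions at the knot params
    coeffs: np.ndarray | None = None  # (n-1, 4, 3) cubic coeffs in local s

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        if self.order == 0:
            out = np.empty((tt.size, 3))
            for j in range(3):
                out[:, j] = np.interp(tt, self.params, self.knots[:, j])
        else:
            seg = np.clip(np.searchsorted(self.params, tt, side="right") - 1,
                          0, len(self.params) - 2)
            dt = self.params[seg + 1] - self.params[seg]
            s = (tt - self.params[seg]) / dt
            c = self.coeffs[seg]  # (m, 4, 3)
            # Horner in s
            out = ((c[:, 3] * s[:, None] + c[:, 2]) * s[:, None] + c[:, 1]) \
                * s[:, None] + c[:, 0]
        return out[0] if scalar else out

    def sample(self, spacing: float) -> PolylineBranch:
        return sample_curve(self, spacing)


def jet_extension_from_polyline(branch: PolylineBranch, order: int) -> JetSequence:
    """One-sided jets of the piecewise-linear interpolant of a polyline.

    The right derivative at knot ``i`` is the chord slope
    ``(x_{i+1} - x_i) / (t_{i+1} - t_i)`` and the left derivative is the
    slope of the preceding segment; endpoints carry a single one-sided
    derivative.  For arc-length parameterized branches all slopes are unit
    vectors.  ``order == 2`` is rejected: second derivatives of a
    first-order spline vanish between knots and are undefined at them.
    """
    if order not in (0, 1):
        raise ValueError(
            "polylines support jet orders 0 and 1 only (second derivatives of "
            "a first-order spline are not defined at the knots)"
        )
    t, x = branch.params, branch.knots
    if order == 0:
        return JetSequence(order=0, t=t.copy(), x0=x.copy())
    slopes = np.diff(x, axis=0) / np.diff(t)[:, None]  # (n-1, 3)
    nan = np.full((1, 3), np.nan)
    x1_right = np.vstack([slopes, nan])
    x1_left = np.vstack([nan, slopes])
    return JetSequence(order=1, t=t.copy(), x0=x.copy(),
                       x1_left=x1_left, x1_right=x1_right)


def jet_extension_from_curve(
    position: Callable[[np.ndarray], np.ndarray],
    params: np.ndarray,
    order: int,
    derivative: Callable[[np.ndarray, int], np.ndarray] | None = None,
) -> JetSequence:
    """Two-sided jets of an analytic curve at the given parameters.

    ``position(t)`` maps (m,) params to (m, 3) points and
    ``derivative(t, k)`` returns the k-th derivative similarly; required
    for ``order >= 1``.
    """
    params = np.asarray(params, dtype=float)
    x0 = np.asarray(position(params), dtype=float)
    kw: dict = {}
    if order >= 1:
        if derivative is None:
            raise ValueError("analytic jets of order >= 1 need a derivative callable")
        d1 = np.asarray(derivative(params, 1), dtype=float)
        kw.update(x1_left=d1.copy(), x1_right=d1.copy())
    if order >= 2:
        d2 = np.asarray(derivative(params, 2), dtype=float)
        kw.update(x2_left=d2.copy(), x2_right=d2.copy())
    return JetSequence(order=order, t=params.copy(), x0=x0, **kw)


def apply_jet_action(seq: JetSequence, transform: Transform) -> JetSequence:
    """Act on every jet sample: the order-k prolongation of ``transform``.

    Timestamps and left/right sidedness are unchanged; positions map
    through ``phi``, first derivatives through the Jacobian, second
    derivatives pick up the Hessian correction ``D2phi[x1, x1]``.
    """
    try:
        y0 = transform.map_points(seq.x0)
    except Exception as exc:  # report which sample failed
        for i, p in enumerate(seq.x0):
            try:
                transform.evaluate(p)
            except Exception:
                raise type(exc)(f"sample {i} at t={seq.t[i]:.3f}: {exc}") from None
        raise
    out = JetSequence(order=seq.order, t=seq.t.copy(), x0=y0,
                      x1_left=None if seq.x1_left is None else np.empty_like(seq.x1_left),
                      x1_right=None if seq.x1_right is None else np.empty_like(seq.x1_right),
                      x2_left=None if seq.x2_left is None else np.empty_like(seq.x2_left),
                      x2_right=None if seq.x2_right is None else np.empty_like(seq.x2_right))
    if seq.order == 0:
        return out
    J = transform.jacobian_many(seq.x0)  # (n, 3, 3)
    for src, dst in ((seq.x1_left, out.x1_left), (seq.x1_right, out.x1_right)):
        dst[:] = np.einsum("nij,nj->ni", J, np.nan_to_num(src))
        dst[np.isnan(src[:, 0])] = np.nan
    if seq.order >= 2:
        H = np.array([transform.hessian(p) for p in seq.x0])  # (n, 3, 3, 3)
        for v1, src, dst in ((seq.x1_left, seq.x2_left, out.x2_left),
                             (seq.x1_right, seq.x2_right, out.x2_right)):
            lin = np.einsum("nij,nj->ni", J, np.nan_to_num(src))
            quad = np.einsum("nipq,np,nq->ni", H, np.nan_to_num(v1), np.nan_to_num(v1))
            dst[:] = lin + quad
            dst[np.isnan(src[:, 0])] = np.nan
    return out


def spline_from_jets(seq: JetSequence) -> MappedCurve:
    """Interpolate a jet sequence by a spline of order ``2k + 1``.

    Order 0: piecewise-linear through the positions.  Order 1: per segment
    ``[t_i, t_{i+1}]`` the cubic Hermite piece matching the positions at
    both knots, the right derivative at ``t_i`` and the left derivative at
    ``t_{i+1}`` — four constraints, one cubic.
    """
    if seq.order == 0:
        return MappedCurve(order=0, params=seq.t.copy(), knots=seq.x0.copy())
    if seq.order > 1:
        raise ValueError("spline reconstruction is implemented for orders 0 and 1")
    t, p = seq.t, seq.x0
    n = seq.n
    dt = np.diff(t)[:, None]  # (n-1, 1)
    p0, p1 = p[:-1], p[1:]
    m0 = seq.x1_right[:-1] * dt  # derivative w.r.t. local s in [0, 1]
    m1 = seq.x1_left[1:] * dt
    # cubic a + b s + c s^2 + d s^3 from Hermite data
    a = p0
    b = m0
    c = 3 * (p1 - p0) - 2 * m0 - m1
    d = 2 * (p0 - p1) + m0 + m1
    coeffs = np.stack([a, b, c, d], axis=1)  # (n-1, 4, 3)
    return MappedCurve(order=1, params=t.copy(), knots=p.copy(), coeffs=coeffs)


def map_zeroth(branch: PolylineBranch, transform: Transform) -> MappedCurve:
    """Zeroth order mapping: move the knots, re-join with straight lines."""
    jets = jet_extension_from_polyline(branch, order=0)
    return spline_from_jets(apply_jet_action(jets, transform))


def map_first(branch: PolylineBranch, transform: Transform) -> MappedCurve:
    """First order mapping: move knots and one-sided derivatives, then
    interpolate each segment with a cubic Hermite piece."""
    jets = jet_extension_from_polyline(branch, order=1)
    return spline_from_jets(apply_jet_action(jets, transform))


def dense_params(params: np.ndarray, spacing: float) -> np.ndarray:
    """Parameter grid with steps <= spacing; original params always included."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pieces = []
    for a, b in zip(params[:-1], params[1:]):
        nsub = max(1, int(np.ceil((b - a) / spacing)))
        pieces.append(np.linspace(a, b, nsub + 1)[:-1])
    pieces.append(params[-1:])
    return np.concatenate(pieces)


def map_dense_reference(
    branch: PolylineBranch, transform: Transform, spacing: float = 2.0
) -> PolylineBranch:
    """The experiment's ground truth: densely resample the piecewise-linear
    curve (steps <= ``spacing`` microns, knots retained), map every point.

    The neuron trace is taken at face value as a piecewise-linear curve;
    its continuous image under ``phi`` is approximated by mapping a dense
    sampling of every segment.
    """
    t = dense_params(branch.params, spacing)
    mapped = transform.map_points(branch.evaluate(t))
    return arc_length_parameterize(mapped)


def sample_curve(curve: MappedCurve, spacing: float) -> PolylineBranch:
    """Sample a mapped spline at parameter steps <= ``spacing`` (original
    arc-length parameter; knot params always included)."""
    t = dense_params(curve.params, spacing)
    return arc_length_parameterize(curve.evaluate(t))


def max_deviation(
    branch: PolylineBranch,
    transform: Transform,
    order: int,
    spacing: float = 2.0,
) -> float:
    """Max distance between a mapped spline and the dense ground truth,
    matched by shared parameter values (an upper bound of Frechet distance).
    """
    mapper = map_zeroth if order == 0 else map_first
    g = mapper(branch, transform)
    t = dense_params(branch.params, spacing)
    f = transform.map_points(branch.evaluate(t))
    return float(np.max(np.linalg.norm(g.evaluate(t) - f, axis=1)))
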