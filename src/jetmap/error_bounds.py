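"""Error bounds for zeroth/first order curve mapping, and Frechet evaluation.

For an arc-length parameterized curve ``c`` with knots ``t_i`` mapped
through a diffeomorphism ``phi`` (transformed curve ``f = phi o c``), the
zeroth order mapping produces a first-order spline ``g`` whose deviation
``max_t |f(t) - g(t)|`` admits computable bounds:

* a C^1 bound proportional to ``delta * max_t |Dphi(c(t))|`` where
  ``delta`` is the largest knot spacing (valid for any piecewise-C^1
  curve, but does not vanish for the identity map);
* a piecewise-linear bound, per segment
  ``(1/2) max |Dphi(c(t)) - I| (t_i - t_{i-1}) + |eps_i - eps_{i-1}|``
  with ``eps_i = c(t_i) - phi(c(t_i))``, which goes to zero as ``phi``
  approaches the identity;
* for C^4 curves and transforms, comparable bounds for zeroth and first
  order mapping in terms of derivative maxima ``M_k`` of ``f`` with
  ``h = delta / 2``: the first-order (cubic Hermite) bound
  ``(sqrt(3)/4!) M4 h^4`` and the zeroth-order bound obtained by adding
  ``(sqrt(3)/2) M3 h^3 + (sqrt(3)/2) M2 h^2`` — so the first-order bound
  is always the tighter of the two.

Applying the piecewise-linear bound to a single straight segment of length
``L`` gives an affine-in-length bound ``a L + b`` with
``a = (1/2) sup |Dphi - I|`` and ``b = 2 sup |x - phi(x)|``, whose
inversion yields the maximal knot spacing that keeps mapping error below a
tolerance — a guide for how sparsely a straight neuronal branch may be
traced.

Curves are compared with the discrete Frechet distance, the minimax
distance over monotone couplings of the two knot sequences; it upper
bounds the continuous Frechet distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .swc_io import PolylineBranch
from .transforms import Transform

try:  # optional acceleration of the Frechet dynamic program
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "BoundReport",
    "FrechetResult",
    "AffineLengthBound",
    "bound_c1",
    "bound_piecewise_linear",
    "bound_smooth_orders",
    "affine_bound_in_length",
    "discrete_frechet",
]

SQRT3 = math.sqrt(3.0)


@dataclass
class BoundReport:
    """Per-segment and overall mapping-error bound, in microns."""

    name: str
    per_segment: list[tuple[int, float, float]]  # (index, length, bound)
    overall: float
    constants: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(
            name=self.name,
            overall=self.overall,
            constants=self.constants,
            per_segment=[
                dict(segment=i, length=ln, bound=b) for i, ln, b in self.per_segment
            ],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_segment, columns=["segment", "length", "bound"]
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class FrechetResult:
    """Discrete Frechet distance and (optionally) an optimal coupling."""

    distance: float
    coupling: list[tuple[int, int]] | None = None

    def to_dict(self) -> dict:
        return dict(distance=self.distance, coupling=self.coupling)


def _segment_samples(branch: PolylineBranch, max_step: float = 0.5,
                     per_segment_divisions: int = 50):
    """Dense parameter samples per segment for estimating continuum maxima.

    Steps are at most ``min(max_step, segment_length / per_segment_divisions)``
    per segment.  Returns the flat parameter array and the slice boundaries
    of each segment's samples.
    """
    t = branch.params
    pieces, bounds = [], [0]
    for a, b in zip(t[:-1], t[1:]):
        step = min(max_step, (b - a) / per_segment_divisions)
        nsub = max(1, int(np.ceil((b - a) / step)))
        pieces.append(np.linspace(a, b, nsub + 1))
        bounds.append(bounds[-1] + nsub + 1)
    return np.concatenate(pieces), bounds


def _segment_max_norms(branch: PolylineBranch, transform: Transform,
                       subtract_identity: bool) -> np.ndarray:
    """Per-segment max of |Dphi(c(t))| (or |Dphi - I|) by dense sampling."""
    tt, bounds = _segment_samples(branch)
    pts = branch.evaluate(tt)
    J = transform.jacobian_many(pts)
    if subtract_identity:
        J = J - np.eye(3)
    norms = np.linalg.svd(J, compute_uv=False)[:, 0]
    return np.array([np.max(norms[bounds[i]:bounds[i + 1]])
                     for i in range(len(bounds) - 1)])


def bound_c1(branch: PolylineBranch, transform: Transform,
             prefactor: float = SQRT3) -> BoundReport:
    """C^1 zeroth-order mapping bound ``prefactor * delta_i * max |Dphi|``.

    The Jacobian spectral norm is maximized over each segment by dense
    sampling (steps of at most 0.5 micron).  The overall value is the max
    over segments; it never exceeds ``prefactor * delta * max_t |Dphi|``
    with ``delta`` the largest knot spacing.
    """
    seg_len = np.diff(branch.params)
    seg_max = _segment_max_norms(branch, transform, subtract_identity=False)
    vals = prefactor * seg_len * seg_max
    per = [(i, float(seg_len[i]), float(vals[i])) for i in range(len(vals))]
    return BoundReport("c1_zeroth_order", per, float(np.max(vals)),
                       constants=dict(prefactor=prefactor,
                                      delta=float(np.max(seg_len)),
                                      max_jacobian_norm=float(np.max(seg_max))))


def bound_piecewise_linear(branch: PolylineBranch, transform: Transform) -> BoundReport:
    """Piecewise-linear zeroth-order bound (vanishes as phi -> identity).

    Per segment: ``(1/2) max_seg |Dphi(c(t)) - I| * length +
    |eps_i - eps_{i-1}|`` with ``eps_i = c(t_i) - phi(c(t_i))``.
    """
    seg_len = np.diff(branch.params)
    seg_max = _segment_max_norms(branch, transform, subtract_identity=True)
    eps = branch.knots - transform.map_points(branch.knots)
    deps = np.linalg.norm(np.diff(eps, axis=0), axis=1)
    vals = 0.5 * seg_max * seg_len + deps
    per = [(i, float(seg_len[i]), float(vals[i])) for i in range(len(vals))]
    return BoundReport("piecewise_linear_zeroth_order", per, float(np.max(vals)),
                       constants=dict(max_jacobian_minus_identity=float(np.max(seg_max))))


def _derivative_maxima(position: Callable[[np.ndarray], np.ndarray],
                       params: np.ndarray, transform: Transform,
                       n_fine: int = 201) -> tuple[float, float, float]:
    """(M2, M3, M4): coordinate-wise derivative maxima of f = phi o c.

    The k-th derivatives of each coordinate of ``f`` are estimated on a
    uniform grid with second-order central stencils (exact for cubics, so
    the quartic term genuinely vanishes for polynomial data); M4 is
    maximized over the whole interval, M3 and M2 at the knots (where the
    zeroth-order bound evaluates them).  The grid step trades truncation
    against roundoff amplification by 1/h^4 in the fourth difference.
    """
    a, b = float(params[0]), float(params[-1])
    tt = np.linspace(a, b, n_fine)
    f = transform.map_points(np.asarray(position(tt), dtype=float))
    h = tt[1] - tt[0]
    d2 = (f[2:] - 2 * f[1:-1] + f[:-2]) / h**2
    d3 = (f[4:] - 2 * f[3:-1] + 2 * f[1:-3] - f[:-4]) / (2 * h**3)
    d4 = (f[4:] - 4 * f[3:-1] + 6 * f[2:-2] - 4 * f[1:-3] + f[:-4]) / h**4
    at_knots = lambda arr, t_arr: np.stack(  # noqa: E731
        [np.interp(params, t_arr, arr[:, j]) for j in range(3)], axis=1
    )
    m4 = float(np.max(np.abs(d4)))
    m3 = float(np.max(np.abs(at_knots(d3, tt[2:-2]))))
    m2 = float(np.max(np.abs(at_knots(d2, tt[1:-1]))))
    return m2, m3, m4


def bound_smooth_orders(
    position: Callable[[np.ndarray], np.ndarray],
    params: np.ndarray,
    transform: Transform,
    quartic_prefactor: float = SQRT3 / 24.0,
    lower_prefactor: float = SQRT3 / 2.0,
    n_fine: int = 201,
) -> tuple[BoundReport, BoundReport]:
    """Comparable C^4 bounds for zeroth and first order mapping.

    With ``h = delta / 2`` and ``M_k`` the coordinate-wise maxima of the
    k-th derivatives of ``f = phi o c``:

    * first order (cubic Hermite):  ``quartic_prefactor * M4 * h^4``
      (the classical per-coordinate Hermite bound ``M4 delta^4 / 384``
      combined over three coordinates);
    * zeroth order:  the first-order bound plus
      ``lower_prefactor * (M3 h^3 + M2 h^2)``.

    The first-order bound is structurally the tighter of the two.  Returns
    ``(zeroth_report, first_report)``.
    """
    params = np.asarray(params, dtype=float)
    m2, m3, m4 = _derivative_maxima(position, params, transform, n_fine=n_fine)
    seg_len = np.diff(params)

    def seg_bounds(order: int) -> np.ndarray:
        h = seg_len / 2.0
        b1 = quartic_prefactor * m4 * h**4
        if order == 1:
            return b1
        return b1 + lower_prefactor * (m3 * h**3 + m2 * h**2)

    reports = []
    consts = dict(M2=m2, M3=m3, M4=m4, quartic_prefactor=quartic_prefactor,
                  lower_prefactor=lower_prefactor)
    for order, name in ((0, "smooth_zeroth_order"), (1, "smooth_first_order")):
        vals = seg_bounds(order)
        per = [(i, float(seg_len[i]), float(vals[i])) for i in range(len(vals))]
        reports.append(BoundReport(name, per, float(np.max(vals)), constants=dict(consts)))
    zeroth, first = reports
    assert first.overall <= zeroth.overall + 1e-12
    return zeroth, first


@dataclass
class AffineLengthBound:
    """Zeroth-order mapping error bound ``a L + b`` for a straight segment
    of length ``L`` microns under a fixed transformation."""

    slope: float  # microns of error per micron of segment length
    intercept: float  # microns

    def bound(self, length: float) -> float:
        return self.slope * length + self.intercept

    def max_length(self, tolerance: float) -> float:
        """Largest integer segment length whose bound stays <= tolerance
        (infinity if the bound never exceeds it)."""
        if self.intercept > tolerance:
            return 0.0
        if self.slope <= 0:
            return math.inf
        return float(math.floor((tolerance - self.intercept) / self.slope))

    def to_dict(self) -> dict:
        return dict(slope=self.slope, intercept=self.intercept)


def affine_bound_in_length(
    transform: Transform,
    lower: Sequence[float] | None = None,
    upper: Sequence[float] | None = None,
    n_per_axis: int = 8,
) -> AffineLengthBound:
    """Fit the ``a L + b`` bound over a sample grid of the domain.

    ``a = (1/2) max |Dphi(x) - I|`` and ``b = 2 max |x - phi(x)|`` over the
    grid, so the piecewise-linear bound applied to one straight segment of
    length ``L`` is at most ``a L + b``.
    """
    from .transforms import DisplacementField, _sample_grid, _spectral_norms

    if lower is None or upper is None:
        if not isinstance(transform, DisplacementField):
            raise ValueError("lower/upper bounds required for non-gridded transforms")
        lower, upper = transform.origin, transform.upper
    pts = _sample_grid(np.asarray(lower, float), np.asarray(upper, float), n_per_axis)
    J = transform.jacobian_many(pts) - np.eye(3)
    a = 0.5 * float(np.max(_spectral_norms(J)))
    b = 2.0 * float(np.max(np.linalg.norm(pts - transform.map_points(pts), axis=1)))
    return AffineLengthBound(slope=a, intercept=b)


def _frechet_dp_python(d: np.ndarray) -> np.ndarray:
    n, m = d.shape
    dp = np.empty_like(d)
    dp[0, 0] = d[0, 0]
    for i in range(1, n):
        dp[i, 0] = max(dp[i - 1, 0], d[i, 0])
    for j in range(1, m):
        dp[0, j] = max(dp[0, j - 1], d[0, j])
    for i in range(1, n):
        for j in range(1, m):
            best = dp[i - 1, j]
            if dp[i, j - 1] < best:
                best = dp[i, j - 1]
            if dp[i - 1, j - 1] < best:
                best = dp[i - 1, j - 1]
            dp[i, j] = best if best > d[i, j] else d[i, j]
    return dp


if _HAVE_NUMBA:
    _frechet_dp = _njit(cache=False)(_frechet_dp_python)
else:  # pragma: no cover
    _frechet_dp = _frechet_dp_python


def discrete_frechet(
    p: PolylineBranch | np.ndarray,
    q: PolylineBranch | np.ndarray,
    return_coupling: bool = False,
) -> FrechetResult:
    """Discrete Frechet distance between two point sequences.

    Dynamic program over the coupling lattice minimizing the maximal
    pointwise distance along monotone couplings.  Symmetric in its
    arguments; zero iff the sequences couple pointwise at distance zero.
    """
    P = p.knots if isinstance(p, PolylineBranch) else np.atleast_2d(np.asarray(p, float))
    Q = q.knots if isinstance(q, PolylineBranch) else np.atleast_2d(np.asarray(q, float))
    if P.size == 0 or Q.size == 0:
        raise ValueError("discrete_frechet requires non-empty point sequences")
    d = cdist(P, Q)
    dp = _frechet_dp(d)
    coupling = None
    if return_coupling:
        i, j = d.shape[0] - 1, d.shape[1] - 1
        coupling = [(i, j)]
        while i > 0 or j > 0:
            options = []
            if i > 0 and j > 0:
                options.append((dp[i - 1, j - 1], i - 1, j - 1))
            if i > 0:
                options.append((dp[i - 1, j], i - 1, j))
            if j > 0:
                options.append((dp[i, j - 1], i, j - 1))
            _, i, j = min(options)
            coupling.append((i, j))
        coupling.reverse()
    return FrechetResult(distance=float(dp[-1, -1]), coupling=coupling)
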