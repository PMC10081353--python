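"""Coordinate transformations phi: R^3 -> R^3 with evaluable derivatives.

A :class:`Transform` exposes the map ``phi(x)``, its Jacobian ``Dphi(x)``
and (where the transform is C^2) the Hessian ``D2phi(x)``.  Concrete kinds:

* :class:`AffineTransform` — ``phi(x) = A x + b``;
* :class:`AnalyticTransform` — arbitrary closed-form map, with
  finite-difference fallbacks for missing derivatives;
* :class:`DisplacementField` — ``phi(x) = x + u(x)`` with ``u`` stored on a
  regular grid and trilinearly interpolated (the representation typically
  produced by nonlinear image registration, e.g. the LDDMM component of a
  brain-to-atlas registration);
* :class:`CompositeTransform` — ordered composition with chain-rule
  derivatives.

Jacobian spectral norms, ``log det Dphi`` (the finite-time Lyapunov
exponent) and displacement statistics over a field's grid are computed by
:func:`field_statistics`; :func:`validate_diffeomorphism` checks the
orientation-preserving-diffeomorphism preconditions that the error bounds
rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Transform",
    "AffineTransform",
    "AnalyticTransform",
    "DisplacementField",
    "CompositeTransform",
    "OutOfDomainError",
    "identity",
    "validate_diffeomorphism",
    "field_statistics",
    "load_transform",
]


class OutOfDomainError(ValueError):
    """A point lies outside the transform's declared domain."""


def _fd_step(x: np.ndarray) -> float:
    # central-difference step for micron-scale coordinates
    return max(1e-3, 1e-6 * float(np.max(np.abs(x))))


class Transform:
    """Base transform contract: ``evaluate``, ``jacobian``, ``hessian``.

    Subclasses override the single-point methods; ``map_points`` /
    ``jacobian_many`` default to loops and are overridden where a
    vectorized path exists.
    """

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """3x3 Jacobian; default is central finite differences."""
        x = np.asarray(x, dtype=float)
        h = _fd_step(x)
        J = np.empty((3, 3))
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            J[:, j] = (self.evaluate(x + e) - self.evaluate(x - e)) / (2 * h)
        return J

    def hessian(self, x: np.ndarray) -> np.ndarray:
        """D2phi as a (3, 3, 3) array, ``H[i, p, q] = d2 phi^i / dx_p dx_q``.

        Default: central finite differences of the Jacobian, symmetrized in
        the last two indices.
        """
        x = np.asarray(x, dtype=float)
        h = 10 * _fd_step(x)
        H = np.empty((3, 3, 3))
        for q in range(3):
            e = np.zeros(3)
            e[q] = h
            H[:, :, q] = (self.jacobian(x + e) - self.jacobian(x - e)) / (2 * h)
        return 0.5 * (H + np.transpose(H, (0, 2, 1)))

    def map_points(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.array([self.evaluate(p) for p in points])

    def jacobian_many(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.array([self.jacobian(p) for p in points])

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.evaluate(np.asarray(x, dtype=float))


@dataclass
class AffineTransform(Transform):
    """``phi(x) = A x + b`` with invertible ``A`` (microns in, microns out)."""

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-300:
            raise ValueError("affine matrix must be invertible")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(x, dtype=float) + self.offset

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        return self.matrix.copy()

    def hessian(self, x: np.ndarray) -> np.ndarray:
        return np.zeros((3, 3, 3))

    def map_points(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.matrix.T + self.offset

    def jacobian_many(self, points: np.ndarray) -> np.ndarray:
        n = np.atleast_2d(points).shape[0]
        return np.broadcast_to(self.matrix, (n, 3, 3)).copy()


def identity() -> AffineTransform:
    return AffineTransform(np.eye(3), np.zeros(3))


class AnalyticTransform(Transform):
    """A closed-form map with optional closed-form Jacobian / Hessian.

    ``func`` maps a (3,) point to a (3,) point.  Missing derivative
    callables fall back to central finite differences.
    """

    def __init__(
        self,
        func: Callable[[np.ndarray], np.ndarray],
        jac: Callable[[np.ndarray], np.ndarray] | None = None,
        hess: Callable[[np.ndarray], np.ndarray] | None = None,
    ):
        self._func = func
        self._jac = jac
        self._hess = hess

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self._func(np.asarray(x, dtype=float)), dtype=float)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        if self._jac is not None:
            return np.asarray(self._jac(np.asarray(x, dtype=float)), dtype=float)
        return super().jacobian(x)

    def hessian(self, x: np.ndarray) -> np.ndarray:
        if self._hess is not None:
            return np.asarray(self._hess(np.asarray(x, dtype=float)), dtype=float)
        return super().hessian(x)


class DisplacementField(Transform):
    """``phi(x) = x + u(x)`` with ``u`` sampled on a regular 3D grid.

    ``values[i, j, k]`` is the displacement vector at grid node
    ``origin + (i, j, k) * spacing``; between nodes ``u`` is trilinearly
    interpolated, so the Jacobian is exact (analytic gradient of the
    trilinear interpolant) within each cell.  Points on a cell face use the
    gradient of the cell with larger indices; on the top boundary the last
    cell is used.

    Points outside the grid raise :class:`OutOfDomainError` unless
    ``padding=True``, in which case the displacement is zero outside.
    """

    def __init__(
        self,
        origin: Sequence[float],
        spacing: Sequence[float],
        values: np.ndarray,
        padding: bool = False,
    ):
        self.origin = np.asarray(origin, dtype=float).reshape(3)
        self.spacing = np.asarray(spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[3] != 3:
            raise ValueError("values must have shape (nx, ny, nz, 3)")
        if min(self.values.shape[:3]) < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        self.padding = padding
        self.shape = np.array(self.values.shape[:3])

    @property
    def upper(self) -> np.ndarray:
        return self.origin + (self.shape - 1) * self.spacing

    def grid_points(self) -> np.ndarray:
        """(N, 3) coordinates of all grid nodes (C order)."""
        axes = [self.origin[d] + self.spacing[d] * np.arange(self.shape[d]) for d in range(3)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def _locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell index (larger-indices convention on faces) and local coords."""
        g = (points - self.origin) / self.spacing  # grid coordinates
        inside = np.all((g >= -1e-12) & (g <= self.shape - 1 + 1e-12), axis=1)
        if not self.padding and not np.all(inside):
            bad = np.flatnonzero(~inside)
            raise OutOfDomainError(
                f"{bad.size} point(s) outside the field grid (first index {bad[0]})"
            )
        # face convention: a point with integer grid coordinate belongs to the
        # cell with larger indices, i.e. cell = floor(g); clamp the top face.
        cell = np.floor(g).astype(int)
        cell = np.clip(cell, 0, self.shape - 2)
        frac = g - cell
        return cell, frac, inside

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated u at (..., 3) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cell, frac, inside = self._locate(pts)
        out = np.zeros((pts.shape[0], 3))
        ii, jj, kk = cell[:, 0], cell[:, 1], cell[:, 2]
        fx, fy, fz = frac[:, 0:1], frac[:, 1:2], frac[:, 2:3]
        v = self.values
        c000 = v[ii, jj, kk]
        c100 = v[ii + 1, jj, kk]
        c010 = v[ii, jj + 1, kk]
        c001 = v[ii, jj, kk + 1]
        c110 = v[ii + 1, jj + 1, kk]
        c101 = v[ii + 1, jj, kk + 1]
        c011 = v[ii, jj + 1, kk + 1]
        c111 = v[ii + 1, jj + 1, kk + 1]
        interp = (
            c000 * (1 - fx) * (1 - fy) * (1 - fz)
            + c100 * fx * (1 - fy) * (1 - fz)
            + c010 * (1 - fx) * fy * (1 - fz)
            + c001 * (1 - fx) * (1 - fy) * fz
            + c110 * fx * fy * (1 - fz)
            + c101 * fx * (1 - fy) * fz
            + c011 * (1 - fx) * fy * fz
            + c111 * fx * fy * fz
        )
        out[inside] = interp[inside]
        return out if np.asarray(points).ndim > 1 else out[0]

    def displacement_jacobian_many(self, points: np.ndarray) -> np.ndarray:
        """(n, 3, 3) array Du, the exact in-cell gradient of the interpolant."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cell, frac, inside = self._locate(pts)
        ii, jj, kk = cell[:, 0], cell[:, 1], cell[:, 2]
        fx, fy, fz = frac[:, 0:1], frac[:, 1:2], frac[:, 2:3]
        v = self.values
        c000 = v[ii, jj, kk]
        c100 = v[ii + 1, jj, kk]
        c010 = v[ii, jj + 1, kk]
        c001 = v[ii, jj, kk + 1]
        c110 = v[ii + 1, jj + 1, kk]
        c101 = v[ii + 1, jj, kk + 1]
        c011 = v[ii, jj + 1, kk + 1]
        c111 = v[ii + 1, jj + 1, kk + 1]
        # d/dfx of the trilinear form, etc.
        dux = (
            (c100 - c000) * (1 - fy) * (1 - fz)
            + (c110 - c010) * fy * (1 - fz)
            + (c101 - c001) * (1 - fy) * fz
            + (c111 - c011) * fy * fz
        )
        duy = (
            (c010 - c000) * (1 - fx) * (1 - fz)
            + (c110 - c100) * fx * (1 - fz)
            + (c011 - c001) * (1 - fx) * fz
            + (c111 - c101) * fx * fz
        )
        duz = (
            (c001 - c000) * (1 - fx) * (1 - fy)
            + (c101 - c100) * fx * (1 - fy)
            + (c011 - c010) * (1 - fx) * fy
            + (c111 - c110) * fx * fy
        )
        Du = np.stack(
            [dux / self.spacing[0], duy / self.spacing[1], duz / self.spacing[2]],
            axis=2,
        )  # (n, 3 components, 3 derivative axes)
        Du[~inside] = 0.0
        return Du

    # -- Transform interface -------------------------------------------------

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x + self.displacement(x)

    def map_points(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points + self.displacement(points)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        return self.jacobian_many(np.atleast_2d(x))[0]

    def jacobian_many(self, points: np.ndarray) -> np.ndarray:
        Du = self.displacement_jacobian_many(points)
        return np.eye(3) + Du

    def hessian(self, x: np.ndarray) -> np.ndarray:
        """In-cell Hessian of the trilinear interpolant (mixed partials only)."""
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        cell, frac, inside = self._locate(pts)
        i, j, k = cell[0]
        fx, fy, fz = frac[0]
        if not inside[0]:
            return np.zeros((3, 3, 3))
        v = self.values
        d = lambda a, b, c: v[i + a, j + b, k + c]  # noqa: E731
        # u = trilinear => d2u/dx2 = 0; mixed partials are linear in the
        # remaining coordinate.
        uxy = (
            (d(1, 1, 0) - d(0, 1, 0) - d(1, 0, 0) + d(0, 0, 0)) * (1 - fz)
            + (d(1, 1, 1) - d(0, 1, 1) - d(1, 0, 1) + d(0, 0, 1)) * fz
        ) / (self.spacing[0] * self.spacing[1])
        uxz = (
            (d(1, 0, 1) - d(0, 0, 1) - d(1, 0, 0) + d(0, 0, 0)) * (1 - fy)
            + (d(1, 1, 1) - d(0, 1, 1) - d(1, 1, 0) + d(0, 1, 0)) * fy
        ) / (self.spacing[0] * self.spacing[2])
        uyz = (
            (d(0, 1, 1) - d(0, 0, 1) - d(0, 1, 0) + d(0, 0, 0)) * (1 - fx)
            + (d(1, 1, 1) - d(1, 0, 1) - d(1, 1, 0) + d(1, 0, 0)) * fx
        ) / (self.spacing[1] * self.spacing[2])
        H = np.zeros((3, 3, 3))
        H[:, 0, 1] = H[:, 1, 0] = uxy
        H[:, 0, 2] = H[:, 2, 0] = uxz
        H[:, 1, 2] = H[:, 2, 1] = uyz
        return H

    # -- persistence ----------------------------------------------------------

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("displacement_field")
            g.create_dataset("origin", data=self.origin)
            g.create_dataset("spacing", data=self.spacing)
            g.create_dataset("values", data=self.values)

    @classmethod
    def from_hdf5(cls, path: str | Path, padding: bool = False) -> "DisplacementField":
        with h5py.File(path, "r") as f:
            g = f["displacement_field"] if "displacement_field" in f else f
            return cls(g["origin"][()], g["spacing"][()], g["values"][()], padding=padding)

    def to_json(self, path: str | Path) -> None:
        """Plain-text sidecar variant for tiny fixtures."""
        obj = dict(
            kind="displacement_field",
            origin=self.origin.tolist(),
            spacing=self.spacing.tolist(),
            shape=[int(s) for s in self.shape],
            values=self.values.ravel().tolist(),
        )
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json_dict(cls, obj: dict, padding: bool = False) -> "DisplacementField":
        values = np.asarray(obj["values"], dtype=float).reshape(*obj["shape"], 3)
        return cls(obj["origin"], obj["spacing"], values, padding=padding)


class CompositeTransform(Transform):
    """Ordered composition ``phi_n o ... o phi_1`` (phi_1 applied first)."""

    def __init__(self, transforms: Sequence[Transform]):
        if not transforms:
            raise ValueError("need at least one transform")
        self.transforms = list(transforms)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        y = np.asarray(x, dtype=float)
        for t in self.transforms:
            y = t.evaluate(y)
        return y

    def map_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        for t in self.transforms:
            pts = t.map_points(pts)
        return pts

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        y = np.asarray(x, dtype=float)
        J = np.eye(3)
        for t in self.transforms:
            J = t.jacobian(y) @ J
            y = t.evaluate(y)
        return J

    def hessian(self, x: np.ndarray) -> np.ndarray:
        # chain rule for second derivatives of psi o phi:
        # D2(psi o phi)[p, q] = Dpsi . D2phi[p, q] + D2psi[Dphi e_p, Dphi e_q]
        x = np.asarray(x, dtype=float)
        if len(self.transforms) == 1:
            return self.transforms[0].hessian(x)
        inner = CompositeTransform(self.transforms[:-1]) if len(self.transforms) > 2 \
            else self.transforms[0]
        outer = self.transforms[-1]
        y = inner.evaluate(x)
        Ji = inner.jacobian(x)
        Hi = inner.hessian(x)
        Jo = outer.jacobian(y)
        Ho = outer.hessian(y)
        H = np.einsum("im,mpq->ipq", Jo, Hi) + np.einsum("imn,mp,nq->ipq", Ho, Ji, Ji)
        return H


@dataclass
class DiffeomorphismReport:
    """Sampled check of the orientation-preserving diffeomorphism surrogate."""

    min_jacobian_det: float
    max_jacobian_norm: float
    sup_displacement_gradient: float | None
    n_samples: int
    passed: bool

    def to_dict(self) -> dict:
        return dict(
            min_jacobian_det=self.min_jacobian_det,
            max_jacobian_norm=self.max_jacobian_norm,
            sup_displacement_gradient=self.sup_displacement_gradient,
            n_samples=self.n_samples,
            passed=self.passed,
        )


def _spectral_norms(mats: np.ndarray) -> np.ndarray:
    """Largest singular value of each (3,3) matrix in a (n,3,3) stack."""
    return np.linalg.svd(mats, compute_uv=False)[:, 0]


def _sample_grid(lo: np.ndarray, hi: np.ndarray, n_per_axis: int) -> np.ndarray:
    axes = [np.linspace(lo[d], hi[d], n_per_axis) for d in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def validate_diffeomorphism(
    transform: Transform,
    lower: Sequence[float] | None = None,
    upper: Sequence[float] | None = None,
    n_per_axis: int = 8,
) -> DiffeomorphismReport:
    """Sample-based check that ``transform`` behaves like a diffeomorphism.

    Reports min ``det Dphi``, max spectral norm ``|Dphi|`` and, for
    displacement fields, ``sup |Du|``.  Fails if ``det <= 0`` anywhere or if
    ``sup |Du| >= 1`` (a sufficient condition for ``x + u(x)`` to be
    injective is ``sup |Du| < 1``).  For displacement fields the bounds
    default to the grid box.
    """
    if lower is None or upper is None:
        if not isinstance(transform, DisplacementField):
            raise ValueError("lower/upper bounds required for non-gridded transforms")
        lower, upper = transform.origin, transform.upper
    pts = _sample_grid(np.asarray(lower, float), np.asarray(upper, float), n_per_axis)
    J = transform.jacobian_many(pts)
    dets = np.linalg.det(J)
    norms = _spectral_norms(J)
    sup_du = None
    if isinstance(transform, DisplacementField):
        sup_du = float(np.max(_spectral_norms(transform.displacement_jacobian_many(pts))))
    passed = bool(np.min(dets) > 0 and (sup_du is None or sup_du < 1.0))
    return DiffeomorphismReport(
        min_jacobian_det=float(np.min(dets)),
        max_jacobian_norm=float(np.max(norms)),
        sup_displacement_gradient=sup_du,
        n_samples=pts.shape[0],
        passed=passed,
    )


def field_statistics(
    field: DisplacementField,
    tangent: Sequence[float] = (1.0, 1.0, 1.0),
) -> tuple[pd.DataFrame, dict]:
    """Per-grid-node deformation statistics and histogram summaries.

    For every grid node reports the displacement magnitude ``|u|``,
    ``log det Dphi`` (local volume expansion/compression), the Jacobian
    spectral norm ``|Dphi|`` (whose log is the finite-time Lyapunov
    exponent), ``|Dphi - I|`` and the tangent displacement
    ``|Dphi v - v|`` for the supplied tangent vector ``v`` (default
    ``(1, 1, 1)^T``).
    """
    v = np.asarray(tangent, dtype=float).reshape(3)
    pts = field.grid_points()
    u = field.displacement(pts)
    J = field.jacobian_many(pts)
    df = pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "displacement_magnitude": np.linalg.norm(u, axis=1),
            "log_jacobian_det": np.log(np.linalg.det(J)),
            "jacobian_norm": _spectral_norms(J),
            "jacobian_minus_identity_norm": _spectral_norms(J - np.eye(3)),
            "tangent_displacement": np.linalg.norm(J @ v - v, axis=1),
        }
    )
    summary = {}
    for col in df.columns[3:]:
        counts, edges = np.histogram(df[col], bins=20)
        summary[col] = dict(
            mean=float(df[col].mean()),
            median=float(df[col].median()),
            max=float(df[col].max()),
            hist_counts=counts.tolist(),
            hist_edges=edges.tolist(),
        )
    return df, summary


def load_transform(path: str | Path, nonlinear_only: bool = False,
                   padding: bool = False) -> Transform:
    """Load a transform from a JSON or HDF5 file.

    JSON kinds: ``{"matrix": [9 numbers row-major], "offset": [3]}`` for an
    affine; ``{"kind": "displacement_field", ...}`` for a tiny field;
    ``{"affine": {...}, "field": "path-or-inline"}`` for an ordered
    composition (field applied first).  ``.h5``/``.hdf5`` files hold a
    displacement field.  ``nonlinear_only=True`` drops the affine component
    of a composition, keeping only the displacement field.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        return DisplacementField.from_hdf5(path, padding=padding)
    obj = json.loads(path.read_text())
    return _transform_from_json(obj, path.parent, nonlinear_only, padding)


def _transform_from_json(obj: dict, base: Path, nonlinear_only: bool,
                         padding: bool) -> Transform:
    if "matrix" in obj and "affine" not in obj:
        return AffineTransform(np.asarray(obj["matrix"], float).reshape(3, 3),
                               obj.get("offset", np.zeros(3)))
    if obj.get("kind") == "displacement_field":
        return DisplacementField.from_json_dict(obj, padding=padding)
    if "affine" in obj or "field" in obj:
        parts: list[Transform] = []
        if "field" in obj:
            fld = obj["field"]
            if isinstance(fld, str):
                parts.append(load_transform(base / fld, padding=padding))
            else:
                parts.append(DisplacementField.from_json_dict(fld, padding=padding))
        if "affine" in obj and not nonlinear_only:
            aff = obj["affine"]
            parts.append(AffineTransform(np.asarray(aff["matrix"], float).reshape(3, 3),
                                         aff.get("offset", np.zeros(3))))
        if len(parts) == 1:
            return parts[0]
        return CompositeTransform(parts)
    raise ValueError("unrecognized transform JSON schema")
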