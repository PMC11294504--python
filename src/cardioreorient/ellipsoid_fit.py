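"""Algebraic ellipsoid fitting of the myocardial point cloud.

The left-ventricular myocardium is modeled by the general quadric

    a1 x^2 + a2 y^2 + a3 z^2 + a4 xy + a5 xz + a6 yz + a7 x + a8 y + a9 z + a10 = 0

fitted by linear least squares — either with the constant coefficient pinned
(a10 = -1, normal equations) or as the homogeneous null-space problem solved
by SVD with a unit-norm constraint.  The ventricle's long axis is the major
axis of this quadric; two deflection angles (alpha about x, beta about y)
take the body z-axis onto it and drive the subsequent rotation to short-axis
orientation.

Two angle extractors are provided: closed-form half-angle arctangent
formulas (exact for single-axis tilts under the unit-norm coefficient
convention in which the sqrt(2) cross-term factors arise) and an
eigen-decomposition of the quadratic form, which is convention-free, handles
combined tilts exactly, and is the pipeline default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

SQRT2 = np.sqrt(2.0)


@dataclass
class EllipsoidParams:
    """Quadric coefficients a1..a10 with their normalization and fit residual.

    Coefficients are stored in the plain polynomial convention (the cross
    terms multiply xy, xz, yz directly).  ``normalization`` records how the
    scale ambiguity was fixed: ``"a10=-1"`` or ``"unit-norm"``.
    ``residual`` is the RMS algebraic residual over the fit points.
    """

    coeffs: np.ndarray
    normalization: str
    residual: float

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.coeffs.shape != (10,):
            raise ValueError("need exactly 10 quadric coefficients")
        if not np.any(self.coeffs):
            raise ValueError("coefficient vector must be non-zero")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")

    @property
    def a(self) -> np.ndarray:
        return self.coeffs

    def quadratic_form(self) -> np.ndarray:
        """Symmetric 3x3 matrix Q with x^T Q x reproducing the 2nd-order terms."""
        a1, a2, a3, a4, a5, a6 = self.coeffs[:6]
        return np.array(
            [
                [a1, a4 / 2.0, a5 / 2.0],
                [a4 / 2.0, a2, a6 / 2.0],
                [a5 / 2.0, a6 / 2.0, a3],
            ]
        )


@dataclass(frozen=True)
class DeflectionAngles:
    """Long-axis deflection: alpha about the x-axis, beta about the y-axis (degrees)."""

    alpha: float
    beta: float
    method: str = "eigen"

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("angles must be finite")


def _design_matrix(pts: np.ndarray) -> np.ndarray:
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    return np.column_stack([x * x, y * y, z * z, x * y, x * z, y * z, x, y, z, np.ones_like(x)])


def _check_points(pts: np.ndarray, n_min: int) -> np.ndarray:
    pts = np.asarray(pts, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array")
    if len(pts) < n_min:
        raise ValueError(f"need at least {n_min} points, got {len(pts)}")
    return pts


def fit_quadric_lls(points: np.ndarray) -> EllipsoidParams:
    """Least-squares quadric with the constant coefficient pinned to -1.

    Solves ``D[:, :9] c = 1`` for the nine free coefficients, i.e. the
    surface ``sum(c_i m_i(x)) - 1 = 0``.  Requires >= 9 non-degenerate
    points; raises on a rank-deficient design (coplanar input).
    """
    pts = _check_points(points, 9)
    D = _design_matrix(pts)[:, :9]
    rhs = np.ones(len(pts))
    sol, _, rank, _ = np.linalg.lstsq(D, rhs, rcond=None)
    if rank < 9:
        raise ValueError("degenerate point cloud: design matrix is rank-deficient")
    coeffs = np.append(sol, -1.0)
    resid = float(np.sqrt(np.mean((D @ sol - rhs) ** 2)))
    return EllipsoidParams(coeffs, "a10=-1", resid)


def fit_quadric_lls_svd(points: np.ndarray, ambiguity_rtol: float = 1e-9) -> EllipsoidParams:
    """Homogeneous quadric fit: smallest right singular vector, unit norm.

    The full 10-column design matrix is decomposed; the coefficient vector is
    the right singular vector of the smallest singular value, with the sign
    fixed so a1 > 0.  Near-equal smallest singular values indicate an
    ambiguous fit and trigger a warning.
    """
    pts = _check_points(points, 10)
    D = _design_matrix(pts)
    _, s, Vt = np.linalg.svd(D, full_matrices=False)
    if s[-2] > 0 and (s[-2] - s[-1]) <= ambiguity_rtol * s[0]:
        warnings.warn("ambiguous quadric fit: two smallest singular values nearly equal")
    coeffs = Vt[-1]
    if coeffs[0] < 0:
        coeffs = -coeffs
    resid = float(np.sqrt(np.mean((D @ coeffs) ** 2)))
    return EllipsoidParams(coeffs.copy(), "unit-norm", resid)


def angles_closed_form(params: EllipsoidParams, literal_xy_form: bool = False) -> DeflectionAngles:
    """Closed-form half-angle deflection angles from the quadric coefficients.

    alpha = 1/2 atan2(sqrt(2) b6, a2 - a3) with b6 the yz coefficient in the
    unit-norm convention (b6 = a6 / sqrt(2) for the plain polynomial stored
    here), which is exact for a pure tilt about x.  The companion beta
    formula is exact for a pure tilt about y when built from the xz
    coefficient against a1 - a3; ``literal_xy_form`` instead evaluates the
    xy-based variant beta = 1/2 atan2(sqrt(2) b4, a2 - a1), which degenerates
    for pure y-tilts (the xy coefficient vanishes identically) and is kept
    only for comparison.  Combined two-axis tilts mix the cross terms, so
    these formulas are small-angle approximations there; ``angles_eigen`` is
    the general route.
    """
    a = params.coeffs
    # sqrt(2)*(a6/sqrt(2)) == a6: the printed sqrt(2) cancels the convention change
    alpha = 0.5 * np.degrees(np.arctan2(SQRT2 * (a[5] / SQRT2), a[1] - a[2]))
    if literal_xy_form:
        beta = 0.5 * np.degrees(np.arctan2(SQRT2 * (a[3] / SQRT2), a[1] - a[0]))
    else:
        beta = 0.5 * np.degrees(np.arctan2(-SQRT2 * (a[4] / SQRT2), a[0] - a[2]))
    return DeflectionAngles(float(alpha), float(beta), method="closed-form")


def angles_eigen(params: EllipsoidParams, degeneracy_rtol: float = 0.01) -> DeflectionAngles:
    """Deflection angles from the principal axes of the quadratic form.

    The long axis is the eigenvector of the smallest eigenvalue (largest
    semi-axis) of the sign-normalized quadratic form; the angles are the
    exact two-rotation factorization u = H2(beta) H1(alpha) e_z of that unit
    axis u (taken with u_z >= 0):

        beta  = atan2(u_x, u_z)
        alpha = atan2(-u_y, hypot(u_x, u_z))

    so that positive alpha tips the apex toward -y and positive beta toward
    +x, matching the rotation matrices that undo the tilt.  Raises TypeError
    for a non-ellipsoidal (indefinite) form; a near-spherical fit (two
    smallest eigenvalues within ``degeneracy_rtol``) returns zero angles
    with a warning.
    """
    Q = params.quadratic_form()
    evals, evecs = np.linalg.eigh(Q)
    if np.all(evals < 0):
        evals, evecs = -evals[::-1], evecs[:, ::-1]
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
    if np.any(evals <= 0):
        raise TypeError("quadric is not an ellipsoid (quadratic form not definite)")
    if (evals[1] - evals[0]) <= degeneracy_rtol * evals[1]:
        warnings.warn("near-spherical quadric: long axis degenerate, returning zero angles")
        return DeflectionAngles(0.0, 0.0, method="eigen")
    u = evecs[:, 0]
    if u[2] < 0:
        u = -u
    beta = np.degrees(np.arctan2(u[0], u[2]))
    alpha = np.degrees(np.arctan2(-u[1], np.hypot(u[0], u[2])))
    return DeflectionAngles(float(alpha), float(beta), method="eigen")
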