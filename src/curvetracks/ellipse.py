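"""Direct least-squares ellipse fitting and elliptic arc geometry.

The fit is the numerically stable direct conic least-squares method
(scatter-matrix block decomposition with the ellipse constraint
4*a*c - b^2 = 1 built into the eigenproblem), so the result is always a
genuine ellipse when one exists, with no iteration and no initial guess.

An ellipse is parametrized as

    p(theta) = center + R(phi) @ (A cos(theta), B sin(theta)),  A >= B > 0,

with theta increasing counterclockwise.  Arc lengths are computed by
adaptive quadrature of sqrt(A^2 sin^2 + B^2 cos^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares

from .exceptions import DegenerateFitError, UndefinedAngleError

__all__ = ["EllipseParams", "fit_ellipse", "arc_length", "arc_coordinate",
           "foot_parameter"]


@dataclass(frozen=True)
class EllipseParams:
    """A fitted slice ellipse: center, semi-axes (A >= B), orientation."""
    center: np.ndarray
    semi_axes: tuple  # (A, B), A >= B > 0
    phi: float        # orientation of the A axis, mod pi
    slice_coord: float = np.nan
    residual: float = np.nan  # RMS approximate geometric distance

    @property
    def A(self):
        return self.semi_axes[0]

    @property
    def B(self):
        return self.semi_axes[1]

    def point(self, theta):
        theta = np.asarray(theta, dtype=float)
        c, s = np.cos(self.phi), np.sin(self.phi)
        x = self.A * np.cos(theta)
        y = self.B * np.sin(theta)
        return np.stack([self.center[0] + c * x - s * y,
                         self.center[1] + s * x + c * y], axis=-1)

    def perimeter(self):
        return arc_length(self, 0.0, 2.0 * np.pi)

    def world_angle(self, theta):
        """Polar angle (about the center) of the point at parameter theta."""
        p = self.point(theta) - self.center
        return np.arctan2(p[..., 1], p[..., 0])

    def parameter_at_world_angle(self, psi):
        """Parameter theta whose point lies in polar direction psi."""
        d = np.asarray([np.cos(psi - self.phi), np.sin(psi - self.phi)])
        return float(np.arctan2(d[1] / self.B, d[0] / self.A))


def foot_parameters_family(cx, cy, A, B, phi, pts: np.ndarray) -> np.ndarray:
    """Vectorized nearest-point parameters, one ellipse per point.

    All ellipse parameter arguments broadcast against ``pts`` rows, so
    this serves both a single ellipse and a smoothly varying family.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    dx = pts[:, 0] - cx
    dy = pts[:, 1] - cy
    c, s = np.cos(phi), np.sin(phi)
    qx = c * dx + s * dy
    qy = -s * dx + c * dy
    def _newton(t):
        for _ in range(50):
            st, ct = np.sin(t), np.cos(t)
            f = (A * A - B * B) * st * ct - qx * A * st + qy * B * ct
            fp = (A * A - B * B) * (ct * ct - st * st) \
                - qx * A * ct - qy * B * st
            step = np.where(fp != 0, f / fp, 0.0)
            step = np.clip(step, -0.5, 0.5)
            t = t - step
            if np.max(np.abs(step)) < 1e-13:
                break
        return t

    def _d2(t):
        return (A * np.cos(t) - qx) ** 2 + (B * np.sin(t) - qy) ** 2

    t = _newton(np.arctan2(qy / B, qx / A))
    # points inside the evolute have several stationary points; verify
    # against a coarse grid and re-polish where the grid wins
    grid = np.linspace(-np.pi, np.pi, 64, endpoint=False)
    A_ = np.broadcast_to(np.asarray(A, dtype=float), qx.shape)
    B_ = np.broadcast_to(np.asarray(B, dtype=float), qx.shape)
    dg = (A_[None, :] * np.cos(grid)[:, None] - qx[None, :]) ** 2 \
        + (B_[None, :] * np.sin(grid)[:, None] - qy[None, :]) ** 2
    tg = grid[np.argmin(dg, axis=0)]
    better = _d2(tg) < _d2(t) - 1e-15
    if np.any(better):
        t2 = _newton(tg)
        use = _d2(t2) < _d2(t)
        t = np.where(use, t2, t)
    return np.arctan2(np.sin(t), np.cos(t))


def foot_parameters(e: EllipseParams, pts: np.ndarray) -> np.ndarray:
    """Vectorized nearest-point parameters for many planar points."""
    return foot_parameters_family(e.center[0], e.center[1], e.A, e.B, e.phi,
                                  pts)


def _geometric_refine(e0: EllipseParams, pts: np.ndarray,
                      max_points: int = 400) -> EllipseParams:
    """Orthogonal-distance refinement of an algebraic ellipse fit.

    The direct least-squares fit is biased toward small ellipses when
    the data cover only part of the arc and carry noise; minimizing true
    point-to-ellipse distances removes that bias.
    """
    if len(pts) > max_points:
        idx = np.linspace(0, len(pts) - 1, max_points).astype(int)
        sub = pts[np.argsort(pts[:, 0])][idx]
    else:
        sub = pts

    def unpack(p):
        cx, cy, la, lb, phi = p
        a, b = np.exp(la), np.exp(lb)
        A, B = (a, b) if a >= b else (b, a)
        ph = phi if a >= b else phi + np.pi / 2
        return EllipseParams(center=np.array([cx, cy]), semi_axes=(A, B),
                             phi=float(np.mod(ph, np.pi)))

    def resid(p):
        e = unpack(p)
        t = foot_parameters(e, sub)
        return np.linalg.norm(sub - e.point(t), axis=1)

    p0 = np.array([e0.center[0], e0.center[1], np.log(e0.A), np.log(e0.B),
                   e0.phi])
    try:
        sol = least_squares(resid, p0, method="lm", max_nfev=200)
    except Exception:
        return e0
    e1 = unpack(sol.x)
    r0 = float(np.sqrt(np.mean(resid(p0) ** 2)))
    r1 = float(np.sqrt(np.mean(sol.fun ** 2)))
    if not np.isfinite(r1) or r1 > r0:
        return e0
    t = foot_parameters(e1, pts)
    rms = float(np.sqrt(np.mean(np.sum((pts - e1.point(t)) ** 2, axis=1))))
    return EllipseParams(center=e1.center, semi_axes=e1.semi_axes, phi=e1.phi,
                         slice_coord=e0.slice_coord, residual=rms)


def fit_ellipse(pts: np.ndarray, slice_coord: float = np.nan,
                refine: bool = True) -> EllipseParams:
    """Fit an ellipse to >= 5 planar points.

    The numerically stable direct least-squares conic fit provides the
    (deterministic) solution; with ``refine`` (default) it is polished
    by an orthogonal-distance Gauss-Newton pass, which matters for
    noisy partial arcs.

    Raises
    ------
    DegenerateFitError
        Fewer than 5 points, (nearly) collinear points, or a conic that
        is not an ellipse.
    """
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise DegenerateFitError("need at least 5 planar points")
    mean = pts.mean(axis=0)
    sd = pts.std(axis=0).max()
    if sd == 0:
        raise DegenerateFitError("all points coincide")
    xy = (pts - mean) / sd
    x, y = xy[:, 0], xy[:, 1]
    # collinearity guard
    sv = np.linalg.svd(xy - xy.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * sv[0]:
        raise DegenerateFitError("points are collinear; no ellipse exists")

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError:
        raise DegenerateFitError("degenerate point configuration") from None
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    w, V = np.linalg.eig(M)
    cond = 4.0 * V[0] * V[2] - V[1] ** 2  # ellipse constraint per eigvec
    idx = np.flatnonzero((cond > 0) & np.isfinite(w))
    if len(idx) == 0:
        raise DegenerateFitError("best-fit conic is not an ellipse")
    k = idx[np.argmin(np.abs(w[idx]))] if len(idx) > 1 else idx[0]
    a1 = np.real(V[:, k])
    coef = np.concatenate([a1, T @ a1])  # a,b,c,d,e,f in scaled frame

    a, b, c, d, e, f = coef
    disc = b * b - 4 * a * c
    if disc >= 0:
        raise DegenerateFitError("best-fit conic is not an ellipse")
    # quadratic-form route: F(x) = (x-x0)' Q (x-x0) + F(x0)
    Q = np.array([[a, b / 2.0], [b / 2.0, c]])
    x0 = np.linalg.solve(-2.0 * Q, np.array([d, e]))
    f0 = x0 @ Q @ x0 + np.array([d, e]) @ x0 + f
    lam, vec = np.linalg.eigh(Q)
    radii2 = -f0 / lam
    if np.any(radii2 <= 0) or not np.all(np.isfinite(radii2)):
        raise DegenerateFitError("degenerate ellipse axes")
    radii = np.sqrt(radii2)
    order = np.argsort(radii)[::-1]  # A >= B
    A, B = radii[order]
    major = vec[:, order[0]]
    phi = float(np.mod(np.arctan2(major[1], major[0]), np.pi))

    center = mean + sd * x0
    ell = EllipseParams(center=center, semi_axes=(float(sd * A), float(sd * B)),
                        phi=phi, slice_coord=slice_coord)
    # approximate geometric residual: |F(p)| / |grad F| per point
    res = _sampson_residual(coef, xy) * sd
    ell = EllipseParams(center=ell.center, semi_axes=ell.semi_axes,
                        phi=ell.phi, slice_coord=slice_coord,
                        residual=float(np.sqrt(np.mean(res ** 2))))
    if refine:
        ell = _geometric_refine(ell, pts)
    return ell


def _sampson_residual(coef, xy):
    a, b, c, d, e, f = coef
    x, y = xy[:, 0], xy[:, 1]
    F = a * x * x + b * x * y + c * y * y + d * x + e * y + f
    gx = 2 * a * x + b * y + d
    gy = b * x + 2 * c * y + e
    return np.abs(F) / np.maximum(np.hypot(gx, gy), 1e-300)


def _speed(e: EllipseParams):
    A, B = e.A, e.B
    return lambda t: np.sqrt((A * np.sin(t)) ** 2 + (B * np.cos(t)) ** 2)


def arc_length(e: EllipseParams, theta0: float, theta1: float) -> float:
    """Signed arc length from parameter theta0 to theta1 (CCW positive),
    by adaptive quadrature; handles multi-turn ranges."""
    sp = _speed(e)
    lo, hi = (theta0, theta1) if theta1 >= theta0 else (theta1, theta0)
    turns = int((hi - lo) // (2 * np.pi))
    total = 0.0
    if turns:
        total += turns * quad(sp, 0.0, 2 * np.pi, epsabs=1e-12, limit=200)[0]
        hi -= turns * 2 * np.pi
    total += quad(sp, lo, hi, epsabs=1e-12, limit=200)[0]
    return total if theta1 >= theta0 else -total


def foot_parameter(e: EllipseParams, p: np.ndarray) -> float:
    """Parameter of the nearest point on the ellipse to p (in (-pi, pi]).

    Newton iteration on the stationarity condition of the squared
    distance, polished by bounded minimization if Newton stalls.
    """
    p = np.asarray(p, dtype=float)
    d = p - e.center
    if np.hypot(*d) < 1e-14 * max(e.A, e.B):
        raise UndefinedAngleError("point at the ellipse center has no foot")
    return float(foot_parameters(e, p[None, :])[0])


def arc_coordinate(e: EllipseParams, p: np.ndarray, ref_angle: float) -> float:
    """Signed elliptic arc length from the reference meridian (parameter
    ``ref_angle``) to the foot of p; counterclockwise positive.  The foot
    parameter is taken in the branch within half a turn of the reference."""
    t = foot_parameter(e, p)
    # choose the representative of t nearest ref_angle
    t = ref_angle + np.arctan2(np.sin(t - ref_angle), np.cos(t - ref_angle))
    return arc_length(e, ref_angle, t)
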