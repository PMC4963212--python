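"""Two-pass unwrapping of point clouds on unseen convex surfaces.

Pass 1 slices the cloud along one axis into equal-count slabs, fits an
ellipse to each slab's cross-section, and replaces the angular position
of every point by the signed elliptic arc length from a common
reference meridian.  The per-slab fits only initialize a *smooth
family* of ellipses — centers linear and shape-matrix entries
quadratic in the axis coordinate, seeded by a global quadric fit —
which is then refined jointly against every point at its own axis
position (orthogonal distances).  The joint fit avoids the two failure
modes of independent slab fits: bias from the slab-thickness smear,
and the indeterminacy of an ellipse fit to a short arc.  Ellipse shape
is carried as the symmetric matrix
S = R(phi) diag(A^2, B^2) R(phi)^T, whose components interpolate
smoothly even through circular sections where the orientation angle is
undefined.

Pass 1 develops the cloud onto a cylindrical-like intermediate, flat in
the circumferential direction.  Pass 2 repeats the idea orthogonally:
it bins the intermediate by arc coordinate, fits the radial profile as
a spline of the axis coordinate, and replaces the axis coordinate by
arc length along that profile, flattening the remaining curvature.

On developable data (cylinders of any elliptical cross-section) the
composite map is an exact isometric development up to quadrature
tolerance; flat slabs degrade gracefully to a straight-line
development.

The fitted chart is exposed statsmodels-style: build an
:class:`Unwrapper` from the data, call :meth:`~Unwrapper.fit`, and use
the returned :class:`UnwrapResult` (2D tracks, per-slab diagnostics,
``transform`` for extra points such as a wound position, ``summary``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy.interpolate import UnivariateSpline
from scipy.optimize import least_squares

from . import ellipse as ell
from .exceptions import (DegenerateFitError, EmptyInputError, ParameterError,
                         SliceCoverageError)
from .tracks import TrackSet

__all__ = ["SliceSpec", "Unwrapper", "UnwrapResult", "unwrap_pass"]

_AXES = {"x": 0, "y": 1, "z": 2}
# plane coordinates (cyclic, keeps the frame right-handed)
_PLANE = {0: (1, 2), 1: (2, 0), 2: (0, 1)}

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(32)


@dataclass(frozen=True)
class SliceSpec:
    """Slicing recipe for one unwrapping pass."""
    axis: str = "auto"
    n_slices: int = 12

    def __post_init__(self):
        if self.n_slices < 3:
            raise ParameterError("need at least 3 slices")
        if isinstance(self.axis, str) and self.axis not in (
                "auto", "auto-residual", *_AXES):
            raise ParameterError(f"unknown axis {self.axis!r}")


def _shape_matrix(A, B, phi):
    c, s = np.cos(phi), np.sin(phi)
    a2, b2 = A * A, B * B
    return (a2 * c * c + b2 * s * s, (a2 - b2) * s * c,
            a2 * s * s + b2 * c * c)


def _shape_unpack(s11, s12, s22, floor=1e-12):
    """(A, B, phi) from shape-matrix components (vectorized)."""
    tr = s11 + s22
    disc = np.sqrt(np.maximum((s11 - s22) ** 2 / 4 + s12 ** 2, 0.0))
    base = np.maximum(np.abs(tr) / 2, 1e-9)
    l1 = np.maximum(tr / 2 + disc, floor * base)
    l2 = np.maximum(tr / 2 - disc, floor * base)
    phi = 0.5 * np.arctan2(2 * s12, s11 - s22)
    return np.sqrt(l1), np.sqrt(l2), phi


class _Pass1Chart:
    """A smooth one-parameter family of ellipses plus a reference
    meridian.

    Family parameters (center, shape matrix) are low-order polynomials
    of the axis coordinate — exact for every quadric surface (sphere,
    ellipsoid, elliptic cylinder, cone), where slice centers are linear
    and squared section shapes quadratic in the slicing coordinate.
    The low-dimensional family is what keeps the fit identified when
    individual slices only cover short arcs, and it makes the chart
    smooth by construction.

    The reference meridian (v = 0) is the locus of a fixed world angle
    ``psi_ref`` about the local section center.
    """

    def __init__(self, s_knots, coefs, psi_ref=0.0, s_range=None):
        # coefs: (5, deg+1) polynomial coefficients (ascending) of
        # (cx, cy, s11, s12, s22) in the axis coordinate
        self.s_knots = np.asarray(s_knots, dtype=float)
        self.coefs = np.asarray(coefs, dtype=float)
        self.psi_ref = float(psi_ref)
        self.s_range = (tuple(s_range) if s_range is not None
                        else (self.s_knots[0], self.s_knots[-1]))
        self.flat = False

    def params_at(self, s):
        s = np.clip(np.asarray(s, dtype=float), *self.s_range)
        p = npoly.polyval(s, self.coefs.T)  # (..., 5) via broadcasting
        cx, cy = p[0], p[1]
        A, B, phi = _shape_unpack(p[2], p[3], p[4])
        return cx, cy, A, B, phi

    def ellipse_at(self, s) -> ell.EllipseParams:
        cx, cy, A, B, phi = (np.atleast_1d(v)[0]
                             for v in self.params_at(np.atleast_1d(s)))
        return ell.EllipseParams(center=np.array([cx, cy]),
                                 semi_axes=(float(A), float(B)),
                                 phi=float(np.mod(phi, np.pi)),
                                 slice_coord=float(np.clip(s, *self.s_range)))

    def t_ref_at(self, s, cx, cy, A, B, phi):
        d0 = np.cos(self.psi_ref - phi)
        d1 = np.sin(self.psi_ref - phi)
        return np.arctan2(d1 / B, d0 / A)

    def eval_points(self, s, W):
        """Vectorized chart: -> (delta, v, rho, residual, foot).

        delta is the foot parameter offset from the reference meridian
        in (-pi, pi]; v the corresponding signed elliptic arc length
        (32-node Gauss-Legendre, exact to machine precision for these
        analytic integrands); foot the on-section 2D foot points.
        """
        s = np.asarray(s, dtype=float)
        W = np.atleast_2d(np.asarray(W, dtype=float))
        cx, cy, A, B, phi = self.params_at(s)
        t = ell.foot_parameters_family(cx, cy, A, B, phi, W)
        t_ref = self.t_ref_at(s, cx, cy, A, B, phi)
        delta = np.arctan2(np.sin(t - t_ref), np.cos(t - t_ref))
        v = self._arc(A, B, t_ref, t_ref + delta)
        ct, st = np.cos(t), np.sin(t)
        c, sph = np.cos(phi), np.sin(phi)
        fx = cx + c * A * ct - sph * B * st
        fy = cy + sph * A * ct + c * B * st
        rho = np.hypot(fx - cx, fy - cy)
        resid = np.hypot(W[:, 0] - fx, W[:, 1] - fy)
        return delta, v, rho, resid, np.column_stack([fx, fy])

    @staticmethod
    def _arc(A, B, t0, t1):
        half = 0.5 * (t1 - t0)
        mid = 0.5 * (t1 + t0)
        tt = mid[..., None] + half[..., None] * _GL_NODES
        sp = np.sqrt((A[..., None] * np.sin(tt)) ** 2
                     + (B[..., None] * np.cos(tt)) ** 2)
        return (sp @ _GL_WEIGHTS) * half

    def v_from_delta(self, s, delta):
        """Arc length for an unwound (possibly multi-turn) parameter
        offset; used for per-track continuity."""
        e = self.ellipse_at(s)
        t_ref = float(np.atleast_1d(self.t_ref_at(
            s, e.center[0], e.center[1], e.A, e.B, e.phi))[0])
        return ell.arc_length(e, t_ref, t_ref + delta)


class _FlatChart:
    """Straight-line development used when every slab is collinear."""

    def __init__(self, s_knots, centers, dirs, anchor):
        self.s_knots = np.asarray(s_knots, dtype=float)
        self.centers = np.asarray(centers, dtype=float)
        self.dirs = np.asarray(dirs, dtype=float)
        self.anchor = np.asarray(anchor, dtype=float)
        self.flat = True

    def eval_points(self, s, W):
        s = np.asarray(s, dtype=float)
        W = np.atleast_2d(np.asarray(W, dtype=float))
        k = np.clip(np.searchsorted(self.s_knots, s) - 1, 0,
                    len(self.s_knots) - 2)
        s0, s1 = self.s_knots[k], self.s_knots[k + 1]
        lam = np.clip((s - s0) / (s1 - s0), 0.0, 1.0)[:, None]
        d = (1 - lam) * self.dirs[k] + lam * self.dirs[k + 1]
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        ctr = (1 - lam) * self.centers[k] + lam * self.centers[k + 1]
        rel = W - self.anchor
        v = np.sum(rel * d, axis=1)
        n = np.column_stack([-d[:, 1], d[:, 0]])
        rho = np.sum((W - ctr) * n, axis=1)
        foot = W - rho[:, None] * n
        return np.full(len(W), np.nan), v, rho, np.abs(rho), foot


def _quantile_slabs(s: np.ndarray, n_slices: int):
    n = len(s)
    if n < 5 * n_slices:
        raise SliceCoverageError(
            f"{n} points cannot fill {n_slices} slices with >= 5 points "
            "each; use fewer slices")
    edges = np.quantile(s, np.linspace(0, 1, n_slices + 1))
    edges[0] -= 1.0
    edges[-1] += 1.0
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_slices - 1)
    for k in range(n_slices):
        if np.sum(idx == k) < 5:
            raise SliceCoverageError(
                f"slice {k} holds fewer than 5 points; use fewer slices")
    return idx


def _quadric_family(s, W):
    """Initial ellipse family from a global algebraic quadric fit.

    A quadric's plane sections have centers linear and shape-matrix
    entries quadratic in the slicing coordinate, so its restriction to
    the slice planes provides a well-conditioned starting family even
    when individual slices cover only short arcs.

    Returns (5, 3) polynomial coefficients or None when the section
    form is not elliptic.
    """
    x, y, z = s, W[:, 0], W[:, 1]
    mu = np.array([x.mean(), y.mean(), z.mean()])
    sc = float(np.std(np.column_stack([x, y, z])) + 1e-300)
    xs, ys, zs = (x - mu[0]) / sc, (y - mu[1]) / sc, (z - mu[2]) / sc
    D = np.column_stack([xs * xs, ys * ys, zs * zs, xs * ys, xs * zs,
                         ys * zs, xs, ys, zs, np.ones_like(xs)])
    _, _, Vt = np.linalg.svd(D, full_matrices=False)
    q = Vt[-1]
    a11, a22, a33, a12, a13, a23, b1, b2, b3, c = q
    M = np.array([[a22, a23 / 2], [a23 / 2, a33]])
    lam, _ = np.linalg.eigh(M)
    if lam[0] * lam[1] <= 0 or abs(lam[0]) < 1e-9 * abs(lam[1]):
        return None
    if lam[0] < 0:
        q = -q
        a11, a22, a33, a12, a13, a23, b1, b2, b3, c = q
        M = -M
    Minv = np.linalg.inv(M)
    # section in scaled coords at scaled slice coordinate t:
    # w' M w + l(t).w + g(t) = 0 with l linear, g quadratic in t
    l0 = np.array([b2, b3])
    l1 = np.array([a12, a13])
    # center(t) = -Minv (l0 + l1 t) / 2
    c0 = -Minv @ l0 / 2
    c1 = -Minv @ l1 / 2
    # k(t) = center' M center - g(t), g(t) = a11 t^2 + b1 t + c
    # center' M center is quadratic: (c0 + c1 t)' M (c0 + c1 t)
    k0 = c0 @ M @ c0 - c
    k1 = 2 * c0 @ M @ c1 - b1
    k2 = c1 @ M @ c1 - a11
    # shape matrix S(t) = k(t) * Minv
    t_lo, t_hi = (s.min() - mu[0]) / sc, (s.max() - mu[0]) / sc
    tt = np.linspace(t_lo, t_hi, 9)
    kk = k0 + k1 * tt + k2 * tt * tt
    if np.any(kk <= 0):
        return None
    coefs = np.zeros((5, 3))
    # back to unscaled coordinates: w = mu_w + sc*w', t = (s - mu_x)/sc
    # center(s) = mu_w + sc*(c0 + c1*(s-mu_x)/sc) -> linear in s
    for j in range(2):
        coefs[j, 0] = mu[1 + j] + sc * c0[j] - c1[j] * mu[0]
        coefs[j, 1] = c1[j]
    # S_unscaled(s) = sc^2 * k(t) * Minv, t=(s-mu_x)/sc
    Ku = np.array([k0 - k1 * mu[0] / sc + k2 * mu[0] ** 2 / sc ** 2,
                   k1 / sc - 2 * k2 * mu[0] / sc ** 2,
                   k2 / sc ** 2]) * sc ** 2
    for comp, (i, j) in zip(range(2, 5), [(0, 0), (0, 1), (1, 1)]):
        coefs[comp] = Ku * Minv[i, j]
    return coefs


def _init_family(s, W, idx, n_slices, degree):
    """Per-slab algebraic fits -> initial family polynomial."""
    fits, s_mid, fails = [], [], []
    for k in range(n_slices):
        m = idx == k
        s_mid.append(float(s[m].mean()))
        try:
            fits.append(ell.fit_ellipse(W[m], slice_coord=s_mid[-1],
                                        refine=False))
        except DegenerateFitError as err:
            fits.append(None)
            fails.append((k, str(err)))
    s_mid = np.asarray(s_mid)
    if len(fails) == n_slices:
        return s_mid, None, fails  # flat data
    if fails and len(fails) > n_slices // 2:
        k, msg = fails[0]
        raise DegenerateFitError(f"slice {k}: {msg}")
    valid = [i for i, f in enumerate(fits) if f is not None]
    raw = np.full((n_slices, 5), np.nan)
    wts = np.zeros(n_slices)
    for i in valid:
        f = fits[i]
        raw[i] = (f.center[0], f.center[1], *_shape_matrix(f.A, f.B, f.phi))
        wts[i] = 1.0 / (f.residual + 1e-9)
    # residual-weighted polynomial trend per parameter damps the
    # occasional wild partial-arc fit before the joint refinement
    deg = min(degree, len(valid) - 1)
    coefs = np.zeros((5, degree + 1))
    sv = s_mid[valid]
    for j in range(5):
        coefs[j, :deg + 1] = npoly.polyfit(sv, raw[valid, j], deg,
                                           w=np.sqrt(wts[valid]))
    return s_mid, coefs, fails


def _refine_family(chart: _Pass1Chart, s, W, max_points=4000):
    """Joint orthogonal-distance refinement of the family polynomial."""
    n = len(s)
    if n > max_points:
        order = np.argsort(s)
        sel = order[np.linspace(0, n - 1, max_points).astype(int)]
    else:
        sel = np.arange(n)
    ss, WW = s[sel], W[sel]
    shape = chart.coefs.shape

    def resid(p):
        ch = _Pass1Chart(chart.s_knots, p.reshape(shape), chart.psi_ref,
                         chart.s_range)
        cx, cy, A, B, phi = ch.params_at(ss)
        t = ell.foot_parameters_family(cx, cy, A, B, phi, WW)
        c, sph = np.cos(phi), np.sin(phi)
        fx = cx + c * A * np.cos(t) - sph * B * np.sin(t)
        fy = cy + sph * A * np.cos(t) + c * B * np.sin(t)
        return np.hypot(WW[:, 0] - fx, WW[:, 1] - fy)

    sol = least_squares(resid, chart.coefs.ravel(), method="trf",
                        max_nfev=60, x_scale="jac", ftol=1e-12, xtol=1e-14)
    return _Pass1Chart(chart.s_knots, sol.x.reshape(shape), chart.psi_ref,
                        chart.s_range)


def _fit_pass1(X, axis_idx, n_slices, refine=True, degree=2):
    i1, i2 = _PLANE[axis_idx]
    s = X[:, axis_idx]
    W = X[:, [i1, i2]]
    idx = _quantile_slabs(s, n_slices)
    coefs_q = _quadric_family(s, W)
    if coefs_q is not None:
        s_mid = np.array([float(s[idx == k].mean())
                          for k in range(n_slices)])
        coefs = np.zeros((5, max(degree, 2) + 1))
        coefs[:, :3] = coefs_q
        fails = []
    else:
        s_mid, coefs, fails = _init_family(s, W, idx, n_slices, degree)
    if coefs is None:
        # flat data: develop each slab as a straight line
        centers, dirs = [], []
        prev = None
        for k in range(n_slices):
            pts = W[idx == k]
            ctr = pts.mean(axis=0)
            _, _, Vt = np.linalg.svd(pts - ctr, full_matrices=False)
            d = Vt[0]
            if prev is None:
                if d[np.argmax(np.abs(d))] < 0:
                    d = -d
            elif d @ prev < 0:
                d = -d
            prev = d
            centers.append(ctr)
            dirs.append(d)
        return _FlatChart(s_mid, centers, dirs, W.mean(axis=0))
    chart = _Pass1Chart(s_mid, coefs, 0.0, (float(s.min()), float(s.max())))
    if refine:
        chart = _refine_family(chart, s, W)
    # reference meridian: world angle of the centroid of the lowest
    # decile of the axis coordinate about the fitted section center
    # there (a fixed fraction, so the chart does not depend on the slab
    # count); if the centroid is too close to the center to define a
    # direction (closed sections), fall back to a fixed angle, which
    # only moves the chart's v origin
    low = s <= np.quantile(s, 0.1)
    c0 = W[low].mean(axis=0)
    s0 = float(s[low].mean())
    cx, cy, A, B, _ = (np.atleast_1d(q)[0] for q in
                       chart.params_at(np.array([s0])))
    d = c0 - np.array([cx, cy])
    if np.hypot(*d) > 0.05 * 0.5 * (A + B):
        chart.psi_ref = float(np.arctan2(d[1], d[0]))
    return chart


def unwrap_pass(points3d: np.ndarray, spec: SliceSpec, refine: bool = True):
    """One slicing/unrolling pass over a raw point cloud.

    Returns
    -------
    coords : DataFrame with columns ``s`` (axis coordinate), ``v``
        (arc coordinate, base branch), ``rho`` (cross-section radius)
        and ``residual`` (distance to the fitted cross-section).
    chart : the fitted cross-section family (ellipse knots or lines).
    """
    X = np.asarray(points3d, dtype=float)
    axis_idx = _resolve_axis(X, spec.axis)
    chart = _fit_pass1(X, axis_idx, spec.n_slices, refine=refine)
    i1, i2 = _PLANE[axis_idx]
    delta, v, rho, resid, _ = chart.eval_points(X[:, axis_idx],
                                                X[:, [i1, i2]])
    out = pd.DataFrame({"s": X[:, axis_idx], "delta": delta, "v": v,
                        "rho": rho, "residual": resid})
    return out, chart


def _resolve_axis(X: np.ndarray, axis) -> int:
    if isinstance(axis, (int, np.integer)):
        return int(axis)
    if axis in _AXES:
        return _AXES[axis]
    if axis == "auto":
        extent = X.max(axis=0) - X.min(axis=0)
        return int(np.argmax(extent))
    if axis == "auto-residual":
        best, best_res = None, np.inf
        for i in range(3):
            try:
                chart = _fit_pass1(X, i, 6, refine=False)
            except (DegenerateFitError, SliceCoverageError):
                continue
            if chart.flat:
                res = 0.0
            else:
                i1, i2 = _PLANE[i]
                _, _, _, r, _ = chart.eval_points(X[:, i], X[:, [i1, i2]])
                res = float(np.median(r))
            if res < best_res:
                best, best_res = i, res
        if best is None:
            raise DegenerateFitError("no axis admits an ellipse slicing")
        return best
    raise ParameterError(f"unknown axis {axis!r}")


class _Pass2Chart:
    """Arc-length reparametrization of the axis direction.

    Per arc-coordinate bin, the cross-section radius about the fitted
    section center is fit as a spline of the axis coordinate (the
    meridian profile); u is arc length along (s, rho(s)) from the
    global axis minimum.  Between bin centers, u blends linearly in v.
    """

    def __init__(self, s, v, rho, n_bins: int):
        n_bins = max(3, min(n_bins, len(s) // 8))
        edges = np.quantile(v, np.linspace(0, 1, n_bins + 1))
        edges[0] -= 1.0
        edges[-1] += 1.0
        idx = np.clip(np.searchsorted(edges, v, side="right") - 1,
                      0, n_bins - 1)
        self.grid = np.linspace(s.min(), s.max(), 512)
        self.centers, self.ugrids = [], []
        for k in range(n_bins):
            m = idx == k
            if m.sum() < 8:
                continue
            self.centers.append(float(np.mean(v[m])))
            self.ugrids.append(self._profile_u(s[m], rho[m]))
        if not self.centers:
            raise SliceCoverageError("pass 2 found no usable arc bins")
        order = np.argsort(self.centers)
        self.centers = np.array(self.centers)[order]
        self.ugrids = [self.ugrids[i] for i in order]

    def _profile_u(self, s, rho):
        # average rho in equal-count s-bins, spline through the means,
        # integrate the meridian length element sqrt(1 + rho'^2)
        nb = int(np.clip(len(s) // 6, 4, 25))
        e = np.quantile(s, np.linspace(0, 1, nb + 1))
        e[0] -= 1.0
        e[-1] += 1.0
        ib = np.clip(np.searchsorted(e, s, side="right") - 1, 0, nb - 1)
        ks = [k for k in range(nb) if (ib == k).any()]
        ms = np.array([s[ib == k].mean() for k in ks])
        mr = np.array([rho[ib == k].mean() for k in ks])
        keep = np.concatenate([[True], np.diff(ms) > 0])
        ms, mr = ms[keep], mr[keep]
        if len(ms) < 4:
            der = np.zeros_like(self.grid)
        else:
            g = np.clip(self.grid, ms[0], ms[-1])
            der = UnivariateSpline(ms, mr, k=3, s=0.0).derivative()(g)
        du = np.sqrt(1.0 + der ** 2)
        u = np.concatenate([[0.0], np.cumsum(
            0.5 * (du[1:] + du[:-1]) * np.diff(self.grid))])
        return u

    def eval(self, s, v):
        s = np.asarray(s, dtype=float)
        v = np.asarray(v, dtype=float)
        if len(self.centers) == 1:
            return np.interp(s, self.grid, self.ugrids[0])
        k = np.clip(np.searchsorted(self.centers, v) - 1, 0,
                    len(self.centers) - 2)
        c0, c1 = self.centers[k], self.centers[k + 1]
        lam = np.clip((v - c0) / (c1 - c0), 0.0, 1.0)
        u = np.empty_like(s)
        for kk in np.unique(k):
            m = k == kk
            u0 = np.interp(s[m], self.grid, self.ugrids[kk])
            u1 = np.interp(s[m], self.grid, self.ugrids[kk + 1])
            u[m] = (1 - lam[m]) * u0 + lam[m] * u1
        return u


class Unwrapper:
    """Two-pass unwrapping model for a 3D track set (or point cloud).

    Parameters
    ----------
    data
        TrackSet3D or (n, 3) array.  With tracks, the arc coordinate is
        unwound along each track so the chart never tears by a full turn.
    axis
        Slicing axis of pass 1: ``"x" | "y" | "z"``, ``"auto"`` (largest
        extent) or ``"auto-residual"`` (tries all three, keeps the axis
        with the smallest median section residual).
    n_slices, n_slices2
        Slab counts of the two passes (equal-count slabs).
    refine
        Joint refinement of the ellipse family (recommended; disable
        only for quick looks).

    Examples
    --------
    >>> res = Unwrapper(tracks, axis="x", n_slices=12).fit()
    >>> flat = res.tracks2d            # TrackSet2D, method_tag "unwrap"
    >>> res.transform([[0., 0., 1.]])  # map the wound position
    """

    def __init__(self, data, axis: str = "auto", n_slices: int = 12,
                 n_slices2: int | None = None, refine: bool = True,
                 family_degree: int = 2, max_gap: int = 0):
        if isinstance(data, TrackSet):
            if data.ndim != 3:
                raise ParameterError("Unwrapper needs 3D data")
            self.tracks = data
            self.X = data.positions()
        else:
            self.tracks = None
            self.X = np.asarray(data, dtype=float)
            if self.X.ndim != 2 or self.X.shape[1] != 3:
                raise ParameterError("expected an (n, 3) point array")
        if len(self.X) == 0:
            raise EmptyInputError("no points to unwrap")
        self.spec1 = SliceSpec(axis=axis, n_slices=n_slices)
        # pass-2 resolution is an independent knob; a fixed default
        # keeps the chart stable under pass-1 slab refinement
        self.n_slices2 = n_slices2 if n_slices2 is not None else 6
        self.refine = refine
        self.family_degree = family_degree
        self.max_gap = max_gap

    def fit(self) -> "UnwrapResult":
        X = self.X
        axis_idx = _resolve_axis(X, self.spec1.axis)
        chart1 = _fit_pass1(X, axis_idx, self.spec1.n_slices,
                            refine=self.refine, degree=self.family_degree)
        i1, i2 = _PLANE[axis_idx]
        s = X[:, axis_idx]
        W = X[:, [i1, i2]]
        delta, v, rho, resid, foot = chart1.eval_points(s, W)

        if self.tracks is not None and not chart1.flat:
            # unwind the angular offset along each track (anti-tearing)
            tid = self.tracks.data["track_id"].to_numpy()
            for t in pd.unique(tid):
                m = tid == t
                d = np.unwrap(delta[m])
                changed = np.abs(d - delta[m]) > 1e-9
                if changed.any():
                    rows = np.flatnonzero(m)[changed]
                    for i, dd in zip(rows, d[changed]):
                        v[i] = chart1.v_from_delta(s[i], dd)
                    delta[m] = d

        chart2 = _Pass2Chart(s, v, rho, self.n_slices2)
        u = chart2.eval(s, v)
        coords = np.column_stack([u, v])
        tracks2d = None
        if self.tracks is not None:
            tracks2d = self.tracks.with_positions(coords, method_tag="unwrap")
        return UnwrapResult(
            model=self, axis_idx=axis_idx, chart1=chart1, chart2=chart2,
            coords=coords, tracks2d=tracks2d, rho=rho, residuals=resid)


@dataclass
class UnwrapResult:
    """Fitted two-pass chart: flattened coordinates and diagnostics."""
    model: Unwrapper
    axis_idx: int
    chart1: _Pass1Chart | _FlatChart
    chart2: _Pass2Chart
    coords: np.ndarray          # (n, 2) chart coordinates (u, v)
    tracks2d: TrackSet | None
    rho: np.ndarray
    residuals: np.ndarray       # per-point distance to the fitted section

    @property
    def ellipses(self):
        """Fitted cross-section ellipses at the slab knots (pass 1)."""
        if self.chart1.flat:
            return None
        return [self.chart1.ellipse_at(sk) for sk in self.chart1.s_knots]

    def transform(self, points3d) -> np.ndarray:
        """Map arbitrary 3D points (e.g. an attractant position) through
        the fitted chart (base angular branch)."""
        P = np.atleast_2d(np.asarray(points3d, dtype=float))
        i1, i2 = _PLANE[self.axis_idx]
        _, v, _, _, _ = self.chart1.eval_points(P[:, self.axis_idx],
                                                P[:, [i1, i2]])
        u = self.chart2.eval(P[:, self.axis_idx], v)
        return np.column_stack([u, v])

    def map_target(self, target3d) -> np.ndarray:
        """Per-point image of a target position, branch-adjusted.

        On charts of closed cross-sections the arc coordinate is
        periodic; each point sees the target in the branch nearest its
        own (possibly unwound) arc coordinate.  Returns (n_points, 2).
        """
        base = self.transform(np.atleast_2d(np.asarray(target3d, float)))[0]
        out = np.tile(base, (len(self.coords), 1))
        if self.chart1.flat:
            return out
        s = self.model.X[:, self.axis_idx]
        _, _, A, B, _ = self.chart1.params_at(s)
        zero = np.zeros_like(A)
        per = self.chart1._arc(A, B, zero, zero + 2 * np.pi)
        v = self.coords[:, 1]
        out[:, 1] = base[1] + per * np.round((v - base[1]) / per)
        return out

    def fit_report(self) -> pd.DataFrame:
        """Per-slab cross-section parameters (pass 1 knots)."""
        if self.chart1.flat:
            return pd.DataFrame({
                "slice": range(len(self.chart1.s_knots)),
                "s_mid": self.chart1.s_knots, "kind": "line"})
        rows = []
        for k, e in enumerate(self.ellipses):
            rows.append(dict(slice=k, s_mid=e.slice_coord, cx=e.center[0],
                             cy=e.center[1], A=e.A, B=e.B, phi=e.phi))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        kind = "line (flat data)" if self.chart1.flat else "ellipse"
        nbins = len(self.chart2.centers)
        lines = [
            "Unwrapping chart summary",
            "========================",
            f"points                 {len(self.coords)}",
            f"slicing axis           {'xyz'[self.axis_idx]}",
            f"pass-1 slabs           {len(self.chart1.s_knots)} ({kind})",
            f"pass-2 arc bins        {nbins}",
            f"median |residual|      {np.median(self.residuals):.4g}",
            f"max |residual|         {np.max(self.residuals):.4g}",
            f"u range                [{self.coords[:, 0].min():.4g}, "
            f"{self.coords[:, 0].max():.4g}]",
            f"v range                [{self.coords[:, 1].min():.4g}, "
            f"{self.coords[:, 1].max():.4g}]",
        ]
        return "\n".join(lines)
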