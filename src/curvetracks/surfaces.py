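"""Parametric convex surfaces used by the random-walk simulator.

Every surface exposes an implicit function ``implicit`` (zero on the
surface, scaled so its magnitude is a length), an orthogonal projection
``project`` back onto the surface, the outward unit ``normal`` and a
deterministic right-handed tangent frame ``tangent_basis``.  Surfaces
are axis-aligned; ``center`` shifts them.

Area-uniform sampling uses rejection from the surface area measure, with
an optional region predicate to restrict the initial patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exceptions import ParameterError

__all__ = [
    "Surface", "Plane", "Sphere", "Cylinder", "Ellipsoid",
    "HemispherePatch", "make_surface",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


@dataclass(frozen=True)
class Surface:
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    # -- interface -------------------------------------------------------
    def implicit(self, p: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def project(self, p: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def normal(self, p: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def scale(self) -> float:  # characteristic length
        raise NotImplementedError  # pragma: no cover

    @property
    def min_curvature_radius(self) -> float:
        raise NotImplementedError  # pragma: no cover

    def sample(self, n: int, rng: np.random.Generator,
               region=None, max_tries: int = 200) -> np.ndarray:
        """n area-uniform points, optionally restricted by ``region(p)->bool``."""
        out = []
        need = n
        for _ in range(max_tries):
            cand = self._propose(max(4 * need, 16), rng)
            if region is not None:
                cand = cand[np.asarray(region(cand), dtype=bool)]
            out.append(cand[:need])
            need -= len(cand[:need])
            if need == 0:
                return np.concatenate(out, axis=0)
        raise ParameterError("could not sample the requested surface region")

    def _propose(self, m: int, rng) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def tangent_basis(self, p: np.ndarray):
        """Right-handed orthonormal tangent frame (e1, e2) with e1 x e2 = n."""
        p = np.atleast_2d(p)
        n = self.normal(p)
        ref = np.tile(np.array([1.0, 0.0, 0.0]), (len(p), 1))
        swap = np.abs(n @ np.array([1.0, 0.0, 0.0])) > 0.9
        ref[swap] = np.array([0.0, 1.0, 0.0])
        e1 = _unit(ref - (np.sum(ref * n, axis=1, keepdims=True)) * n)
        e2 = np.cross(n, e1)
        return e1, e2

    def on_surface(self, p: np.ndarray, tol: float = 1e-8) -> np.ndarray:
        return np.abs(self.implicit(p)) < tol * self.scale


@dataclass(frozen=True)
class Plane(Surface):
    """The z = center_z plane; ``extent`` bounds sampling only."""
    extent: float = 4.0

    def implicit(self, p):
        return np.asarray(p)[..., 2] - self.center[2]

    def project(self, p):
        q = np.array(p, dtype=float, copy=True)
        q[..., 2] = self.center[2]
        return q

    def normal(self, p):
        p = np.atleast_2d(p)
        return np.tile(np.array([0.0, 0.0, 1.0]), (len(p), 1))

    @property
    def scale(self):
        return self.extent

    @property
    def min_curvature_radius(self):
        return np.inf

    def _propose(self, m, rng):
        xy = rng.uniform(-self.extent / 2, self.extent / 2, size=(m, 2))
        return np.column_stack([xy, np.zeros(m)]) + self.center


@dataclass(frozen=True)
class Sphere(Surface):
    radius: float = 1.0

    def __post_init__(self):
        super().__post_init__()
        if self.radius <= 0:
            raise ParameterError("sphere radius must be positive")

    def implicit(self, p):
        return np.linalg.norm(np.asarray(p) - self.center, axis=-1) - self.radius

    def project(self, p):
        d = np.asarray(p, dtype=float) - self.center
        return self.center + self.radius * _unit(d)

    def normal(self, p):
        return _unit(np.asarray(p, dtype=float) - self.center)

    @property
    def scale(self):
        return self.radius

    @property
    def min_curvature_radius(self):
        return self.radius

    def _propose(self, m, rng):
        u = _unit(rng.normal(size=(m, 3)))
        return self.center + self.radius * u


@dataclass(frozen=True)
class HemispherePatch(Sphere):
    """Spherical cap around ``axis`` of half-angle ``half_angle`` (radians).

    Projection and normals are those of the full sphere (walkers may step
    slightly past the rim); the cap bounds area-uniform sampling and the
    region membership test.
    """
    half_angle: float = np.pi / 2
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        super().__post_init__()
        object.__setattr__(self, "axis", _unit(np.asarray(self.axis, dtype=float)))
        if not 0 < self.half_angle <= np.pi:
            raise ParameterError("half_angle must lie in (0, pi]")

    def in_patch(self, p):
        u = _unit(np.asarray(p, dtype=float) - self.center)
        return u @ self.axis >= np.cos(self.half_angle)

    def _propose(self, m, rng):
        cand = super()._propose(m, rng)
        return cand[self.in_patch(cand)]


@dataclass(frozen=True)
class Cylinder(Surface):
    """Circular cylinder with axis along z; ``height`` bounds sampling only."""
    radius: float = 1.0
    height: float = 4.0

    def __post_init__(self):
        super().__post_init__()
        if self.radius <= 0 or self.height <= 0:
            raise ParameterError("cylinder radius and height must be positive")

    def implicit(self, p):
        d = np.asarray(p) - self.center
        return np.hypot(d[..., 0], d[..., 1]) - self.radius

    def project(self, p):
        d = np.asarray(p, dtype=float) - self.center
        r = np.hypot(d[..., 0], d[..., 1])[..., None]
        q = d.copy()
        q[..., :2] = d[..., :2] * (self.radius / r)
        return self.center + q

    def normal(self, p):
        d = np.asarray(p, dtype=float) - self.center
        n = d.copy()
        n[..., 2] = 0.0
        return _unit(n)

    @property
    def scale(self):
        return self.radius

    @property
    def min_curvature_radius(self):
        return self.radius

    def _propose(self, m, rng):
        th = rng.uniform(-np.pi, np.pi, size=m)
        z = rng.uniform(-self.height / 2, self.height / 2, size=m)
        return self.center + np.column_stack(
            [self.radius * np.cos(th), self.radius * np.sin(th), z])


@dataclass(frozen=True)
class Ellipsoid(Surface):
    """Axis-aligned ellipsoid with semi-axes (a, b, c)."""
    semi_axes: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        super().__post_init__()
        ax = np.asarray(self.semi_axes, dtype=float)
        if ax.shape != (3,) or np.any(ax <= 0):
            raise ParameterError("semi-axes must be three positive numbers")
        object.__setattr__(self, "semi_axes", tuple(ax))

    def _ax(self):
        return np.asarray(self.semi_axes)

    def implicit(self, p):
        d = (np.asarray(p) - self.center) / self._ax()
        # scaled so the value is approximately a distance
        return (np.linalg.norm(d, axis=-1) - 1.0) * np.min(self._ax())

    def normal(self, p):
        d = (np.asarray(p, dtype=float) - self.center) / self._ax() ** 2
        return _unit(d)

    def project(self, p):
        """Exact closest point, via the Lagrange condition
        x_i = a_i^2 p_i / (a_i^2 + lam) solved for lam per point."""
        p = np.atleast_2d(np.asarray(p, dtype=float)) - self.center
        a2 = self._ax() ** 2
        lam = np.zeros(len(p))
        # Newton on g(lam) = sum(a_i^2 p_i^2/(a_i^2+lam)^2) - 1 (convex, decreasing)
        for _ in range(60):
            denom = a2 + lam[:, None]
            g = np.sum(a2 * p ** 2 / denom ** 2, axis=1) - 1.0
            gp = -2.0 * np.sum(a2 * p ** 2 / denom ** 3, axis=1)
            step = g / gp
            lam = lam - step
            lam = np.maximum(lam, -0.95 * a2.min())
            if np.max(np.abs(step)) < 1e-14 * a2.max():
                break
        bad = np.abs(np.sum(a2 * p ** 2 / (a2 + lam[:, None]) ** 2, axis=1) - 1) > 1e-9
        for i in np.flatnonzero(bad):  # bisection fallback, rare
            f = lambda l: float(np.sum(a2 * p[i] ** 2 / (a2 + l) ** 2) - 1.0)
            lo = -a2.min() * (1 - 1e-12)
            hi = a2.max() * (1 + np.linalg.norm(p[i]))
            while f(hi) > 0:
                hi *= 2
            lam[i] = brentq(f, lo, hi, xtol=1e-15)
        x = a2 * p / (a2 + lam[:, None])
        return self.center + x

    @property
    def scale(self):
        return float(np.max(self._ax()))

    @property
    def min_curvature_radius(self):
        ax = self._ax()
        return float(np.min(ax) ** 2 / np.max(ax))

    def _propose(self, m, rng):
        # map unit-sphere samples, rejection-correct for area distortion
        u = _unit(rng.normal(size=(m, 3)))
        a, b, c = self.semi_axes
        w = np.sqrt((u[:, 0] * b * c) ** 2 + (u[:, 1] * a * c) ** 2
                    + (u[:, 2] * a * b) ** 2)
        keep = rng.uniform(0, w.max(), size=m) < w
        return self.center + u[keep] * self._ax()


_KINDS = {
    "plane": Plane,
    "sphere": Sphere,
    "hemisphere_patch": HemispherePatch,
    "cylinder": Cylinder,
    "ellipsoid": Ellipsoid,
}


def make_surface(kind: str, **params) -> Surface:
    """Factory for the supported surface kinds.

    Examples
    --------
    >>> make_surface("sphere", radius=2.0)
    >>> make_surface("ellipsoid", semi_axes=(5, 1, 0.2))
    """
    try:
        cls = _KINDS[kind]
    except KeyError:
        raise ParameterError(
            f"unknown surface kind {kind!r}; choose from {sorted(_KINDS)}"
        ) from None
    return cls(**params)
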