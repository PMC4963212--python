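"""Biased-persistent random walks constrained to curved surfaces.

The walk draws a heading angle in the local tangent plane at every step.
Attraction toward a target and alignment with the previous step are both
von Mises kernels over the heading; when both are active they combine
multiplicatively, which for von Mises densities is again von Mises with

    kappa* e^{i mu*} = kappa_p e^{i theta_prev} + kappa_b e^{i theta_target}.

Stepping is projected Euler: move the step length along the sampled
tangent direction, then orthogonally project back onto the surface
(exact on planes and along cylinder generators, O(L^2/R) geodesic error
elsewhere).  The previous heading is carried between steps by projecting
the realized 3D step direction onto the new tangent plane.

The sampled heading angles are recorded per step as the intrinsic ground
truth against which 2D reconstructions are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .directional import AngleDistribution, wrap_angle
from .exceptions import ParameterError
from .surfaces import (Cylinder, Ellipsoid, HemispherePatch, Plane, Sphere,
                       Surface)
from .tracks import TrackSet

__all__ = [
    "WalkModel", "SimResult", "tangent_step", "simulate_walk",
    "true_angle_distribution", "SURFACE_PRESETS", "WALK_PRESETS",
    "preset_surface", "preset_model",
]


@dataclass(frozen=True)
class WalkModel:
    """Parameters of a biased-persistent surface walk.

    bias_strength / persistence_strength are von Mises concentration
    parameters (0 switches the term off); the four classic walk classes
    are the sign pattern of the two strengths.  ``target`` (3-vector) is
    required iff bias_strength > 0.  ``step_length`` is the surface
    distance covered per frame.
    """
    bias_strength: float = 0.0
    persistence_strength: float = 0.0
    target: np.ndarray | None = None
    step_length: float = 0.05

    def __post_init__(self):
        if self.bias_strength < 0 or self.persistence_strength < 0:
            raise ParameterError("concentration parameters must be >= 0")
        if self.step_length <= 0:
            raise ParameterError("step_length must be positive")
        if self.bias_strength > 0 and self.target is None:
            raise ParameterError("a biased walk needs a target position")
        if self.target is not None:
            object.__setattr__(
                self, "target", np.asarray(self.target, dtype=float))


@dataclass(frozen=True)
class SimResult:
    """Simulated tracks plus the per-step intrinsic ground truth angles."""
    tracks3d: TrackSet
    intrinsic: pd.DataFrame  # track_id, t_start, turn_angle, bias_angle
    seed: int
    surface: Surface
    model: WalkModel

    def true_distribution(self, which: str, bins: int = 36
                          ) -> AngleDistribution:
        """Analytic/Monte-Carlo distribution implied by the walk kernels."""
        return true_angle_distribution(self.model, which, bins=bins)

    def intrinsic_distribution(self, which: str, bins: int = 36
                               ) -> AngleDistribution:
        """Empirical distribution of the realized intrinsic angles."""
        col = {"bias": "bias_angle", "persistence": "turn_angle"}[which]
        vals = self.intrinsic[col].dropna().to_numpy()
        return AngleDistribution.from_angles(
            vals, bins=bins, provenance={"which": which, "method": "intrinsic"})


def tangent_step(surface: Surface, p: np.ndarray, heading: np.ndarray,
                 step_length: float, tol: float = 1e-6) -> np.ndarray:
    """One projected-Euler step from on-surface point(s) ``p``.

    ``heading`` is the angle in the deterministic tangent frame at p.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if not np.all(np.abs(surface.implicit(p)) < tol * surface.scale + 1e-12):
        raise ParameterError("starting point is not on the surface")
    heading = np.atleast_1d(np.asarray(heading, dtype=float))
    e1, e2 = surface.tangent_basis(p)
    d = np.cos(heading)[:, None] * e1 + np.sin(heading)[:, None] * e2
    return surface.project(p + step_length * d)


def _heading_of(vec3, e1, e2):
    """Angle of tangent-projected 3-vectors in the local frame; NaN where
    the projection vanishes."""
    x = np.sum(vec3 * e1, axis=1)
    y = np.sum(vec3 * e2, axis=1)
    ang = np.arctan2(y, x)
    ang[np.hypot(x, y) < 1e-300] = np.nan
    return ang


def simulate_walk(surface: Surface, model: WalkModel, n_tracks: int,
                  n_steps: int, seed: int, start_region=None,
                  dt: float = 1.0) -> SimResult:
    """Simulate ``n_tracks`` walks of ``n_steps`` steps on a surface.

    Initial positions are area-uniform over the surface (restricted by
    ``start_region`` when given; HemispherePatch restricts to its cap by
    default).  Initial headings are uniform.  Reproducible given
    (surface, model, n, seed).
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    if n_tracks < 1:
        raise ParameterError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    L = model.step_length
    kb, kp = model.bias_strength, model.persistence_strength

    p = surface.sample(n_tracks, rng, region=start_region)
    pos = np.empty((n_steps + 1, n_tracks, 3))
    pos[0] = p
    turn = np.full((n_steps, n_tracks), np.nan)
    biasa = np.full((n_steps, n_tracks), np.nan)
    prev_dir = None  # realized 3D step directions

    for s in range(n_steps):
        e1, e2 = surface.tangent_basis(p)
        mu_re = np.zeros(n_tracks)
        mu_im = np.zeros(n_tracks)
        th_prev = np.full(n_tracks, np.nan)
        th_tgt = np.full(n_tracks, np.nan)
        if prev_dir is not None and kp > 0:
            th_prev = _heading_of(prev_dir, e1, e2)
            ok = ~np.isnan(th_prev)
            mu_re[ok] += kp * np.cos(th_prev[ok])
            mu_im[ok] += kp * np.sin(th_prev[ok])
        if kb > 0:
            tv = model.target[None, :] - p
            if np.any(np.linalg.norm(tv, axis=1) == 0):
                raise ParameterError("a walker sits exactly on the target")
            th_tgt = _heading_of(tv, e1, e2)
            ok = ~np.isnan(th_tgt)
            mu_re[ok] += kb * np.cos(th_tgt[ok])
            mu_im[ok] += kb * np.sin(th_tgt[ok])
        kappa = np.hypot(mu_re, mu_im)
        mu = np.arctan2(mu_im, mu_re)
        theta = np.where(kappa > 1e-12,
                         rng.vonmises(mu, np.maximum(kappa, 1e-12)),
                         rng.uniform(-np.pi, np.pi, size=n_tracks))
        if prev_dir is not None:
            th0 = _heading_of(prev_dir, e1, e2)
            turn[s] = wrap_angle(theta - th0)
        if model.target is not None:
            tv = model.target[None, :] - p
            tt = _heading_of(tv, e1, e2)
            biasa[s] = wrap_angle(theta - tt)
        d = np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2
        q = surface.project(p + L * d)
        prev_dir = q - p
        p = q
        pos[s + 1] = p

    frames = []
    for i in range(n_tracks):
        frames.append(pd.DataFrame({
            "track_id": i, "t": np.arange(n_steps + 1),
            "x": pos[:, i, 0], "y": pos[:, i, 1], "z": pos[:, i, 2]}))
    ts = TrackSet.from_dataframe(pd.concat(frames, ignore_index=True), dt=dt)
    intr = pd.concat([
        pd.DataFrame({"track_id": i, "t_start": np.arange(n_steps),
                      "turn_angle": turn[:, i], "bias_angle": biasa[:, i]})
        for i in range(n_tracks)], ignore_index=True)
    return SimResult(tracks3d=ts, intrinsic=intr, seed=seed,
                     surface=surface, model=model)


# ---------------------------------------------------------------------------
# Ground-truth angle distributions implied by the walk kernels
# ---------------------------------------------------------------------------

def _vm_density(kappa):
    return lambda a: np.exp(kappa * np.cos(a)) / (2 * np.pi * special.i0(kappa))


def _vm_difference_density(kappa, n_terms: int = 60):
    """Density of the difference of two iid von Mises(0, kappa) angles.

    Fourier coefficients of VM are I_n(k)/I_0(k); the difference has
    squared coefficients.
    """
    rho = np.array([special.iv(n, kappa) / special.i0(kappa)
                    for n in range(1, n_terms + 1)])

    def fn(a):
        a = np.asarray(a, dtype=float)
        s = np.ones_like(a)
        for n, r in enumerate(rho, start=1):
            s = s + 2.0 * r ** 2 * np.cos(n * a)
        return s / (2 * np.pi)

    return fn


def _mc_stationary(model: WalkModel, bins: int, which: str,
                   n_chains: int = 20000, n_steps: int = 80,
                   burn: int = 30, seed: int = 12345) -> AngleDistribution:
    """Stationary bias/turn distribution of the heading Markov chain for a
    biased-persistent walk with a fixed (far-field) target direction."""
    rng = np.random.default_rng(seed)
    kb, kp = model.bias_strength, model.persistence_strength
    th = rng.uniform(-np.pi, np.pi, size=n_chains)
    keep_bias, keep_turn = [], []
    for s in range(n_steps):
        re = kp * np.cos(th) + kb
        im = kp * np.sin(th)
        kappa = np.hypot(re, im)
        mu = np.arctan2(im, re)
        new = rng.vonmises(mu, np.maximum(kappa, 1e-12))
        if s >= burn:
            keep_bias.append(new.copy())
            keep_turn.append(wrap_angle(new - th))
        th = new
    vals = keep_bias if which == "bias" else keep_turn
    return AngleDistribution.from_angles(
        np.concatenate(vals), bins=bins,
        provenance={"which": which, "method": "true_mc",
                    "model": (kb, kp), "n_mc": n_chains * (n_steps - burn)})


def true_angle_distribution(model: WalkModel, which: str, bins: int = 36
                            ) -> AngleDistribution:
    """The bias or persistence angle distribution the walk kernels imply.

    Closed forms where they exist (uniform; von Mises; the self-
    convolution for the persistence distribution of a bias-only walk);
    the stationary chain of the combined kernel is sampled by Monte
    Carlo with a fixed seed otherwise.
    """
    if which not in ("bias", "persistence"):
        raise ParameterError("which must be 'bias' or 'persistence'")
    kb, kp = model.bias_strength, model.persistence_strength
    prov = {"which": which, "method": "true", "model": (kb, kp)}
    if which == "bias":
        if kb == 0:
            return AngleDistribution.uniform(bins, provenance=prov)
        if kp == 0:
            return AngleDistribution.from_density(_vm_density(kb), bins, prov)
        return _mc_stationary(model, bins, "bias")
    # persistence
    if kp == 0 and kb == 0:
        return AngleDistribution.uniform(bins, provenance=prov)
    if kp > 0 and kb == 0:
        return AngleDistribution.from_density(_vm_density(kp), bins, prov)
    if kp == 0 and kb > 0:
        return AngleDistribution.from_density(
            _vm_difference_density(kb), bins, prov)
    return _mc_stationary(model, bins, "persistence")


# ---------------------------------------------------------------------------
# Named presets: the validation grid's geometries and walk models
# ---------------------------------------------------------------------------
# Six geometries spanning zero to strong curvature.  Each preset fixes the
# surface, the patch over which walkers start (both reconstruction methods
# chart one open patch, so start patches keep the sampled cloud open), the
# step length (<= 2% of the smallest curvature radius) and, for biased
# walks, an on-surface attractant inside the patch.

def _cap_region(axis, cos_limit):
    axis = np.asarray(axis, dtype=float)

    def region(p):
        u = p / np.linalg.norm(p, axis=-1, keepdims=True)
        return u @ axis >= cos_limit
    return region


def _band_region(cos_limit):
    def region(p):
        r = np.hypot(p[..., 0], p[..., 1])
        return p[..., 0] / r >= cos_limit
    return region


SURFACE_PRESETS = {
    "plane": dict(
        surface=Plane(extent=4.0), start_region=None, step_length=0.05,
        target=np.array([1.5, 1.0, 0.0])),
    "cylinder": dict(
        surface=Cylinder(radius=1.0, height=4.0),
        start_region=_band_region(np.cos(np.pi / 3)),  # |angle| <= 60 deg
        step_length=0.02, target=np.array([1.0, 0.0, 1.0])),
    "hemisphere": dict(
        # dome patch: walkers start on the 60-degree polar cap and move
        # freely on the sphere afterwards (coverage ~75 degrees after
        # 200 steps)
        surface=Sphere(radius=1.0),
        start_region=_cap_region([0, 0, 1], np.cos(np.deg2rad(60))),
        step_length=0.02,
        target=np.array([np.sin(0.7), 0.0, np.cos(0.7)])),
    "sphere": dict(
        # wider cap on the same full-curvature surface
        surface=Sphere(radius=1.0),
        start_region=_cap_region([0, 0, 1], np.cos(np.deg2rad(70))),
        step_length=0.02,
        target=np.array([np.sin(0.7), 0.0, np.cos(0.7)])),
    # closed surfaces, walkers everywhere: per-track angular unwinding
    # keeps the charts continuous along tracks
    "ellipsoid_mild": dict(
        surface=Ellipsoid(semi_axes=(1.5, 1.0, 0.75)),
        start_region=None, step_length=0.04,
        target=None),  # filled below (on-surface point)
    "ellipsoid_thin": dict(
        surface=Ellipsoid(semi_axes=(5.0, 1.0, 0.2)),
        start_region=None, step_length=0.03,
        target=None),
}
SURFACE_PRESETS["ellipsoid_mild"]["target"] = \
    SURFACE_PRESETS["ellipsoid_mild"]["surface"].project([0.8, 0.5, 0.6])[0]
SURFACE_PRESETS["ellipsoid_thin"]["target"] = \
    SURFACE_PRESETS["ellipsoid_thin"]["surface"].project([2.5, 0.5, 0.2])[0]

WALK_PRESETS = {
    "brownian": dict(bias_strength=0.0, persistence_strength=0.0),
    "biased": dict(bias_strength=2.0, persistence_strength=0.0),
    "biased_persistent": dict(bias_strength=2.0, persistence_strength=1.0),
}


def preset_surface(name: str):
    """(surface, start_region, step_length, target) for a named geometry."""
    try:
        c = SURFACE_PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown surface preset {name!r}; choose from "
            f"{sorted(SURFACE_PRESETS)}") from None
    return c["surface"], c["start_region"], c["step_length"], c["target"]


def preset_model(walk: str, surface_preset: str) -> WalkModel:
    """A WalkModel for a named walk class on a named geometry."""
    try:
        w = WALK_PRESETS[walk]
    except KeyError:
        raise ParameterError(
            f"unknown walk preset {walk!r}; choose from "
            f"{sorted(WALK_PRESETS)}") from None
    _, _, L, target = preset_surface(surface_preset)
    return WalkModel(step_length=L,
                     target=target if w["bias_strength"] > 0 else None, **w)
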