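"""Directional statistics of migrating cells.

Bias angle: signed angle between a step displacement and the direction
from the step origin to the attractant.  Persistence (turning) angle:
signed angle between two consecutive steps of one track.  Both live in
[-pi, pi), counterclockwise positive.  With a metric field attached to
the 2D representation, inner products, norms and orientation all use the
local metric g, which is what removes chart distortion.

The straightness index D of a track is net displacement over total path
length: 1 for ballistic motion, approaching 0 for diffusive motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .exceptions import (EmptyInputError, ParameterError, UndefinedAngleError)
from .tracks import TrackSet, steps

__all__ = [
    "AngleDistribution", "bias_angles", "persistence_angles",
    "straightness_index", "deviation_distance", "chi2_uniform_gof",
    "circular_mean", "vonmises_concentration",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap to [-pi, pi)."""
    return np.mod(np.asarray(a) + np.pi, TWO_PI) - np.pi


@dataclass(frozen=True)
class AngleDistribution:
    """A circular distribution: raw angles (when available) plus a binned
    density normalized to integrate to 1 over [-pi, pi)."""

    density: np.ndarray
    bin_edges: np.ndarray
    angles: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)
    n_excluded: int = 0

    def __post_init__(self):
        if len(self.density) < 8:
            raise ParameterError("use at least 8 bins for a circular histogram")
        total = float(np.sum(self.density) * self.bin_width)
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ParameterError(f"density integrates to {total}, not 1")

    @property
    def n_bins(self) -> int:
        return len(self.density)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n(self) -> int:
        return 0 if self.angles is None else len(self.angles)

    @classmethod
    def from_angles(cls, angles, bins: int = 36, provenance=None,
                    n_excluded: int = 0) -> "AngleDistribution":
        angles = wrap_angle(np.asarray(angles, dtype=float))
        if angles.size == 0:
            raise EmptyInputError("no angles to bin")
        edges = np.linspace(-np.pi, np.pi, bins + 1)
        dens, _ = np.histogram(angles, bins=edges, density=True)
        return cls(density=dens, bin_edges=edges, angles=angles,
                   provenance=dict(provenance or {}), n_excluded=n_excluded)

    @classmethod
    def from_density(cls, fn, bins: int = 36, provenance=None
                     ) -> "AngleDistribution":
        """Bin-average an analytic density over equal bins and renormalize."""
        edges = np.linspace(-np.pi, np.pi, bins + 1)
        fine = 64
        dens = np.empty(bins)
        for i in range(bins):
            g = np.linspace(edges[i], edges[i + 1], fine)
            dens[i] = np.trapezoid(fn(g), g) / (edges[i + 1] - edges[i])
        dens /= np.sum(dens) * (edges[1] - edges[0])
        return cls(density=dens, bin_edges=edges,
                   provenance=dict(provenance or {}))

    @classmethod
    def uniform(cls, bins: int = 36, provenance=None) -> "AngleDistribution":
        edges = np.linspace(-np.pi, np.pi, bins + 1)
        return cls(density=np.full(bins, 1.0 / TWO_PI), bin_edges=edges,
                   provenance=dict(provenance or {}))


def _metric_at(metric, rows):
    """Per-row 2x2 metrics (identity when metric is None)."""
    if metric is None:
        return None
    g = metric.g if hasattr(metric, "g") else np.asarray(metric)
    return g[rows]


def _signed_angles(a: np.ndarray, b: np.ndarray, g: np.ndarray | None):
    """Signed angle from ``a`` to ``b`` per row under metric g (or Euclid).

    Returns (angles, valid): rows where either vector has zero norm are
    flagged invalid rather than raising.
    """
    if g is None:
        dot = np.sum(a * b, axis=1)
        cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
    else:
        dot = np.einsum("ni,nij,nj->n", a, g, b)
        cross = np.sqrt(np.maximum(np.linalg.det(g), 0.0)) * (
            a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
        na = np.sqrt(np.maximum(np.einsum("ni,nij,nj->n", a, g, a), 0.0))
        nb = np.sqrt(np.maximum(np.einsum("ni,nij,nj->n", b, g, b), 0.0))
    valid = (na > 0) & (nb > 0)
    ang = np.arctan2(cross, dot)
    return ang, valid


def bias_angles(ts2d: TrackSet, target2d, metric=None, bins: int = 36,
                max_gap: int = 0) -> AngleDistribution:
    """Signed angles between each step and the local direction to the
    attractant; with ``metric``, evaluated with g at the step origin.

    ``target2d`` is a single 2-vector, or an (n_points, 2) array of
    per-point target images (needed on charts with a periodic
    coordinate, where the target's arc branch depends on the point).
    """
    target2d = np.asarray(target2d, dtype=float)
    st = steps(ts2d, max_gap=max_gap)
    if len(st) == 0:
        raise EmptyInputError("no steps in the track set")
    d = st[["du", "dv"]].to_numpy()
    origin = st[["u", "v"]].to_numpy()
    if target2d.ndim == 2:
        r = target2d[st["row"].to_numpy()] - origin
    else:
        r = target2d[None, :] - origin
    if np.any(np.all(r == 0, axis=1)):
        raise UndefinedAngleError("target coincides with a step origin")
    g = _metric_at(metric, st["row"].to_numpy())
    ang, valid = _signed_angles(r, d, g)
    return AngleDistribution.from_angles(
        ang[valid], bins=bins,
        provenance={"which": "bias", "method": ts2d.method_tag},
        n_excluded=int((~valid).sum()))


def persistence_angles(ts2d: TrackSet, metric=None, bins: int = 36,
                       max_gap: int = 0) -> AngleDistribution:
    """Signed turning angles between consecutive steps of each track;
    with ``metric``, evaluated with g at the shared point."""
    st = steps(ts2d, max_gap=max_gap)
    cols = [f"d{c}" for c in ts2d.coord_cols]
    same = (st["track_id"].to_numpy()[1:] == st["track_id"].to_numpy()[:-1]) & (
        st["t_start"].to_numpy()[1:]
        == st["t_start"].to_numpy()[:-1] + st["dtframes"].to_numpy()[:-1])
    if not same.any():
        raise EmptyInputError("no track contains two consecutive steps")
    d1 = st[cols].to_numpy()[:-1][same]
    d2 = st[cols].to_numpy()[1:][same]
    # g at the shared point = origin of the second step
    g = _metric_at(metric, st["row"].to_numpy()[1:][same])
    ang, valid = _signed_angles(d1, d2, g)
    return AngleDistribution.from_angles(
        ang[valid], bins=bins,
        provenance={"which": "persistence", "method": ts2d.method_tag},
        n_excluded=int((~valid).sum()))


def straightness_index(ts: TrackSet) -> pd.Series:
    """Per-track straightness D = net displacement / total path length."""
    cols = list(ts.coord_cols)
    out = {}
    for tid, grp in ts.data.groupby("track_id", sort=False):
        pos = grp[cols].to_numpy()
        if len(pos) < 2:
            continue
        seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        total = seg.sum()
        if total == 0:
            raise UndefinedAngleError(
                f"track {tid!r} has zero path length; D is undefined")
        out[tid] = float(np.linalg.norm(pos[-1] - pos[0]) / total)
    if not out:
        raise EmptyInputError("no track of length >= 2")
    return pd.Series(out, name="straightness")


def deviation_distance(d: AngleDistribution, truth: AngleDistribution,
                       kind: str = "tv") -> float:
    """Distance between a computed and a reference angle distribution.

    ``tv``  total-variation distance of the binned densities, in [0, 1];
    ``l2``  L2 distance of the binned densities;
    ``ks``  Kolmogorov-Smirnov statistic on the raw angles (both
            distributions must carry raw angles).
    """
    if kind == "ks":
        if d.angles is None or truth.angles is None:
            raise ParameterError("ks distance needs raw angles on both sides")
        return float(sps.ks_2samp(d.angles, truth.angles).statistic)
    if d.n_bins != truth.n_bins or not np.allclose(d.bin_edges, truth.bin_edges):
        raise ParameterError("distributions use different binnings")
    diff = d.density - truth.density
    if kind == "tv":
        return float(0.5 * np.sum(np.abs(diff)) * d.bin_width)
    if kind == "l2":
        return float(np.sqrt(np.sum(diff ** 2) * d.bin_width))
    raise ParameterError(f"unknown deviation kind {kind!r}")


def chi2_uniform_gof(dist: AngleDistribution) -> tuple[float, float]:
    """Pearson chi-square goodness of fit of the raw angles against the
    uniform circular distribution.  Returns (statistic, p value)."""
    if dist.angles is None:
        raise ParameterError("chi-square test needs raw angles")
    counts, _ = np.histogram(dist.angles, bins=dist.bin_edges)
    res = sps.chisquare(counts)
    return float(res.statistic), float(res.pvalue)


def circular_mean(angles) -> tuple[float, float]:
    """Circular mean direction and resultant length R of a sample."""
    z = np.exp(1j * np.asarray(angles, dtype=float))
    m = z.mean()
    return float(np.angle(m)), float(np.abs(m))


def vonmises_concentration(angles) -> dict:
    """Von Mises MLE of (mu, kappa) with an asymptotic 95% CI for kappa.

    The CI uses the Fisher information for kappa at fixed mu,
    Var(kappa_hat) ~ 1 / (n A'(kappa)) with A = I1/I0.
    """
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    if n < 10:
        raise ParameterError("too few angles for a von Mises fit")
    kappa, mu, _ = sps.vonmises.fit(angles, fscale=1)
    A = special.i1(kappa) / special.i0(kappa) if kappa > 0 else 0.0
    Ap = 1.0 - A / kappa - A ** 2 if kappa > 1e-8 else 0.5
    se = np.sqrt(1.0 / (n * max(Ap, 1e-12)))
    return {"mu": float(mu), "kappa": float(kappa),
            "kappa_ci": (float(kappa - 1.96 * se), float(kappa + 1.96 * se)),
            "n": n}
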