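"""Cross-method comparison of 2D reconstructions on one track set.

Runs each requested method — naive xy projection, PCA projection,
two-pass unwrapping, manifold learning with and without the metric —
on the *same* tracks, computes bias and persistence angle
distributions on the identical step set, and scores each against the
true distribution with a deviation distance.  This is the machinery
behind the validation grid (six geometries x three walk models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .directional import (AngleDistribution, bias_angles, deviation_distance,
                          persistence_angles)
from .exceptions import (CurveTracksError, DimensionalityError,
                         DisconnectedGraphError, MetricQualityError,
                         ParameterError)
from .manifold import MetricManifold
from .tracks import TrackSet, pca_plane, project_pca, project_xy
from .unwrap import Unwrapper
from .walks import (preset_model, preset_surface, simulate_walk,
                    true_angle_distribution)

ALL_METHODS = ("xy", "pca", "unwrap", "manifold_euclidean",
               "manifold_metric")

__all__ = ["ALL_METHODS", "MethodOutput", "ComparisonReport",
           "apply_method", "compare_methods", "bootstrap_deviation_ci",
           "paired_difference_ci", "validate_grid"]


@dataclass(frozen=True)
class MethodOutput:
    """A fitted 2D representation plus everything angle statistics need."""
    method: str
    tracks2d: TrackSet
    target2d: np.ndarray | None   # (2,) or per-point (n, 2)
    metric: object | None


def apply_method(ts3d: TrackSet, method: str, target3d=None,
                 unwrap_kw: dict | None = None,
                 manifold_kw: dict | None = None,
                 _manifold_cache: dict | None = None) -> MethodOutput:
    """Run one reconstruction method on a track set.

    The two manifold variants share a single fit (the Euclidean
    baseline is the same embedding scored without its metric) when a
    cache dict is passed.
    """
    target3d = None if target3d is None else np.asarray(target3d, float)
    if method == "xy":
        t2 = project_xy(ts3d)
        return MethodOutput(method, t2,
                            None if target3d is None else target3d[:2], None)
    if method == "pca":
        t2 = project_pca(ts3d)
        tg = None
        if target3d is not None:
            mean, V = pca_plane(ts3d)
            tg = (target3d - mean) @ V.T
        return MethodOutput(method, t2, tg, None)
    if method == "unwrap":
        res = Unwrapper(ts3d, **(unwrap_kw or {})).fit()
        tg = None if target3d is None else res.map_target(target3d)
        return MethodOutput(method, res.tracks2d, tg, None)
    if method in ("manifold_euclidean", "manifold_metric"):
        cache = _manifold_cache if _manifold_cache is not None else {}
        if "fit" not in cache:
            kw = dict(manifold_kw or {})
            if target3d is not None:
                kw.setdefault("extra_points", [target3d])
            cache["fit"] = MetricManifold(ts3d, **kw).fit()
        res = cache["fit"]
        tg = None if res.extra_embedded is None else res.extra_embedded[0]
        metric = res.metric if method == "manifold_metric" else None
        return MethodOutput(method, res.tracks2d, tg, metric)
    raise ParameterError(f"unknown method {method!r}; choose from "
                         f"{ALL_METHODS}")


@dataclass
class ComparisonReport:
    """Tidy per-(method, which) table plus the underlying distributions."""
    table: pd.DataFrame
    distributions: dict
    truth: dict
    notes: dict = field(default_factory=dict)

    def deviation(self, method: str, which: str) -> float:
        m = self.table
        row = m[(m["method"] == method) & (m["which"] == which)]
        if len(row) == 0:
            raise KeyError((method, which))
        return float(row["deviation"].iloc[0])


def compare_methods(ts3d: TrackSet, target3d=None, truth: dict | None = None,
                    methods=ALL_METHODS, bins: int = 36,
                    unwrap_kw: dict | None = None,
                    manifold_kw: dict | None = None) -> ComparisonReport:
    """Run several methods on one track set and score them.

    ``truth`` maps ``"bias"``/``"persistence"`` to reference
    :class:`AngleDistribution` objects (e.g. from
    :func:`true_angle_distribution`); without it, deviations are NaN
    but the distributions are still produced.

    A method that fails with a known degeneracy (disconnected graph,
    1D collapse, indefinite metric) is recorded in ``notes`` instead of
    aborting the whole comparison.
    """
    rows, dists, notes = [], {}, {}
    cache: dict = {}
    counts: dict = {}
    for method in methods:
        try:
            out = apply_method(ts3d, method, target3d=target3d,
                               unwrap_kw=unwrap_kw, manifold_kw=manifold_kw,
                               _manifold_cache=cache)
        except (DimensionalityError, DisconnectedGraphError,
                MetricQualityError) as err:
            notes[method] = f"{type(err).__name__}: {err}"
            continue
        which_list = [("persistence", None)]
        if target3d is not None:
            which_list.append(("bias", out.target2d))
        for which, tg in which_list:
            if which == "bias":
                dist = bias_angles(out.tracks2d, tg, metric=out.metric,
                                   bins=bins)
            else:
                dist = persistence_angles(out.tracks2d, metric=out.metric,
                                          bins=bins)
            dists[(method, which)] = dist
            dev = np.nan
            if truth and which in truth:
                dev = deviation_distance(dist, truth[which])
            rows.append(dict(method=method, which=which, n_steps=dist.n,
                             n_excluded=dist.n_excluded, deviation=dev))
            counts.setdefault(which, set()).add(dist.n + dist.n_excluded)
    for which, ns in counts.items():
        if len(ns) > 1:
            raise CurveTracksError(
                f"methods disagree on the {which} step count: {sorted(ns)}")
    return ComparisonReport(table=pd.DataFrame(rows), distributions=dists,
                            truth=dict(truth or {}), notes=notes)


def bootstrap_deviation_ci(dist: AngleDistribution,
                           truth: AngleDistribution, n_boot: int = 400,
                           seed: int = 0, alpha: float = 0.05):
    """Percentile bootstrap CI for the deviation distance of a sample."""
    rng = np.random.default_rng(seed)
    a = dist.angles
    devs = np.empty(n_boot)
    for b in range(n_boot):
        res = AngleDistribution.from_angles(
            rng.choice(a, size=len(a), replace=True), bins=dist.n_bins)
        devs[b] = deviation_distance(res, truth)
    return (float(np.quantile(devs, alpha / 2)),
            float(np.quantile(devs, 1 - alpha / 2)))


def paired_difference_ci(dist_a: AngleDistribution,
                         dist_b: AngleDistribution,
                         truth: AngleDistribution, n_boot: int = 400,
                         seed: int = 0, alpha: float = 0.05):
    """Bootstrap CI of deviation(a) - deviation(b) on the shared steps.

    Both distributions must hold per-step angles for the identical step
    set in identical order (the compare pipeline guarantees this); the
    paired design removes the shared sampling noise from the
    difference, which a pair of independent CIs would double-count.
    """
    if dist_a.n != dist_b.n:
        raise ParameterError("paired CI needs aligned angle sets")
    rng = np.random.default_rng(seed)
    n = dist_a.n
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        da = AngleDistribution.from_angles(dist_a.angles[idx],
                                           bins=dist_a.n_bins)
        db = AngleDistribution.from_angles(dist_b.angles[idx],
                                           bins=dist_b.n_bins)
        diffs[b] = (deviation_distance(da, truth)
                    - deviation_distance(db, truth))
    return (float(np.quantile(diffs, alpha / 2)),
            float(np.quantile(diffs, 1 - alpha / 2)))


DEFAULT_GRID_SURFACES = ("plane", "cylinder", "hemisphere", "sphere",
                         "ellipsoid_mild", "ellipsoid_thin")
DEFAULT_GRID_WALKS = ("brownian", "biased", "biased_persistent")


def validate_grid(surfaces=DEFAULT_GRID_SURFACES, walks=DEFAULT_GRID_WALKS,
                  n_tracks: int = 50, n_steps: int = 200, seed: int = 7,
                  bins: int = 36, methods=ALL_METHODS):
    """Simulate every (surface, walk) cell, reconstruct with every
    method and score against the walk kernels' true distributions.

    Returns (table, failures, notes):

    * ``table`` — tidy frame: surface, walk, method, which, deviation;
    * ``failures`` — the claim inequalities that failed beyond paired
      bootstrap tolerance (the reconstruction methods should never be
      worse than the raw xy projection, and the metric should not lose
      to the metric-free embedding);
    * ``notes`` — known degeneracies hit (e.g. the thinnest ellipsoid's
      1D collapse), reported rather than raised.
    """
    all_rows, failures, notes = [], [], {}
    rng = np.random.default_rng(seed)
    for si, sname in enumerate(surfaces):
        surface, region, step_length, target = preset_surface(sname)
        for wi, wname in enumerate(walks):
            model = preset_model(wname, sname)
            cell_seed = int(rng.integers(0, 2 ** 31 - 1))
            sim = simulate_walk(surface, model, n_tracks, n_steps,
                                cell_seed, start_region=region)
            truth = {
                "persistence": true_angle_distribution(model, "persistence",
                                                       bins),
                "bias": true_angle_distribution(model, "bias", bins),
            }
            rep = compare_methods(sim.tracks3d, target3d=target, truth=truth,
                                  methods=methods, bins=bins)
            for m, msg in rep.notes.items():
                notes[(sname, wname, m)] = msg
            for _, row in rep.table.iterrows():
                all_rows.append(dict(surface=sname, walk=wname, **row))
            failures.extend(_check_claims(rep, sname, wname, cell_seed))
    return pd.DataFrame(all_rows), failures, notes


def _check_claims(rep: ComparisonReport, sname: str, wname: str, seed: int):
    """The headline inequalities, tested as paired bootstrap CIs.

    A claim only *fails* when the supposedly better method is worse
    beyond the 95% CI of the paired deviation difference.
    """
    failures = []
    pairs = [("unwrap", "xy"), ("manifold_metric", "xy"),
             ("manifold_metric", "manifold_euclidean")]
    for which in ("bias", "persistence"):
        truth = rep.truth.get(which)
        if truth is None:
            continue
        for better, worse in pairs:
            a = rep.distributions.get((better, which))
            b = rep.distributions.get((worse, which))
            if a is None or b is None:
                continue
            try:
                lo, hi = paired_difference_ci(a, b, truth, seed=seed)
            except ParameterError:
                continue
            if lo > 0:  # "better" is significantly worse
                failures.append(
                    f"{sname}/{wname}/{which}: deviation({better}) > "
                    f"deviation({worse}) (95% CI of difference "
                    f"[{lo:.4f}, {hi:.4f}])")
    return failures
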