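"""Track containers, CSV I/O, step decomposition and the linear baselines.

Tracks are stored as a tidy :class:`pandas.DataFrame` with one row per
(track, frame) observation.  The canonical 3D columns are
``track_id, t, x, y, z``; 2D representations use ``track_id, t, u, v``
plus a ``method_tag`` recording which transformation produced them
(``xy`` | ``pca`` | ``unwrap`` | ``manifold``).

Angles computed downstream never depend on the frame interval ``dt``;
``dt`` only scales velocities.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, ParameterError, TrackFormatError

COLS_3D = ("x", "y", "z")
COLS_2D = ("u", "v")


def _canonicalize(df: pd.DataFrame, coord_cols: tuple[str, ...]) -> pd.DataFrame:
    required = ("track_id", "t") + coord_cols
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
    out = df.loc[:, list(required)].copy()
    out["t"] = out["t"].astype(np.int64)
    for c in coord_cols:
        out[c] = out[c].astype(float)
    dup = out.duplicated(subset=["track_id", "t"])
    if dup.any():
        first = out.loc[dup.idxmax(), ["track_id", "t"]]
        raise TrackFormatError(
            f"duplicate (track_id, t) pair: ({first['track_id']!r}, {first['t']})"
        )
    out = out.sort_values(["track_id", "t"], kind="mergesort").reset_index(drop=True)
    return out


@dataclass(frozen=True)
class TrackSet:
    """A collection of time-ordered trajectories sharing a frame interval.

    Parameters
    ----------
    data
        Tidy frame with columns ``track_id, t`` plus the coordinate columns.
        Rows are kept sorted by (track_id, t); (track_id, t) pairs are unique.
    dt
        Time per frame (optional; only used to express velocities).
    method_tag
        For 2D sets, the transformation that produced the representation.
    """

    data: pd.DataFrame
    dt: float | None = None
    method_tag: str | None = None

    @property
    def coord_cols(self) -> tuple[str, ...]:
        return COLS_3D if "z" in self.data.columns else COLS_2D

    @property
    def ndim(self) -> int:
        return len(self.coord_cols)

    @property
    def n_points(self) -> int:
        return len(self.data)

    @property
    def track_ids(self) -> list:
        return list(self.data["track_id"].unique())

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def positions(self) -> np.ndarray:
        """All coordinates as an (n_points, ndim) array in row order."""
        return self.data[list(self.coord_cols)].to_numpy(dtype=float)

    def track(self, track_id) -> pd.DataFrame:
        return self.data[self.data["track_id"] == track_id]

    def with_positions(self, pos: np.ndarray, method_tag: str | None = None
                       ) -> "TrackSet":
        """Same (track_id, t) index with new coordinates (2 or 3 columns)."""
        pos = np.asarray(pos, dtype=float)
        if pos.shape[0] != self.n_points:
            raise ParameterError(
                f"positions have {pos.shape[0]} rows for {self.n_points} points")
        cols = COLS_3D if pos.shape[1] == 3 else COLS_2D
        df = self.data[["track_id", "t"]].copy()
        for j, c in enumerate(cols):
            df[c] = pos[:, j]
        return TrackSet(_canonicalize(df, cols), dt=self.dt,
                        method_tag=method_tag or self.method_tag)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dt: float | None = None,
                       method_tag: str | None = None,
                       columns: dict[str, str] | None = None) -> "TrackSet":
        """Build from a frame, optionally renaming via ``columns``
        (mapping from canonical name to the name used in ``df``)."""
        if columns:
            df = df.rename(columns={v: k for k, v in columns.items()})
        # 2D sets use (u, v); anything else is held to the 3D contract
        is_2d = {"u", "v"} <= set(df.columns) and "x" not in df.columns
        coord_cols = COLS_2D if is_2d else COLS_3D
        if len(df) == 0:
            raise EmptyInputError("track table is empty")
        df = df.copy()
        pos = df[[c for c in coord_cols if c in df.columns]]
        bad = ~np.isfinite(pos.to_numpy(dtype=float)).all(axis=1)
        n_bad = int(bad.sum())
        if n_bad:
            df = df.loc[~bad]
        if len(df) == 0:
            raise EmptyInputError("no rows with finite coordinates")
        ts = cls(_canonicalize(df, coord_cols), dt=dt, method_tag=method_tag)
        object.__setattr__(ts, "n_rejected", n_bad)
        # every track needs >= 2 points to yield any step; single-point
        # tracks are legal input but contribute nothing downstream
        return ts


# 3D/2D aliases used throughout the docs; the container is shared.
TrackSet3D = TrackSet
TrackSet2D = TrackSet


def read_tracks(path, columns: dict[str, str] | None = None,
                dt: float | None = None) -> TrackSet:
    """Read a track table from CSV.

    Parameters
    ----------
    path
        CSV file with a header.  Lines starting with ``#`` are metadata.
    columns
        Optional mapping from canonical names (``track_id, t, x, y, z``)
        to the header names actually present (e.g. TrackMate's
        ``TRACK_ID, FRAME, POSITION_X, ...``).

    Returns
    -------
    TrackSet sorted by (track_id, t).  Rows with non-finite coordinates
    are dropped; their count is available as ``ts.n_rejected``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    meta = {}
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            k, _, v = line[1:].partition("=")
            meta[k.strip()] = v.strip()
        elif not line.startswith("#"):
            break
    try:
        df = pd.read_csv(io.StringIO(text), comment="#",
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} contains no data") from None
    if len(df) == 0:
        raise EmptyInputError(f"{path} contains no data rows")
    tag = meta.get("method_tag")
    if dt is None and "dt" in meta:
        dt = float(meta["dt"])
    return TrackSet.from_dataframe(df, dt=dt, method_tag=tag, columns=columns)


def write_tracks(ts: TrackSet, path) -> None:
    """Write a TrackSet to CSV (header, ``#`` metadata lines, full precision)."""
    if ts.n_points == 0:
        raise EmptyInputError("refusing to write an empty TrackSet")
    path = Path(path)
    lines = []
    if ts.method_tag is not None:
        lines.append(f"# method_tag = {ts.method_tag}")
    if ts.dt is not None:
        lines.append(f"# dt = {ts.dt!r}")
    body = ts.data.to_csv(index=False, float_format="%.17g")
    path.write_text("\n".join(lines + [body]))


def steps(ts: TrackSet, max_gap: int = 0) -> pd.DataFrame:
    """Decompose tracks into per-frame step vectors.

    One step per consecutive frame pair within a track; a track of length
    n yields n-1 steps.  Frame gaps larger than ``max_gap`` (in skipped
    frames) break the track: with the default 0 only t -> t+1 pairs form
    steps.

    Returns
    -------
    DataFrame with columns ``track_id, t_start, dtframes``, origin
    coordinates (``x,y,z`` or ``u,v``) and displacement columns prefixed
    with ``d`` (``dx,dy,dz`` or ``du,dv``).
    """
    cols = list(ts.coord_cols)
    df = ts.data
    gid = df["track_id"].to_numpy()
    tv = df["t"].to_numpy()
    pos = df[cols].to_numpy(dtype=float)
    same = gid[1:] == gid[:-1]
    dtf = tv[1:] - tv[:-1]
    keep = same & (dtf >= 1) & (dtf <= 1 + max_gap)
    rows = np.arange(len(df) - 1)[keep]
    out = pd.DataFrame({
        "track_id": gid[:-1][keep],
        "t_start": tv[:-1][keep],
        "dtframes": dtf[keep],
        "row": rows,  # row index of the step origin in ts.data
    })
    o = pos[:-1][keep]
    d = pos[1:][keep] - o
    for j, c in enumerate(cols):
        out[c] = o[:, j]
    for j, c in enumerate(cols):
        out["d" + c] = d[:, j]
    return out


def project_xy(ts: TrackSet) -> TrackSet:
    """Drop the z coordinate — the naive projection baseline."""
    if ts.ndim != 3:
        raise ParameterError("project_xy expects a 3D TrackSet")
    return ts.with_positions(ts.positions()[:, :2], method_tag="xy")


def pca_plane(ts: TrackSet) -> tuple[np.ndarray, np.ndarray]:
    """Pooled mean and top-2 principal axes (2, 3) of the point cloud.

    Sign convention: in each principal axis the largest-magnitude
    loading is positive, so the projection is deterministic.
    """
    X = ts.positions()
    Xc = X - X.mean(axis=0)
    # SVD of the pooled cloud; right singular vectors are the axes
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if len(s) < 2 or s[1] <= 1e-12 * max(s[0], 1.0):
        raise ParameterError(
            "degenerate covariance: points are (nearly) collinear, "
            "no 2D principal plane exists")
    V = Vt[:2]
    for i in range(2):
        j = np.argmax(np.abs(V[i]))
        if V[i, j] < 0:
            V[i] = -V[i]
    return X.mean(axis=0), V


def project_pca(ts: TrackSet) -> TrackSet:
    """Project the pooled cloud onto its top-2 principal axes.

    Centering and axes are pooled over all points of all tracks (the
    whole dataset is projected through one plane).
    """
    if ts.ndim != 3:
        raise ParameterError("project_pca expects a 3D TrackSet")
    mean, V = pca_plane(ts)
    return ts.with_positions((ts.positions() - mean) @ V.T,
                             method_tag="pca")
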