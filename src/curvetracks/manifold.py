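"""Riemannian (metric) manifold learning for 3D point clouds on surfaces.

Any 2D embedding of a curved surface distorts geometry somewhere.  The
distortion at each point is captured by the pullback metric tensor g, a
position-dependent symmetric positive-semidefinite 2x2 matrix: inner
products computed as u' g v are the true on-surface inner products.
The dual (co-)metric h = g^+ can be estimated directly from data by
applying a graph-Laplacian approximation L of the Laplace-Beltrami
operator to products of the embedding coordinate functions:

    h_kl(i) = 1/2 [ L(f_k f_l) - f_k L(f_l) - f_l L(f_k) ](i)

(the estimator introduced with the LEARNMETRIC algorithm).  g is the
pseudo-inverse of h with an eigenvalue floor.

The graph Laplacian uses density renormalization (alpha = 1), which is
required for convergence to the Laplace-Beltrami operator under
non-uniform sampling — cell tracks oversample wherever cells dwell.
The operator scale is calibrated per node from the local kernel second
moment, which removes the bias that a k-nearest-neighbor truncation of
the heat kernel otherwise leaves at a fixed epsilon^2/4 scale.

Model interface, statsmodels-style::

    res = MetricManifold(tracks, k_embed=10).fit()
    res.tracks2d            # TrackSet2D (method_tag "manifold")
    res.metric.g            # (n, 2, 2) metric field
    res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from sklearn.manifold import LocallyLinearEmbedding
from sklearn.neighbors import NearestNeighbors

from .exceptions import (DimensionalityError, DisconnectedGraphError,
                         EmptyInputError, MetricQualityError, ParameterError,
                         UndefinedAngleError)
from .tracks import TrackSet

__all__ = [
    "NeighborGraph", "MetricField", "build_graph", "graph_laplacian",
    "lle_embed", "spectral_embed", "estimate_metric",
    "riemannian_inner", "riemannian_norm",
    "riemannian_angle", "MetricManifold", "MetricManifoldResult",
]


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetrized k-NN graph with heat-kernel weights
    w_ij = exp(-|x_i - x_j|^2 / eps^2) (self-weight 1)."""
    weights: sparse.csr_matrix   # symmetric, incl. unit diagonal
    dist2: sparse.csr_matrix     # squared distances on the same sparsity
    bandwidth: float
    k: int

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def median_knn_distance(points: np.ndarray, k: int = 50) -> float:
    """Median distance to the k-th nearest neighbor (default bandwidth).

    The default k = 50 looks beyond a track's own consecutive points:
    tracks oversample along their path, so a 10-NN distance would
    reflect the frame spacing instead of the cloud density and set the
    bandwidth far too small.
    """
    nn = NearestNeighbors(n_neighbors=min(k, len(points) - 1) + 1).fit(points)
    d, _ = nn.kneighbors(points)
    return float(np.median(d[:, -1]))


def build_graph(points: np.ndarray, k: int | None = None,
                bandwidth: float | None = None) -> NeighborGraph:
    """Symmetric k-NN graph (union of directed k-NN) with heat-kernel
    weights; verifies connectivity.

    ``bandwidth`` defaults to the median 50-NN distance of the cloud —
    the scale below which the surface is treated as flat.  ``k``
    defaults to 5x the bandwidth neighbor count so the graph reaches
    ~2.2 bandwidths out and the kernel truncation is negligible.
    """
    X = np.asarray(points, dtype=float)
    n = len(X)
    if k is None:
        k = min(n - 1, 250)
    if n < k + 1:
        raise ParameterError(f"need at least k+1 = {k + 1} points")
    if bandwidth is None:
        bandwidth = median_knn_distance(X)
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be positive")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    d, j = nn.kneighbors(X)
    i = np.repeat(np.arange(n), k + 1)
    D = sparse.csr_matrix((d.ravel() ** 2, (i, j.ravel())), shape=(n, n))
    D = D.maximum(D.T)  # union symmetrization
    D.setdiag(0.0)
    W = D.copy()
    W.data = np.exp(-W.data / bandwidth ** 2)
    W.setdiag(1.0)  # self-weight convention
    ncomp, labels = connected_components(W > 0, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise DisconnectedGraphError(sizes.tolist())
    return NeighborGraph(weights=W.tocsr(), dist2=D.tocsr(),
                         bandwidth=float(bandwidth), k=k)


@dataclass(frozen=True)
class Laplacian:
    """Graph approximation of the Laplace-Beltrami operator.

    Sign convention: L f ~ Delta f with Delta(x^2) = +2 on flat space,
    so L annihilates constants exactly and is negative on pure
    harmonics (L sin = -sin on the unit circle).
    """
    matrix: sparse.csr_matrix    # L = diag(2/(m2)) (P - I)
    transition: sparse.csr_matrix  # row-stochastic P (alpha = 1)
    m2: np.ndarray               # per-node kernel second moment / dim
    bandwidth: float

    def __call__(self, f: np.ndarray) -> np.ndarray:
        return self.matrix @ f


def graph_laplacian(graph: NeighborGraph, intrinsic_dim: int = 2,
                    alpha: float = 1.0) -> Laplacian:
    """Density-renormalized random-walk graph Laplacian.

    alpha = 1 removes the sampling-density bias (Laplace-Beltrami limit
    regardless of how unevenly the surface is sampled).  The operator
    scale 2/m2 comes from the per-node second moment of the transition
    kernel, m2 = sum_j P_ij |x_j - x_i|^2 / dim, instead of the nominal
    eps^2/4: the two agree for an untruncated Gaussian kernel, but the
    per-node form stays calibrated under k-NN truncation and variable
    local geometry.
    """
    W = graph.weights
    q = np.asarray(W.sum(axis=1)).ravel()
    if alpha != 0:
        Dq = sparse.diags(1.0 / q ** alpha)
        K = Dq @ W @ Dq
    else:
        K = W
    d = np.asarray(K.sum(axis=1)).ravel()
    P = sparse.diags(1.0 / d) @ K
    m2 = np.asarray(P.multiply(graph.dist2).sum(axis=1)).ravel() / intrinsic_dim
    if np.any(m2 <= 0):
        raise ParameterError("a node has no neighbors at this bandwidth")
    L = sparse.diags(2.0 / m2) @ (P - sparse.eye(graph.n_nodes, format="csr"))
    return Laplacian(matrix=L.tocsr(), transition=P.tocsr(), m2=m2,
                     bandwidth=graph.bandwidth)


def lle_embed(points: np.ndarray, k: int = 20, n_components: int = 2,
              method: str = "modified",
              dimensionality_check: bool = True) -> np.ndarray:
    """Locally linear embedding to 2D, deterministic signs.

    The modified-weights variant (MLLE) is the default: the standard
    single-weight LLE eigenproblem is prone to spurious localized
    eigenvectors on densely sampled track data, which MLLE's
    multi-weight regularization removes.

    Raises
    ------
    DimensionalityError
        When the embedding collapses to a filament — the known failure
        mode on very narrow surfaces sampled sparsely, where the
        algorithm reads the cloud as a 1D line.
    """
    X = np.asarray(points, dtype=float)
    if k < 3:
        raise ParameterError("LLE needs k >= 3")
    if len(X) < 5 * k:
        raise ParameterError("too few points for a stable embedding")
    lle = LocallyLinearEmbedding(n_neighbors=k, n_components=n_components,
                                 method=method, random_state=0)
    Y = lle.fit_transform(X)
    for c in range(Y.shape[1]):
        nz = np.flatnonzero(np.abs(Y[:, c]) > 1e-12 * np.abs(Y[:, c]).max())
        if len(nz) and Y[nz[0], c] < 0:
            Y[:, c] = -Y[:, c]
    if dimensionality_check and n_components == 2:
        r = _local_aspect_ratio(Y)
        if r < 0.05:
            raise DimensionalityError(
                "embedding collapsed to a 1D filament (median local "
                f"aspect ratio {r:.4f} < 0.05): the data's spatial extent "
                "in one direction is not resolved at this sampling; "
                "more points or a different method are needed")
    return Y


def spectral_embed(graph: NeighborGraph, n_components: int = 2,
                   dimensionality_check: bool = True) -> np.ndarray:
    """Laplacian-eigenmaps chart from the density-renormalized kernel.

    The two slowest non-trivial eigenfunctions of the diffusion
    operator give a smooth 2D chart of an open patch.  Unlike the LLE
    eigenproblem this is robust to the filamentary sampling of track
    data, provided the kernel bandwidth exceeds the track spacing.
    Deterministic (fixed start vector).
    """
    W = graph.weights
    q = np.asarray(W.sum(axis=1)).ravel()
    Dq = sparse.diags(1.0 / q)
    K1 = Dq @ W @ Dq
    d = np.asarray(K1.sum(axis=1)).ravel()
    Dm = sparse.diags(d ** -0.5)
    S = Dm @ K1 @ Dm
    n = S.shape[0]
    try:
        vals, vecs = sparse.linalg.eigsh(
            S, k=n_components + 1, which="LA", ncv=min(n, 64),
            maxiter=max(2000, n), v0=np.ones(n) / np.sqrt(n))
    except sparse.linalg.ArpackNoConvergence as err:
        # a vanishing spectral gap: the cloud is fragmented or does not
        # resolve a second dimension at this sampling
        raise DimensionalityError(
            "spectral chart did not converge — the sampled cloud is too "
            "sparse or fragmented to resolve a 2D chart") from err
    order = np.argsort(-vals)
    Y = np.asarray(Dm @ vecs[:, order[1:n_components + 1]])
    for c in range(Y.shape[1]):
        nz = np.flatnonzero(np.abs(Y[:, c]) > 1e-12 * np.abs(Y[:, c]).max())
        if len(nz) and Y[nz[0], c] < 0:
            Y[:, c] = -Y[:, c]
    if dimensionality_check and n_components == 2:
        r = _local_aspect_ratio(Y)
        if r < 0.05:
            raise DimensionalityError(
                "embedding collapsed to a 1D filament (median local "
                f"aspect ratio {r:.4f} < 0.05): the data's spatial extent "
                "in one direction is not resolved at this sampling")
    return Y


def _local_aspect_ratio(Y: np.ndarray, k: int = 10, sample: int = 500) -> float:
    """Median ratio of local singular values — ~O(1) for a genuinely 2D
    embedding, near 0 along a filament."""
    n = len(Y)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(Y)
    idx = np.linspace(0, n - 1, min(sample, n)).astype(int)
    _, j = nn.kneighbors(Y[idx])
    ratios = np.empty(len(idx))
    for a, row in enumerate(j):
        nb = Y[row] - Y[row].mean(axis=0)
        sv = np.linalg.svd(nb, compute_uv=False)
        ratios[a] = sv[1] / sv[0] if sv[0] > 0 else 0.0
    return float(np.median(ratios))


@dataclass(frozen=True)
class MetricField:
    """Per-point metric g, co-metric h, pseudo-inverse rank and a
    boundary flag (estimator bias grows at the chart boundary)."""
    g: np.ndarray         # (n, 2, 2)
    h: np.ndarray         # (n, 2, 2)
    rank: np.ndarray      # (n,)
    boundary: np.ndarray  # (n,) bool

    def __len__(self):
        return len(self.g)


def _eigh2(M):
    """Closed-form eigendecomposition of symmetric 2x2 matrices (n,2,2)."""
    a, b, c = M[:, 0, 0], M[:, 0, 1], M[:, 1, 1]
    tr = a + c
    disc = np.sqrt(np.maximum(((a - c) / 2) ** 2 + b * b, 0.0))
    l1, l2 = tr / 2 + disc, tr / 2 - disc
    theta = 0.5 * np.arctan2(2 * b, a - c)
    ct, st = np.cos(theta), np.sin(theta)
    V = np.empty_like(M)
    V[:, 0, 0], V[:, 1, 0] = ct, st     # eigenvector of l1
    V[:, 0, 1], V[:, 1, 1] = -st, ct    # eigenvector of l2
    return np.stack([l1, l2], axis=1), V


def estimate_metric(embedding: np.ndarray, lap: Laplacian,
                    points3d: np.ndarray | None = None,
                    centered: bool = True,
                    smooth: int = 0,
                    indefinite_tol: float = 0.1,
                    max_indefinite_frac: float = 0.05) -> MetricField:
    """Per-point co-metric h and metric g from coordinate functions.

    The raw estimator h_kl = 1/2[L(f_k f_l) - f_k L f_l - f_l L f_k]
    reduces, node by node, to the kernel-weighted second moment of the
    coordinate differences (scaled by 2/m2); ``centered`` subtracts the
    kernel mean-shift outer product, turning the moment into a local
    covariance.  The two forms agree in the interior, but centering
    removes the leading boundary bias of the estimator (the mean shift
    is first-order at a chart boundary, zero inside).  Requires
    ``points3d`` to also center the length scale m2.

    ``smooth`` optional neighborhood-averaging sweeps of the h field
    (off by default: averaging across regions where the chart's
    Jacobian varies introduces bias faster than it removes variance on
    typical track data).

    Raises
    ------
    MetricQualityError
        If h is indefinite beyond tolerance at more than 5% of points,
        which signals a badly chosen bandwidth.
    """
    f = np.asarray(embedding, dtype=float)
    if f.ndim != 2 or f.shape[1] != 2:
        raise ParameterError("embedding must be (n, 2)")
    if f.shape[0] != lap.matrix.shape[0]:
        raise ParameterError("embedding and Laplacian sizes differ")
    P = lap.transition
    m2 = lap.m2.copy()
    mu = None
    ms_norm = np.zeros(len(f))
    if points3d is not None:
        X = np.asarray(points3d, dtype=float)
        muX = P @ X - X
        ms_norm = np.linalg.norm(muX, axis=1) / np.sqrt(
            np.maximum(m2 * 2, 1e-300))
    if centered:
        mu = np.column_stack([P @ f[:, 0] - f[:, 0], P @ f[:, 1] - f[:, 1]])
        if points3d is not None:
            m2 = m2 - np.sum(muX ** 2, axis=1) / 2.0
            m2 = np.maximum(m2, 1e-12 * np.median(lap.m2))
    h = np.empty((len(f), 2, 2))
    for k in range(2):
        for l in range(k, 2):
            val = P @ (f[:, k] * f[:, l]) - f[:, k] * (P @ f[:, l]) \
                - f[:, l] * (P @ f[:, k]) + f[:, k] * f[:, l]
            if centered:
                val = val - mu[:, k] * mu[:, l]
            h[:, k, l] = h[:, l, k] = val / m2
    for _ in range(max(0, smooth)):
        for k in range(2):
            for l in range(2):
                h[:, k, l] = P @ h[:, k, l]

    lam, V = _eigh2(h)
    tr = np.maximum(lam.sum(axis=1), 0.0)
    # judged against the global field scale: a near-zero h is rank
    # deficient, not indefinite
    tr_scale = np.median(tr) + 1e-300
    frac_indef = float(np.mean(lam[:, 1] < -indefinite_tol * tr_scale))
    if frac_indef > max_indefinite_frac:
        raise MetricQualityError(
            f"co-metric indefinite at {frac_indef:.1%} of points "
            "(> 5%); adjust the bandwidth")
    floor = 1e-8 * np.maximum(tr, 1e-300)
    lam_f = np.where(lam > floor[:, None], lam, 0.0)
    rank = (lam_f > 0).sum(axis=1)
    inv = np.where(lam_f > 0, 1.0 / np.where(lam_f > 0, lam_f, 1.0), 0.0)
    g = np.einsum("nij,nj,nkj->nik", V, inv, V)
    hp = np.einsum("nij,nj,nkj->nik", V, lam_f, V)
    boundary = ms_norm > 0.2
    return MetricField(g=g, h=hp, rank=rank, boundary=boundary)


# ---------------------------------------------------------------------------
# metric-aware inner products
# ---------------------------------------------------------------------------

def riemannian_inner(u, v, g) -> np.ndarray:
    """u' g v (batched over leading dimension when arrays are stacked)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    g = np.asarray(g, dtype=float)
    if u.ndim == 1:
        return float(u @ g @ v)
    return np.einsum("ni,nij,nj->n", u, g, v)


def riemannian_norm(u, g) -> np.ndarray:
    val = riemannian_inner(u, u, g)
    return np.sqrt(np.maximum(val, 0.0))


def riemannian_angle(u, v, g, signed: bool = True):
    """Angle between u and v under metric g.

    The sign uses the metric's orientation (sqrt(det g) times the
    coordinate cross product), counterclockwise positive.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    g = np.asarray(g, dtype=float)
    single = u.ndim == 1
    u2 = np.atleast_2d(u)
    v2 = np.atleast_2d(v)
    g2 = g[None] if g.ndim == 2 else g
    dot = np.einsum("ni,nij,nj->n", u2, g2, v2)
    nu = riemannian_norm(u2, g2)
    nv = riemannian_norm(v2, g2)
    if np.any(nu == 0) or np.any(nv == 0):
        raise UndefinedAngleError("zero-norm vector has no direction")
    cross = np.sqrt(np.maximum(np.linalg.det(g2), 0.0)) * (
        u2[:, 0] * v2[:, 1] - u2[:, 1] * v2[:, 0])
    ang = np.arctan2(cross, dot) if signed else np.arccos(
        np.clip(dot / (nu * nv), -1.0, 1.0))
    return float(ang[0]) if single else ang


# ---------------------------------------------------------------------------
# model interface
# ---------------------------------------------------------------------------

class MetricManifold:
    """Riemannian manifold learning model for a 3D track set.

    Embeds the cloud in 2D with locally linear embedding and estimates
    the per-point metric tensor from the density-renormalized graph
    Laplacian, so downstream angle/length statistics can undo the
    embedding's distortion.

    Parameters
    ----------
    data
        TrackSet3D or (n, 3) point array.
    embedding
        2D chart: ``"eigenmaps"`` (default; Laplacian eigenmaps from
        the package's own diffusion kernel — robust on filamentary
        track data), one of the LLE variants
        ``standard | modified | hessian | ltsa``, or ``"precomputed"``
        with coordinates in ``embedding_coords`` (e.g. an unwrapping
        chart: the metric estimator applies to any smooth invertible
        2D map).
    bandwidth
        Heat-kernel bandwidth of the metric graph; defaults to the
        median 50-NN distance of the cloud.  The chart operator uses
        ``chart_bandwidth_factor`` times this value — the chart should
        be smooth above the track-filament spacing, while the metric
        wants the smallest bandwidth the sampling supports.
    k_embed
        Neighbors for the LLE variants.
    extra_points
        Optional (m, 3) positions (e.g. an attractant) mapped jointly
        with the data; their 2D images are in ``result.extra_embedded``.
    smooth
        Neighborhood-averaging sweeps applied to the estimated
        co-metric field (default 0).

    Examples
    --------
    >>> res = MetricManifold(tracks, extra_points=[wound]).fit()
    >>> dist = bias_angles(res.tracks2d, res.extra_embedded[0],
    ...                    metric=res.metric)
    """

    def __init__(self, data, embedding: str = "eigenmaps",
                 bandwidth: float | None = None,
                 chart_bandwidth_factor: float = 2.0,
                 k_embed: int = 20, k_graph: int | None = None,
                 extra_points=None, smooth: int = 0,
                 embedding_coords: np.ndarray | None = None):
        if isinstance(data, TrackSet):
            if data.ndim != 3:
                raise ParameterError("MetricManifold needs 3D data")
            self.tracks = data
            self.X = data.positions()
        else:
            self.tracks = None
            self.X = np.asarray(data, dtype=float)
        if len(self.X) == 0:
            raise EmptyInputError("no points")
        valid = ("eigenmaps", "standard", "modified", "hessian", "ltsa",
                 "precomputed")
        if embedding not in valid:
            raise ParameterError(f"embedding must be one of {valid}")
        if embedding == "precomputed" and embedding_coords is None:
            raise ParameterError(
                "precomputed embedding needs embedding_coords")
        self.embedding_method = embedding
        self.embedding_coords = embedding_coords
        self.k_embed = k_embed
        self.k_graph = k_graph
        self.bandwidth = bandwidth
        self.chart_bandwidth_factor = chart_bandwidth_factor
        self.smooth = smooth
        self.extra = (None if extra_points is None
                      else np.atleast_2d(np.asarray(extra_points, float)))

    def fit(self) -> "MetricManifoldResult":
        X = self.X
        n = len(X)
        if self.extra is not None:
            X = np.vstack([X, self.extra])
        bw = self.bandwidth
        if bw is None:
            bw = median_knn_distance(X)
        # fast pre-check: sparse tracks form 1D filaments in 3D; no 2D
        # chart can be learned from a locally one-dimensional cloud
        r3d = _local_aspect_ratio(X, k=30)
        if r3d < 0.05:
            raise DimensionalityError(
                "the 3D cloud is locally one-dimensional (median local "
                f"aspect ratio {r3d:.4f} < 0.05): the tracks are too "
                "sparse to reveal the surface's second dimension")
        if self.embedding_method == "eigenmaps":
            k_chart = min(len(X) - 1,
                          (self.k_graph or 250) *
                          max(1, int(self.chart_bandwidth_factor ** 2 / 2)))
            chart_graph = build_graph(
                X, k=k_chart, bandwidth=self.chart_bandwidth_factor * bw)
            Y = spectral_embed(chart_graph)
        elif self.embedding_method == "precomputed":
            Y = np.asarray(self.embedding_coords, dtype=float)
            if len(Y) != len(X):
                raise ParameterError(
                    "embedding_coords must cover data plus extra points")
        else:
            Y = lle_embed(X, k=self.k_embed, method=self.embedding_method)
        graph = build_graph(X, k=self.k_graph, bandwidth=bw)
        lap = graph_laplacian(graph, intrinsic_dim=2)
        metric_all = estimate_metric(Y, lap, points3d=X,
                                     smooth=self.smooth)
        metric = MetricField(g=metric_all.g[:n], h=metric_all.h[:n],
                             rank=metric_all.rank[:n],
                             boundary=metric_all.boundary[:n])
        tracks2d = None
        if self.tracks is not None:
            tracks2d = self.tracks.with_positions(Y[:n],
                                                  method_tag="manifold")
        return MetricManifoldResult(
            model=self, embedding=Y[:n], tracks2d=tracks2d, metric=metric,
            extra_embedded=None if self.extra is None else Y[n:],
            graph=graph, laplacian=lap)


@dataclass
class MetricManifoldResult:
    """Fitted embedding + metric field with diagnostics."""
    model: MetricManifold
    embedding: np.ndarray
    tracks2d: TrackSet | None
    metric: MetricField
    extra_embedded: np.ndarray | None
    graph: NeighborGraph
    laplacian: Laplacian

    def summary(self) -> str:
        detg = np.linalg.det(self.metric.g)
        lines = [
            "Riemannian manifold learning summary",
            "====================================",
            f"points                 {len(self.embedding)}",
            f"embedding              {self.model.embedding_method}",
            f"graph                  k={self.graph.k}, "
            f"bandwidth={self.graph.bandwidth:.4g}",
            f"metric rank 2          {np.mean(self.metric.rank == 2):.1%}",
            f"boundary-flagged       {np.mean(self.metric.boundary):.1%}",
            f"median sqrt(det g)     {np.median(np.sqrt(np.maximum(detg, 0))):.4g}",
        ]
        return "\n".join(lines)
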