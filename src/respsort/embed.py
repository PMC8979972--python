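"""One-dimensional Laplacian-Eigenmaps respiratory curve.

The diaphragm ROI sub-images ``x_1 ... x_N`` (one flattened vector per
frame) are turned into a weighted adjacency graph whose edge weights are
Gaussian-kernel intensity similarities,

    W(i, j) = exp(-||x_i - x_j||^2 / (2 sigma^2))   for connected i, j,

and the respiratory curve ``y_1 ... y_N`` is the minimizer of

    phi(y) = sum_ij (y_i - y_j)^2 W(i, j)

subject to y' D y = 1 and y' D 1 = 0 (D = diagonal degree matrix), i.e. the
generalized eigenvector of L = D - W for the smallest nonzero eigenvalue of
L y = lambda D y.

Graph connectivity determines what the curve means.  The package supports
three constructions:

* ``temporal`` -- each frame connects to its k temporally nearest
  neighbours (floor(k/2) before, ceil(k/2) after).  On its own this banded
  graph is path-like and its first nontrivial eigenvector is a monotone
  function of acquisition time (one sign change, by Sturm oscillation
  theory), so it carries no respiratory oscillation.
* ``intensity`` -- classical Laplacian Eigenmaps: k nearest neighbours in
  image space, which ties together same-displacement frames from different
  breaths.
* ``hybrid`` (default) -- the union of both edge sets.  The temporal band
  regularizes the manifold; the intensity edges make the embedding a
  function of diaphragm position rather than of time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh, lobpcg

from .io import CineSeries, RespROI, crop_roi

__all__ = [
    "TemporalGraph",
    "RespCurve",
    "build_temporal_knn_graph",
    "build_intensity_knn_graph",
    "estimate_sigma2",
    "gaussian_weight",
    "laplacian_embedding_1d",
    "orient_curve",
    "respiratory_curve",
]


@dataclass
class TemporalGraph:
    """Weighted adjacency graph over the N frames.

    ``edges`` is an (m, 2) integer array with i < j per row; ``weights``
    holds W(i, j) in (0, 1] for each edge; ``sigma2`` the Gaussian kernel
    variance used to compute them.
    """

    n_nodes: int
    k: int
    edges: np.ndarray
    weights: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.edges.ndim != 2 or self.edges.shape[1] != 2:
            raise ValueError("edges must be an (m, 2) array")
        if len(self.weights) != len(self.edges):
            raise ValueError("weights length must match edges")
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("edge weights must lie in (0, 1]")

    def adjacency(self) -> sparse.csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.weights
        return sparse.csr_matrix(
            (np.r_[w, w], (np.r_[i, j], np.r_[j, i])),
            shape=(self.n_nodes, self.n_nodes))

    @classmethod
    def from_sub_images(cls, sub_images: np.ndarray, k: int = 10,
                        sigma2: float | None = None,
                        mode: str = "hybrid") -> "TemporalGraph":
        """Build the graph for a sub-image sequence (one row per frame)."""
        X = np.asarray(sub_images, dtype=float)
        n = X.shape[0]
        if mode == "temporal":
            edges = build_temporal_knn_graph(n, k)
        elif mode == "intensity":
            edges = build_intensity_knn_graph(X, k)
        elif mode == "hybrid":
            et = build_temporal_knn_graph(n, k)
            ei = build_intensity_knn_graph(X, k)
            edges = np.unique(np.vstack([et, ei]), axis=0)
        else:
            raise ValueError(f"unknown graph mode {mode!r}")
        d2 = np.sum((X[edges[:, 0]] - X[edges[:, 1]]) ** 2, axis=1)
        if sigma2 is None:
            sigma2 = estimate_sigma2(X, edges)
        w = gaussian_weight(d2, sigma2)
        return cls(n_nodes=n, k=k, edges=edges, weights=w, sigma2=sigma2)


def build_temporal_knn_graph(n: int, k: int) -> np.ndarray:
    """Edge set connecting each frame to its k temporally nearest neighbours.

    Node i connects to the floor(k/2) preceding and ceil(k/2) following
    frames, truncated at the sequence boundaries; the edge set is
    symmetrized by union. Returns an (m, 2) array of node pairs with i < j.
    """
    if n < 4:
        raise ValueError("need at least 4 frames")
    if k < 2:
        raise ValueError("k too small")
    if k >= n:
        raise ValueError("k too large")
    before, after = k // 2, (k + 1) // 2
    edges = set()
    for i in range(n):
        for j in range(max(0, i - before), i):
            edges.add((j, i))
        for j in range(i + 1, min(n, i + after + 1)):
            edges.add((i, j))
    return np.array(sorted(edges), dtype=int)


def build_intensity_knn_graph(sub_images: np.ndarray, k: int) -> np.ndarray:
    """Edge set connecting each frame to its k nearest neighbours in image space."""
    X = np.asarray(sub_images, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 frames")
    if k < 2:
        raise ValueError("k too small")
    if k >= n:
        raise ValueError("k too large")
    sq = np.sum(X ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, np.inf)
    nn = np.argpartition(d2, kth=k - 1, axis=1)[:, :k]
    edges = set()
    for i in range(n):
        for j in nn[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            edges.add((a, b))
    return np.array(sorted(edges), dtype=int)


def estimate_sigma2(sub_images: np.ndarray, edges: np.ndarray) -> float:
    """Self-tuned kernel variance: median edge squared distance / 2.

    When the plain median is zero (identical frames within plateaus) the
    median of the positive distances is used instead; if every edge distance
    is zero the sequence carries no signal.
    """
    X = np.asarray(sub_images, dtype=float)
    edges = np.asarray(edges, dtype=int)
    if len(edges) == 0:
        raise ValueError("degenerate sequence: no edges")
    d2 = np.sum((X[edges[:, 0]] - X[edges[:, 1]]) ** 2, axis=1)
    med = float(np.median(d2))
    if med <= 0:
        pos = d2[d2 > 0]
        if len(pos) == 0:
            raise ValueError("degenerate sequence: all edge distances zero")
        med = float(np.median(pos))
    return med / 2.0


def gaussian_weight(squared_distance, sigma2: float, connected: bool = True):
    """Gaussian kernel weight exp(-d^2 / (2 sigma^2)); 0 when not connected."""
    if sigma2 <= 0:
        raise ValueError("invalid bandwidth: sigma2 must be positive")
    if not connected:
        return np.zeros_like(np.asarray(squared_distance, dtype=float))
    return np.exp(-np.asarray(squared_distance, dtype=float) / (2.0 * sigma2))


@dataclass
class RespCurve:
    """Per-frame scalar respiratory embedding.

    After orientation fixing, local maxima correspond to end expiration.
    ``orientation`` is ``"expiration-up"`` once fixed, ``"expiration-down"``
    for a raw curve known to be inverted, or ``"undetermined"``.
    """

    values: np.ndarray
    orientation: str = "undetermined"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding failed: non-finite curve values")

    @property
    def n_frames(self) -> int:
        return len(self.values)


def objective(values: np.ndarray, graph: TemporalGraph) -> float:
    """phi(y) = sum over ordered pairs of W(i,j) (y_i - y_j)^2."""
    y = np.asarray(values, dtype=float)
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    return float(2.0 * np.sum(graph.weights * (y[i] - y[j]) ** 2))


def _solve_fiedler(L: sparse.csc_matrix, deg: np.ndarray) -> tuple[np.ndarray, float, str]:
    """Smallest-nonzero generalized eigenpair of L y = lambda D y."""
    n = L.shape[0]
    D = sparse.diags(deg).tocsc()
    scale = float(deg.mean())
    try:
        vals, vecs = eigsh(L, k=2, M=D, sigma=-1e-3 * scale, maxiter=5000, tol=0)
        order = np.argsort(vals)
        return vecs[:, order[1]], float(vals[order[1]]), "arpack"
    except Exception:
        pass
    try:  # larger subspace often converges where k=2 stalls
        kk = min(6, n - 1)
        vals, vecs = eigsh(L, k=kk, M=D, sigma=-1e-3 * scale, maxiter=5000)
        order = np.argsort(vals)
        return vecs[:, order[1]], float(vals[order[1]]), "arpack-k6"
    except Exception:
        pass
    rng = np.random.default_rng(12345)
    Y = np.ones((n, 1))
    X0 = rng.standard_normal((n, 2))
    with np.errstate(all="ignore"):
        vals, vecs = lobpcg(L, X0, B=sparse.diags(deg), Y=Y, largest=False,
                            maxiter=1000, tol=1e-9)
    order = np.argsort(vals)
    return vecs[:, order[0]], float(vals[order[0]]), "lobpcg"


def laplacian_embedding_1d(graph: TemporalGraph) -> RespCurve:
    """Solve the 1D embedding on a connected weighted graph.

    Returns the generalized eigenvector of L = D - W for the smallest
    nonzero eigenvalue of L y = lambda D y, normalized to y' D y = 1 and
    deflated against the constant mode (y' D 1 = 0); this minimizes phi
    among all feasible curves.  Orientation is left undetermined.
    """
    if graph.n_nodes < 4:
        raise ValueError("need at least 4 frames")
    W = graph.adjacency()
    ncomp, _ = connected_components(W, directed=False)
    if ncomp > 1:
        raise ValueError("graph not connected")
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = (sparse.diags(deg) - W).tocsc()
    y, lam, solver = _solve_fiedler(L, deg)
    # deflate the constant mode and D-normalize
    y = y - (y @ (deg * np.ones_like(y))) / deg.sum()
    nrm = float(np.sqrt(y @ (deg * y)))
    if nrm <= 0 or not np.isfinite(nrm):
        raise ValueError("embedding failed: degenerate eigenvector")
    y = y / nrm
    residual = float(np.linalg.norm(L @ y - lam * deg * y))
    if not np.isfinite(residual) or residual > 1e-4 * max(1.0, abs(lam)) * np.sqrt(len(y)):
        raise ValueError(f"embedding failed: residual {residual:.2e}")
    if y[np.argmax(np.abs(y))] < 0:  # canonical sign before orientation
        y = -y
    return RespCurve(values=y, orientation="undetermined",
                     provenance={"k": graph.k, "sigma2": graph.sigma2,
                                 "eigenvalue": lam, "solver": solver,
                                 "residual": residual})


def orient_curve(curve: RespCurve, sub_images: np.ndarray,
                 roi_shape: tuple[int, int],
                 weak_correlation: float = 0.3) -> RespCurve:
    """Fix the sign so local maxima correspond to end expiration.

    Primary heuristic: the intensity-weighted vertical centroid of the ROI
    tracks the diaphragm; the diaphragm is most cranial (lowest row index)
    at end expiration, so the oriented curve must anticorrelate with the
    centroid row.  When the centroid correlation is weak (|r| below
    ``weak_correlation``) the plateau-duration heuristic is used (the
    extreme with more frames in its neighbourhood is expiration); if that is
    also uninformative the orientation stays undetermined.
    """
    X = np.asarray(sub_images, dtype=float)
    n_rows, n_cols = roi_shape
    if X.shape[1] != n_rows * n_cols:
        raise ValueError("ROI outside image: sub-image size does not match roi_shape")
    y = curve.values.copy()
    rows = np.repeat(np.arange(n_rows, dtype=float), n_cols)
    weights = X - X.min() + 1e-12
    centroid = (weights @ rows) / weights.sum(axis=1)

    method, r = "centroid", np.nan
    sy, sc = np.std(y), np.std(centroid)
    if sy > 0 and sc > 0:
        r = float(np.corrcoef(y, centroid)[0, 1])
    if np.isfinite(r) and abs(r) >= weak_correlation:
        if r > 0:  # maxima currently at caudal diaphragm = inspiration
            y = -y
        orientation = "expiration-up"
    else:
        # plateau-duration fallback: expiration occupies the longer extreme
        rng_y = y.max() - y.min()
        if rng_y > 0:
            eps = 0.1 * rng_y
            n_hi = int(np.sum(y >= y.max() - eps))
            n_lo = int(np.sum(y <= y.min() + eps))
        else:
            n_hi = n_lo = 0
        method = "plateau"
        if n_hi > n_lo:
            orientation = "expiration-up"
        elif n_lo > n_hi:
            y = -y
            orientation = "expiration-up"
        else:
            orientation = "undetermined"
            method = "none"
    prov = dict(curve.provenance)
    prov.update({"orientation_method": method, "centroid_correlation": r})
    return RespCurve(values=y, orientation=orientation, provenance=prov)


def respiratory_curve(series: CineSeries, roi: RespROI, k: int = 10,
                      sigma2: float | None = None,
                      graph_mode: str = "hybrid") -> RespCurve:
    """Convenience pipeline: crop ROI, build graph, embed, orient."""
    X = crop_roi(series, roi)
    graph = TemporalGraph.from_sub_images(X, k=k, sigma2=sigma2, mode=graph_mode)
    curve = laplacian_embedding_1d(graph)
    return orient_curve(curve, X, roi.shape)
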