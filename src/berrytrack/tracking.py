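"""Time-consistent berry labelling across an image series.

Tracking combines three ingredients:

* *baseline* — greedy one-to-one nearest-neighbour matching of berry
  centre points between two frames, with pairs further than
  delta = 16 px discarded;
* *registration* — affine coherent point drift (CPD) realigning one
  centre set onto another before matching, absorbing global
  bunch/camera motion;
* *matching tree* — a layered tree over time steps, built from a
  pairwise set-distance matrix, choosing the best root frame and the
  order in which labels propagate so that dissimilar frame pairs are
  never matched directly.

The set distance d(S_i, S_j) is the median over points of S_i of the
nearest-neighbour distance to S_j; D symmetrizes it by averaging both
directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from berrytrack.features import BerryObservation

__all__ = [
    "DELTA",
    "THETA",
    "FrameSet",
    "AffineCPD",
    "MatchingTree",
    "TrackTable",
    "greedy_match",
    "register_affine",
    "set_distance_d",
    "symmetric_distance_D",
    "build_distance_matrix",
    "build_matching_tree",
    "select_root",
    "propagate_labels",
    "track",
]

DELTA = 16.0  # px; matching pairs further apart are discarded
THETA = 8.0   # px; set-distance threshold of the matching tree


@dataclass
class FrameSet:
    """Berry centre points of one time step, with their observations."""

    t: int
    observations: list[BerryObservation] = field(default_factory=list)
    time_days: float = 0.0

    @property
    def points(self) -> np.ndarray:
        if not self.observations:
            return np.empty((0, 2))
        return np.array([[o.ellipse.x_e, o.ellipse.y_e] for o in self.observations])

    def __len__(self) -> int:
        return len(self.observations)


def greedy_match(points_a: np.ndarray, points_b: np.ndarray,
                 delta: float = DELTA) -> list[tuple[int, int]]:
    """Greedy one-to-one pairing, closest pairs first.

    Each point is paired at most once; pairs with Euclidean distance
    above ``delta`` are discarded.  Ties are broken by lowest a-index
    then lowest b-index, which makes the result deterministic.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        return []
    d = cdist(a, b)
    order = np.argsort(d, axis=None, kind="stable")  # row-major: a-index then b-index on ties
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), len(b))
        if d[i, j] > delta:
            break
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((i, j))
    return pairs


class AffineCPD:
    """Affine coherent point drift (EM point-set registration).

    Estimates the affine map ``y -> y @ B.T + t`` aligning a moving set
    onto a reference set by expectation-maximisation over a Gaussian
    mixture with a uniform outlier component (weight ``w``).
    """

    def __init__(self, w: float = 0.1, tol: float = 1e-6, max_iter: int = 200):
        self.w = w
        self.tol = tol
        self.max_iter = max_iter

    def register(self, X: np.ndarray, Y: np.ndarray):
        """Align ``Y`` (moving) onto ``X`` (reference).

        Both sets are normalized to zero mean and unit RMS radius before
        EM (without this, the near-uniform responsibilities of the first
        iterations collapse the affine map toward zero) and the
        estimated transform is mapped back to image units.
        Returns ``(TY, (B, t), converged)``.
        """
        X_raw = np.asarray(X, dtype=float)
        Y_raw = np.asarray(Y, dtype=float)
        mx, my = X_raw.mean(axis=0), Y_raw.mean(axis=0)
        sx = math.sqrt(((X_raw - mx) ** 2).sum(axis=1).mean()) or 1.0
        sy = math.sqrt(((Y_raw - my) ** 2).sum(axis=1).mean()) or 1.0
        X = (X_raw - mx) / sx
        Y = (Y_raw - my) / sy
        N, D = X.shape
        M = Y.shape[0]
        B = np.eye(D)
        t = np.zeros(D)
        TY = Y.copy()
        diff2 = cdist(X, Y, "sqeuclidean")
        sigma2 = diff2.sum() / (D * M * N)
        if sigma2 <= 0:  # the sets coincide exactly
            return Y_raw.copy(), (np.eye(D), np.zeros(D)), True
        prev_sigma2 = sigma2
        converged = False
        for _ in range(self.max_iter):
            # E-step: responsibilities with uniform outlier component
            d2 = cdist(TY, X, "sqeuclidean")  # M x N
            P = np.exp(-d2 / (2.0 * sigma2))
            c = ((2.0 * math.pi * sigma2) ** (D / 2.0)
                 * self.w / (1.0 - self.w) * M / N)
            denom = P.sum(axis=0) + c
            denom[denom == 0] = np.finfo(float).tiny
            P /= denom
            # M-step: weighted affine least squares
            Np = P.sum()
            if Np <= 0:
                break
            P1 = P.sum(axis=1)       # M
            Pt1 = P.sum(axis=0)      # N
            mu_x = (Pt1 @ X) / Np
            mu_y = (P1 @ Y) / Np
            Xh = X - mu_x
            Yh = Y - mu_y
            A = Xh.T @ P.T @ Yh      # D x D
            G = Yh.T @ (P1[:, None] * Yh)
            try:
                B = A @ np.linalg.inv(G)
            except np.linalg.LinAlgError:
                break
            t = mu_x - B @ mu_y
            TY = Y @ B.T + t
            trXPX = float((Pt1 @ (Xh * Xh).sum(axis=1)))
            sigma2 = (trXPX - float(np.trace(A @ B.T))) / (Np * D)
            if sigma2 <= np.finfo(float).eps:
                sigma2 = self.tol / 10.0
            if abs(prev_sigma2 - sigma2) < self.tol:
                converged = True
                break
            prev_sigma2 = sigma2
        # map the normalized-space transform back to image units
        B_img = (sx / sy) * B
        t_img = mx + sx * t - B_img @ my
        TY_img = Y_raw @ B_img.T + t_img
        return TY_img, (B_img, t_img), converged


def _collinear(pts: np.ndarray) -> bool:
    if len(pts) < 3:
        return True
    centred = pts - pts.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return s[-1] < 1e-9 * max(s[0], 1.0)


def register_affine(ref_points: np.ndarray, mov_points: np.ndarray,
                    cpd: AffineCPD | None = None):
    """Affine-CPD alignment of ``mov_points`` onto ``ref_points``.

    Sets with fewer than 3 non-collinear points are returned unchanged
    with the identity transform (an affine fit is meaningless there).
    Returns ``(registered_points, (B, t), converged)``.
    """
    ref = np.asarray(ref_points, dtype=float).reshape(-1, 2)
    mov = np.asarray(mov_points, dtype=float).reshape(-1, 2)
    if _collinear(ref) or _collinear(mov):
        return mov.copy(), (np.eye(2), np.zeros(2)), True
    return (cpd or AffineCPD()).register(ref, mov)


def set_distance_d(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Median over points of ``a`` of the nearest distance to ``b``."""
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("set distance undefined for empty point sets")
    return float(np.median(cdist(a, b).min(axis=1)))


def symmetric_distance_D(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Average of the two directed set distances (symmetric)."""
    return 0.5 * (set_distance_d(points_a, points_b)
                  + set_distance_d(points_b, points_a))


def build_distance_matrix(series: list[FrameSet], use_registration: bool = True,
                          cpd: AffineCPD | None = None) -> np.ndarray:
    """Pairwise frame dissimilarities m_ij = D(S_i, S~_j).

    For each ordered pair (i, j), S_j is registered onto S_i (when
    registration is enabled and both sets support an affine fit) before
    evaluating the symmetric set distance.  Empty frames get +inf
    against everything; the diagonal is zero.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 frames")
    cpd = cpd or AffineCPD()
    N = len(series)
    pts = [fs.points for fs in series]
    M = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            if len(pts[i]) == 0 or len(pts[j]) == 0:
                M[i, j] = np.inf
                continue
            moved = pts[j]
            if use_registration:
                moved, _, _ = register_affine(pts[i], pts[j], cpd)
            M[i, j] = symmetric_distance_D(pts[i], moved)
    return M


@dataclass
class MatchingTree:
    """Layered tree over time steps governing label propagation order."""

    root: int
    parent: dict[int, int]
    depth: dict[int, int]
    long_distance: set[tuple[int, int]]  # (parent, child) edges above theta

    @property
    def n_frames(self) -> int:
        return len(self.depth)

    def edges_breadth_first(self) -> list[tuple[int, int]]:
        """(parent, child) edges ordered by child depth, then child index."""
        return sorted(((p, c) for c, p in self.parent.items()),
                      key=lambda e: (self.depth[e[1]], e[1]))

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "parent": {str(c): p for c, p in sorted(self.parent.items())},
            "depth": {str(f): d for f, d in sorted(self.depth.items())},
            "long_distance": sorted(list(e) for e in self.long_distance),
        }


def _symmetric_min(M: np.ndarray) -> np.ndarray:
    return np.minimum(M, M.T)


def build_matching_tree(M: np.ndarray, root: int | None = None,
                        theta: float = THETA) -> MatchingTree:
    """Grow the matching tree from the distance matrix.

    Starting from the root, the unplaced frame with the smallest
    d_min = min(m_ij, m_ji) to any placed frame is attached, as long as
    d_min < theta.  When no candidate qualifies, a single *long-distance*
    edge attaches the globally closest unplaced frame (ties broken in
    favour of the deepest placed parent) and growth resumes in the next
    layer.  A child's depth is its parent's depth plus one.
    """
    N = M.shape[0]
    if root is None:
        root = 0
    W = _symmetric_min(M)
    placed = np.zeros(N, dtype=bool)
    placed[root] = True
    depth = {root: 0}
    parent: dict[int, int] = {}
    long_distance: set[tuple[int, int]] = set()
    while not placed.all():
        sub = W[np.ix_(~placed, placed)]
        un_idx = np.flatnonzero(~placed)
        pl_idx = np.flatnonzero(placed)
        best = np.unravel_index(np.argmin(sub), sub.shape)
        best_w = sub[best]
        if best_w < theta:
            child, par = int(un_idx[best[0]]), int(pl_idx[best[1]])
        else:
            # long-distance edge: among minimal pairs prefer the deepest parent
            cand = np.argwhere(sub == best_w)
            child, par = max(
                ((int(un_idx[ci]), int(pl_idx[pj])) for ci, pj in cand),
                key=lambda e: (depth[e[1]], -e[0], -e[1]),
            )
            long_distance.add((par, child))
        parent[child] = par
        depth[child] = depth[par] + 1
        placed[child] = True
    return MatchingTree(root=root, parent=parent, depth=depth,
                        long_distance=long_distance)


def _theta_component_sizes(M: np.ndarray, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of the graph with edges where d_min < theta."""
    W = _symmetric_min(M)
    adj = csr_matrix((W < theta).astype(int))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return labels, sizes


def select_root(M: np.ndarray, sizes: list[int], theta: float = THETA) -> int:
    """Root frame choice: most nodes placed before the first
    long-distance edge, then most points, then earliest frame.

    The number of nodes placed before the first long-distance edge when
    growing from a root equals the size of the root's theta-connected
    component, so candidates are ranked by component size.
    """
    labels, comp_sizes = _theta_component_sizes(M, theta)
    n_points = np.asarray(sizes)
    order = sorted(
        range(M.shape[0]),
        key=lambda i: (-comp_sizes[labels[i]], -n_points[i], i),
    )
    return int(order[0])


class TrackTable:
    """Label x frame grid of berry observations."""

    def __init__(self, series: list[FrameSet]):
        self.series = series
        #: per frame, one label per observation (-1 = unlabeled)
        self.labels: dict[int, np.ndarray] = {
            fs.t: np.full(len(fs), -1, dtype=int) for fs in series
        }

    def assign(self, frame: int, obs_index: int, label: int) -> None:
        self.labels[frame][obs_index] = label
        self.series_by_t[frame].observations[obs_index].label = label

    @property
    def series_by_t(self) -> dict[int, FrameSet]:
        return {fs.t: fs for fs in self.series}

    @property
    def n_labels(self) -> int:
        all_labels = np.concatenate(list(self.labels.values())) if self.labels else np.empty(0)
        valid = all_labels[all_labels >= 0]
        return int(valid.max()) + 1 if valid.size else 0

    def coverage(self) -> float:
        """Fraction of observations carrying a label."""
        total = sum(len(v) for v in self.labels.values())
        if total == 0:
            return 0.0
        labelled = sum(int((v >= 0).sum()) for v in self.labels.values())
        return labelled / total

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for fs in self.series:
            lab = self.labels[fs.t]
            for k, o in enumerate(fs.observations):
                e = o.ellipse
                rows.append({
                    "label": int(lab[k]), "frame": fs.t, "time_days": o.time,
                    "x_e": e.x_e, "y_e": e.y_e, "w_e": e.w_e, "h_e": e.h_e,
                    "a_e": e.a_e, "h_raw": o.h_raw, "H": o.H, "A_px2": o.A,
                    "V_px3": o.V, "V_mL": o.V_mL,
                })
        return pd.DataFrame(rows)


def propagate_labels(series: list[FrameSet], tree: MatchingTree,
                     delta: float = DELTA, use_registration: bool = True,
                     cpd: AffineCPD | None = None) -> TrackTable:
    """Propagate root-frame labels along the matching tree.

    Labels are initialized one per observation at the root (integers in
    reading order).  Edges are processed breadth first; along each edge
    the child's centre set is registered onto its parent's, matched
    greedily under ``delta``, and matched child observations inherit the
    parent observation's label.  Unmatched observations stay unlabeled.
    """
    cpd = cpd or AffineCPD()
    by_t = {fs.t: fs for fs in series}
    table = TrackTable(series)
    root_fs = by_t[tree.root]
    for k in range(len(root_fs)):
        table.assign(tree.root, k, k)
    for par, child in tree.edges_breadth_first():
        p_pts, c_pts = by_t[par].points, by_t[child].points
        if len(p_pts) == 0 or len(c_pts) == 0:
            continue
        moved = c_pts
        if use_registration:
            moved, _, _ = register_affine(p_pts, c_pts, cpd)
        for i, j in greedy_match(p_pts, moved, delta=delta):
            lab = table.labels[par][i]
            if lab >= 0:
                table.assign(child, j, int(lab))
    return table


def chain_tree(n_frames: int) -> MatchingTree:
    """Chronological chain 0 -> 1 -> ... used by the baseline tracker."""
    return MatchingTree(
        root=0,
        parent={t: t - 1 for t in range(1, n_frames)},
        depth={t: t for t in range(n_frames)},
        long_distance=set(),
    )


def track(series: list[FrameSet], use_registration: bool = True,
          use_tree: bool = True, delta: float = DELTA, theta: float = THETA,
          cpd: AffineCPD | None = None):
    """End-to-end tracking of a frame series.

    ``use_registration`` / ``use_tree`` switch the two optional
    components on or off (off/off is the chronological baseline).
    Returns ``(TrackTable, MatchingTree, distance_matrix_or_None)``.
    """
    if len(series) < 2:
        raise ValueError("tracking needs at least 2 frames")
    cpd = cpd or AffineCPD()
    matrix = None
    if use_tree:
        matrix = build_distance_matrix(series, use_registration=use_registration,
                                       cpd=cpd)
        root = select_root(matrix, [len(fs) for fs in series], theta=theta)
        tree = build_matching_tree(matrix, root=root, theta=theta)
    else:
        tree = chain_tree(len(series))
    table = propagate_labels(series, tree, delta=delta,
                             use_registration=use_registration, cpd=cpd)
    return table, tree, matrix
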