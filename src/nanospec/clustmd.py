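"""Conformational clustering of a flexible solute.

Torsion angles are periodic, so trajectories are analyzed with dihedral PCA
(DPCA): each angle θ is lifted to (sin θ, cos θ), doubling the feature space
(e.g. 6 dihedrals → 12 features), and PCA is performed on the lifted
covariance.  Frames are clustered in the reduced space by partition around
medoids (PAM) under the Chebyshev (L∞) distance, which maximizes the
dissimilarity between structures that differ strongly along any single
transformed coordinate.  The number of clusters is chosen by consensus of
three internal criteria: the within-cluster sum of squares (WSS) elbow, the
maximum Silhouette score and the maximum Dunn index.  Cartesian-space
diagnostics use Kabsch superposition RMSD over non-hydrogen atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

__all__ = [
    "DihedralSeries",
    "DPCAModel",
    "ClusterModel",
    "compute_dihedral",
    "fold_symmetric",
    "dpca_fit_transform",
    "pam_cluster",
    "select_k",
    "cluster_weights",
    "kabsch_rmsd",
    "UndefinedDihedralError",
]


class UndefinedDihedralError(ValueError):
    """Three consecutive dihedral atoms are collinear."""


@dataclass
class DihedralSeries:
    """Per-frame torsion angles in degrees, each within (−180, 180]."""

    angles: np.ndarray           # (n_frames, n_dihedrals)
    names: list[str] | None = None

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be (n_frames, n_dihedrals)")
        if np.any(self.angles <= -180.0) or np.any(self.angles > 180.0):
            # normalize into (−180, 180]
            a = np.mod(self.angles + 180.0, 360.0) - 180.0
            a[a == -180.0] = 180.0
            self.angles = a
        if self.names is None:
            self.names = [f"chi{i+1}" for i in range(self.angles.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.angles.shape[1]


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Zero for the cis (eclipsed) arrangement, positive for a clockwise
    rotation of the far bond viewed from p2 towards p3; result in
    (−180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise UndefinedDihedralError("three consecutive atoms are collinear")
    b2n = b2 / np.linalg.norm(b2)
    x = n1 @ n2
    y = np.cross(n1, n2) @ b2n
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def fold_symmetric(angles: np.ndarray, divisor: int) -> np.ndarray:
    """Collapse a dihedral with an n-fold symmetric rotor onto one period.

    ``divisor`` = 2 maps chemically equivalent orientations of, e.g., a
    phenyl ring or planar amino group onto (−90, 90]; divisor 1 is a no-op.
    """
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    if divisor == 1:
        return np.asarray(angles, dtype=float)
    period = 360.0 / divisor
    a = np.mod(np.asarray(angles, dtype=float) + period / 2.0, period) - period / 2.0
    a[a == -period / 2.0] = period / 2.0
    return a


@dataclass
class DPCAModel:
    mean: np.ndarray             # (2d,) mean of the lifted features
    components: np.ndarray       # (2d, 2d) eigenvectors as columns, sorted
    eigenvalues: np.ndarray      # descending
    explained_variance_ratio: np.ndarray
    n_retained: int
    variance_threshold: float

    def transform(self, series: DihedralSeries) -> np.ndarray:
        lifted = _sincos_lift(series.angles)
        centered = lifted - self.mean
        return centered @ self.components[:, : self.n_retained]


def _sincos_lift(angles_deg: np.ndarray) -> np.ndarray:
    rad = np.radians(angles_deg)
    return np.concatenate([np.sin(rad), np.cos(rad)], axis=1)


def dpca_fit_transform(
    series: DihedralSeries, variance_threshold: float = 0.90
) -> tuple[DPCAModel, np.ndarray]:
    """Fit dihedral PCA and return the model plus transformed coordinates.

    Retains the smallest number of leading components whose cumulative
    explained-variance fraction reaches ``variance_threshold`` (default 90%).
    A constant trajectory has zero covariance: zero components are retained
    and a warning is issued.
    """
    if series.n_frames < 2:
        raise ValueError("need at least two frames")
    lifted = _sincos_lift(series.angles)
    mean = lifted.mean(axis=0)
    centered = lifted - mean
    cov = centered.T @ centered / (series.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    # sin/cos features are bounded by 1: total variance below 1e-14 is noise
    if total <= 1e-14:
        warnings.warn("constant dihedral series: zero covariance", stacklevel=2)
        ratio = np.zeros_like(evals)
        n_retained = 0
    else:
        ratio = evals / total
        cum = np.cumsum(ratio)
        n_retained = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    model = DPCAModel(mean, evecs, evals, ratio, n_retained, variance_threshold)
    return model, centered @ evecs[:, :n_retained]


# ---------------------------------------------------------------------------
# PAM with Chebyshev distance
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray
    medoids: np.ndarray          # frame indices into the dataset
    wss: float                   # Σ within-cluster squared medoid distances
    silhouette: float | None = None
    dunn: float | None = None

    def weights_percent(self) -> np.ndarray:
        return cluster_weights(self.labels)


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    """Deterministic greedy BUILD phase: no RNG, reproducible by contract."""
    n = len(D)
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dn = D[:, medoids[0]].copy()
    for _ in range(1, k):
        # gain of adding each candidate: Σ_j max(dn_j − d(j,c), 0)
        gain = np.maximum(dn[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        dn = np.minimum(dn, D[:, c])
    return medoids


def pam_cluster(
    coords: np.ndarray, k: int, max_swap_iter: int = 200
) -> ClusterModel:
    """Partition around medoids under the Chebyshev (L∞) distance.

    Greedy BUILD initialization followed by best-improvement SWAP passes
    until no swap lowers the total within-cluster distance.  The reported
    WSS is the sum of squared distances of members to their medoid.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = len(coords)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    D = cdist(coords, coords, metric="chebyshev")
    medoids = _pam_build(D, k)

    for _ in range(max_swap_iter):
        med = np.asarray(medoids)
        Dm = D[:, med]                         # (n, k)
        nearest_idx = np.argmin(Dm, axis=1)
        dn = Dm[np.arange(n), nearest_idx]     # distance to nearest medoid
        if k > 1:
            part = np.partition(Dm, 1, axis=1)
            ds = part[:, 1]                    # second nearest
        else:
            ds = np.full(n, np.inf)
        # ΔT(m, h) for every (removed medoid m, candidate h)
        X = np.minimum(D, ds[:, None]) - dn[:, None]   # if j's medoid removed
        Y = np.minimum(D - dn[:, None], 0.0)           # otherwise
        onehot = np.zeros((k, n))
        onehot[nearest_idx, np.arange(n)] = 1.0
        delta = onehot @ X + (Y.sum(axis=0) - onehot @ Y)  # (k, n)
        delta[:, med] = np.inf
        m_best, h_best = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[m_best, h_best] >= -1e-12:
            break
        medoids[m_best] = int(h_best)
    else:
        warnings.warn("PAM swap phase hit the iteration cap", stacklevel=2)

    med = np.asarray(sorted(medoids))
    labels = np.argmin(D[:, med], axis=1)
    dmin = D[np.arange(n), med[labels]]
    wss = float(np.sum(dmin**2))
    return ClusterModel(k=k, labels=labels, medoids=med, wss=wss)


def dunn_index(D: np.ndarray, labels: np.ndarray) -> float:
    """min inter-cluster point distance / max intra-cluster diameter."""
    ks = np.unique(labels)
    if len(ks) < 2:
        return 0.0
    max_diam = 0.0
    for c in ks:
        idx = np.where(labels == c)[0]
        if len(idx) > 1:
            max_diam = max(max_diam, float(D[np.ix_(idx, idx)].max()))
    min_inter = np.inf
    for i, a in enumerate(ks):
        ia = np.where(labels == a)[0]
        for b in ks[i + 1:]:
            ib = np.where(labels == b)[0]
            min_inter = min(min_inter, float(D[np.ix_(ia, ib)].min()))
    if max_diam == 0.0:
        return np.inf
    return min_inter / max_diam


def _wss_elbow(ks: np.ndarray, wss: np.ndarray) -> int:
    """Elbow as the k with the largest discrete second difference of WSS."""
    if len(ks) < 3:
        return int(ks[np.argmin(wss)])
    second = wss[:-2] - 2.0 * wss[1:-1] + wss[2:]
    return int(ks[1:-1][np.argmax(second)])


def select_k(
    coords: np.ndarray, k_range=range(2, 21)
) -> tuple["pd.DataFrame", int]:
    """Run PAM over ``k_range`` and pick k by three-criterion consensus.

    Consensus is the mode of {argmax Silhouette, argmax Dunn, WSS elbow};
    ties (including three distinct votes) resolve toward the smaller k.
    Returns the per-k validation curves and the consensus k.
    """
    import pandas as pd

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = len(coords)
    ks = np.array([k for k in k_range if k < n])
    if ks.size == 0:
        raise ValueError("k_range has no feasible values")
    D = cdist(coords, coords, metric="chebyshev")
    rows = []
    for k in ks:
        model = pam_cluster(coords, int(k))
        si = float(silhouette_score(D, model.labels, metric="precomputed"))
        di = dunn_index(D, model.labels)
        rows.append((int(k), model.wss, si, di))
    curves = pd.DataFrame(rows, columns=["k", "wss", "silhouette", "dunn"])
    votes = [
        int(curves.loc[curves["silhouette"].idxmax(), "k"]),
        int(curves.loc[curves["dunn"].idxmax(), "k"]),
        _wss_elbow(curves["k"].to_numpy(), curves["wss"].to_numpy()),
    ]
    uniq, counts = np.unique(votes, return_counts=True)
    consensus = int(uniq[counts == counts.max()].min())
    return curves, consensus


def cluster_weights(labels: np.ndarray) -> np.ndarray:
    """Percent population of each cluster, in sorted-label order."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels are empty")
    _, counts = np.unique(labels, return_counts=True)
    return counts / labels.size * 100.0


def kabsch_rmsd(
    A: np.ndarray, B: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Minimum RMSD (Å) between conformers after optimal superposition.

    Standard SVD (Kabsch) construction with reflection correction; ``mask``
    selects the atoms entering the fit (e.g. non-hydrogens).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("coordinate sets must have the same shape")
    if mask is not None:
        A = A[np.asarray(mask)]
        B = B[np.asarray(mask)]
    ac = A - A.mean(axis=0)
    bc = B - B.mean(axis=0)
    H = bc.T @ ac
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, 1.0, d])
    R = U @ S @ Vt
    diff = ac - bc @ R
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
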