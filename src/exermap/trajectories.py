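"""Fuzzy c-means clustering of differential-response trajectories.

Per-timepoint z-score matrices from several omes are stacked into one
feature-by-timepoint matrix and scaled by a standard deviation computed
with two temporary zero columns standing in for the pre-exercise
baseline (so the scaling reflects departure from no change). Clustering
uses the standard fuzzy c-means objective sum_f sum_k u_fk^m d_fk^2 with
the fuzzifier m set by an empirical estimator of cluster softness; the
number of clusters is chosen from a scree of minimum centroid distances;
hard labels are assigned only where the winning membership reaches 0.3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = ["stack_and_scale", "estimate_fuzzifier", "FuzzyCMeans",
           "fuzzy_cmeans", "choose_c", "hard_assign"]

#: number of zero baseline columns temporarily included in the row SD
N_BASELINE_ZEROS = 2


def stack_and_scale(z_matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Row-stack per-ome z-score matrices and scale rows by a zero-padded SD.

    Each row is divided by the sample standard deviation of
    (0, 0, z_1, ..., z_T): the zero columns represent the pre-exercise
    timepoints and are discarded before clustering. All-zero rows are
    dropped.
    """
    if not z_matrices:
        raise ValueError("no z-score matrices given")
    cols = list(z_matrices[0].columns)
    for zm in z_matrices[1:]:
        if list(zm.columns) != cols:
            raise ValueError("z-score matrices must share identical "
                             "contrast-timepoint columns")
    stacked = pd.concat(z_matrices, axis=0)
    vals = stacked.to_numpy(dtype=float)
    nonzero = ~np.all(vals == 0.0, axis=1)
    vals = vals[nonzero]
    padded = np.concatenate(
        [np.zeros((vals.shape[0], N_BASELINE_ZEROS)), vals], axis=1)
    sd = padded.std(axis=1, ddof=1)
    return pd.DataFrame(vals / sd[:, None], index=stacked.index[nonzero],
                        columns=cols)


def estimate_fuzzifier(n_features: int, n_dims: int) -> float:
    """Empirical fuzzifier m(N, D) for FCM on omics trajectories.

    The Schwaemmle-Jensen estimate
    m = 1 + (1418/N + 22.05) D^-2
        + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134);
    decreases with the number of features and is always > 1.
    """
    if n_features < 3:
        raise ValueError("need at least 3 features")
    N, D = float(n_features), float(n_dims)
    return 1.0 + (1418.0 / N + 22.05) * D**-2.0 \
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means with the standard alternating-update algorithm.

    Parameters
    ----------
    n_clusters : int, >= 2
    m : float or None
        Fuzzifier (> 1); None estimates it from the data shape via
        :func:`estimate_fuzzifier`.
    hard_threshold : float
        Minimum winning membership for a hard label; below it a feature
        is left unassigned (label -1).
    tol, max_iter, random_state : convergence / reproducibility controls.

    Attributes (after ``fit``): ``cluster_centers_`` (c x T, rows ordered
    lexicographically so labels are stable), ``membership_`` (n x c, rows
    sum to 1), ``labels_``, ``objective_``, ``n_iter_``.
    """

    def __init__(self, n_clusters: int = 8, m: float | None = None,
                 hard_threshold: float = 0.3, tol: float = 1e-6,
                 max_iter: int = 500, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.m = m
        self.hard_threshold = hard_threshold
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        c = self.n_clusters
        if c < 2:
            raise ValueError("n_clusters must be >= 2")
        m = self.m if self.m is not None else estimate_fuzzifier(n, d)
        if m <= 1.0:
            raise ValueError("fuzzifier m must exceed 1")
        rng = np.random.default_rng(self.random_state)
        u = rng.random((n, c))
        u /= u.sum(axis=1, keepdims=True)
        prev_obj = np.inf
        objective_trace = []
        for it in range(self.max_iter):
            um = u**m
            weights = um.sum(axis=0)
            collapsed = weights < 1e-12
            centers = (um.T @ X) / np.maximum(weights[:, None], 1e-12)
            if collapsed.any():
                # re-initialize collapsed centroids at random data points
                centers[collapsed] = X[rng.integers(0, n, collapsed.sum())]
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            obj = float((um * d2).sum())
            objective_trace.append(obj)
            d2c = np.maximum(d2, 1e-300)
            inv = d2c ** (-1.0 / (m - 1.0))
            u = inv / inv.sum(axis=1, keepdims=True)
            # exact assignment for coincident points
            zero_rows, zero_cols = np.nonzero(d2 < 1e-300)
            for r_ in np.unique(zero_rows):
                u[r_] = 0.0
                u[r_, zero_cols[zero_rows == r_][0]] = 1.0
            if abs(prev_obj - obj) < self.tol * max(abs(prev_obj), 1.0):
                break
            prev_obj = obj
        # stabilize arbitrary cluster numbering: sort centroids lexicographically
        order = np.lexsort(centers.T[::-1])
        centers = centers[order]
        u = u[:, order]
        self.cluster_centers_ = centers
        self.membership_ = u
        self.m_ = m
        self.objective_ = objective_trace[-1]
        self.objective_trace_ = np.array(objective_trace)
        self.n_iter_ = len(objective_trace)
        self.labels_ = hard_assign(u, self.hard_threshold)
        return self

    def predict(self, X):
        """Hard labels for new points from distances to the fitted centroids."""
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        d2c = np.maximum(d2, 1e-300)
        inv = d2c ** (-1.0 / (self.m_ - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        return hard_assign(u, self.hard_threshold)


def fuzzy_cmeans(X, c: int, m: float | None = None, seed=None,
                 tol: float = 1e-6, max_iter: int = 500) -> FuzzyCMeans:
    """Functional wrapper around :class:`FuzzyCMeans`. Returns the fitted model."""
    return FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter,
                       random_state=seed).fit(np.asarray(X, dtype=float))


def hard_assign(membership: np.ndarray, threshold: float = 0.3) -> np.ndarray:
    """Argmax labels where the winning membership reaches ``threshold``.

    Features whose maximum membership falls below the threshold are left
    unassigned (label -1).
    """
    u = np.asarray(membership, dtype=float)
    labels = u.argmax(axis=1)
    labels = np.where(u.max(axis=1) >= threshold, labels, -1)
    return labels


def choose_c(X, c_range=range(3, 15), m: float | None = None,
             seed=None) -> pd.DataFrame:
    """Scree table of minimum pairwise centroid distance per cluster count.

    The final cluster number is a manual choice from the scree; no
    automatic selection is performed.
    """
    X = np.asarray(X, dtype=float)
    rows = []
    for c in c_range:
        model = fuzzy_cmeans(X, c=c, m=m, seed=seed)
        centers = model.cluster_centers_
        dmin = np.inf
        for i in range(c):
            for j in range(i + 1, c):
                dmin = min(dmin, float(np.linalg.norm(centers[i] - centers[j])))
        rows.append(dict(c=c, min_centroid_distance=dmin,
                         objective=model.objective_, n_iter=model.n_iter_))
    return pd.DataFrame(rows)
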