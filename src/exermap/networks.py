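"""Signed weighted co-expression networks, modules, eigengenes and traits.

Builds a signed adjacency a_ij = ((1 + cor_ij)/2)^beta over features,
derives topological-overlap dissimilarity, cuts an average-linkage tree
into modules (label 0 = unassigned), merges modules whose eigengenes are
nearly identical, and correlates module eigengenes with clinical traits
using the robust biweight midcorrelation, optionally after residualizing
both sides on covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

__all__ = ["bicor", "bicor_matrix", "pick_soft_power", "build_modules",
           "module_trait", "CoexpressionNetwork", "ModuleAssignment",
           "eigengene"]


def _biweight_standardize(X: np.ndarray):
    """Row-wise Tukey-biweight standardization for midcorrelation.

    Rows with zero MAD fall back to ordinary (Pearson) standardization.
    Returns (standardized rows with unit sum of squares, fallback mask).
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    num = dev * w
    if fallback.any():
        mean = X[fallback].mean(axis=1, keepdims=True)
        num[fallback] = X[fallback] - mean
    norm = np.sqrt((num**2).sum(axis=1, keepdims=True))
    if np.any(norm == 0.0):
        raise ValueError("constant vector: biweight midcorrelation undefined")
    return num / norm, fallback


def bicor(x, y, return_flag: bool = False):
    """Biweight midcorrelation of two vectors with a t-approximation p-value.

    Deviations from the median are weighted by (1-u^2)^2 with
    u = (x - median)/(9*MAD), zeroed beyond |u| >= 1; vectors with MAD = 0
    fall back to Pearson standardization (flagged when
    ``return_flag=True``). p uses the t distribution with df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("vectors must share length >= 4")
    S, flags = _biweight_standardize(np.vstack([x, y]))
    r = float(np.clip(S[0] @ S[1], -1.0, 1.0))
    n = x.size
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    if return_flag:
        return r, p, bool(flags.any())
    return r, p


def bicor_matrix(X: np.ndarray, Y: np.ndarray | None = None):
    """All-pairs biweight midcorrelation between rows of X and rows of Y.

    Returns (r, p) arrays of shape (n_x, n_y); p from the t approximation
    with df = n_samples - 2.
    """
    Sx, _ = _biweight_standardize(np.asarray(X, dtype=float))
    Sy = Sx if Y is None else _biweight_standardize(np.asarray(Y, dtype=float))[0]
    r = np.clip(Sx @ Sy.T, -1.0, 1.0)
    n = np.asarray(X).shape[1]
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return r, p


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) on log10 k over equal-width connectivity bins.

    Zero when the slope is positive (no power-law decay).
    """
    k = k[k > 0]
    if k.size < 10 or k.max() == k.min():
        return 0.0
    cuts = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(cuts, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2) if slope < 0 else 0.0


def _signed_adjacency(values: np.ndarray, beta: float) -> np.ndarray:
    corr = np.corrcoef(values)
    return ((1.0 + corr) / 2.0) ** beta


def pick_soft_power(matrix: pd.DataFrame, powers=tuple(range(1, 21)),
                    fit_target: float = 0.8):
    """Smallest soft-threshold power achieving scale-free fit R^2 >= target.

    Returns (beta, table, reached) where table lists the fit R^2 and mean
    connectivity per candidate power; when no power reaches the target the
    best-fitting power is returned with ``reached=False`` and a warning.
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[0] < 30:
        raise ValueError("need at least 30 features to assess scale-free fit")
    rows = []
    corr = np.corrcoef(values)
    base = (1.0 + corr) / 2.0
    for beta in powers:
        a = base**beta
        k = a.sum(axis=1) - 1.0
        rows.append(dict(power=beta, fit_r2=_scale_free_fit(k),
                         mean_connectivity=float(k.mean())))
    table = pd.DataFrame(rows)
    ok = table[table["fit_r2"] >= fit_target]
    if len(ok):
        return int(ok["power"].iloc[0]), table, True
    best = int(table.loc[table["fit_r2"].idxmax(), "power"])
    warnings.warn(f"no power on the grid reaches scale-free fit R^2 >= "
                  f"{fit_target}; returning best fit (power={best})")
    return best, table, False


def eigengene(module_values: np.ndarray) -> np.ndarray:
    """First principal component of a module (features x samples), per sample.

    Standardized to unit variance; sign fixed so the average
    feature-eigengene correlation is positive.
    """
    V = np.asarray(module_values, dtype=float)
    Vs = (V - V.mean(axis=1, keepdims=True))
    sd = Vs.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Vs = Vs / sd
    _, _, vt = np.linalg.svd(Vs, full_matrices=False)
    e = vt[0]
    e = (e - e.mean()) / e.std()
    cors = (Vs @ e) / (np.linalg.norm(Vs, axis=1) * np.linalg.norm(e) + 1e-300)
    if cors.mean() < 0:
        e = -e
    return e


@dataclass
class ModuleAssignment:
    """Module labels (0 = unassigned), eigengenes, kME and parameters."""

    labels: pd.Series                 # feature -> int module label
    eigengenes: pd.DataFrame          # module x sample
    kme: pd.DataFrame                 # feature x module correlation
    beta: float
    merge_threshold: float

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def build_modules(matrix: pd.DataFrame, beta: float,
                  merge_threshold: float = 0.3,
                  min_module_size: int = 30,
                  cut_height_quantile: float = 0.5) -> ModuleAssignment:
    """Detect signed co-expression modules.

    Signed adjacency -> topological overlap dissimilarity ->
    average-linkage tree -> height-based cut (at the given quantile of
    merge heights) -> drop clusters below ``min_module_size`` to module 0
    -> merge modules whose eigengene correlation exceeds
    1 - merge_threshold -> relabel by decreasing size -> kME of every
    feature against every eigengene.
    """
    values = matrix.to_numpy(dtype=float)
    p = values.shape[0]
    if p < min_module_size:
        labels = pd.Series(np.zeros(p, dtype=int), index=matrix.index)
        return ModuleAssignment(labels, pd.DataFrame(columns=matrix.columns),
                                pd.DataFrame(index=matrix.index), beta,
                                merge_threshold)
    a = _signed_adjacency(values, beta)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l_mat = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l_mat + a) / denom
    np.fill_diagonal(tom, 1.0)
    dist = 1.0 - tom
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    h = np.quantile(Z[:, 2], cut_height_quantile)
    raw = fcluster(Z, t=h, criterion="distance")
    labels = np.zeros(p, dtype=int)
    next_label = 1
    for lab in np.unique(raw):
        members = np.flatnonzero(raw == lab)
        if members.size >= min_module_size:
            labels[members] = next_label
            next_label += 1

    def eigs(labs):
        return {m: eigengene(values[labs == m]) for m in np.unique(labs) if m != 0}

    # iterative eigengene merging
    while True:
        e = eigs(labels)
        mods = sorted(e)
        if len(mods) < 2:
            break
        best, best_cor = None, 1.0 - merge_threshold
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                c = float(np.corrcoef(e[mods[i]], e[mods[j]])[0, 1])
                if c > best_cor:
                    best, best_cor = (mods[i], mods[j]), c
        if best is None:
            break
        labels[labels == best[1]] = best[0]

    # relabel by decreasing size, 1-based; 0 stays unassigned
    sizes = {m: int((labels == m).sum()) for m in np.unique(labels) if m != 0}
    order = sorted(sizes, key=lambda m: -sizes[m])
    relabel = {m: i + 1 for i, m in enumerate(order)}
    labels = np.array([relabel.get(m, 0) for m in labels])

    e = eigs(labels)
    eig_df = pd.DataFrame({m: e[m] for m in sorted(e)},
                          index=matrix.columns).T
    eig_df.index.name = "module"
    if len(eig_df):
        Vs = values - values.mean(axis=1, keepdims=True)
        sd = Vs.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Vs /= sd
        E = eig_df.to_numpy(dtype=float)
        En = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
        kme_vals = (Vs @ En.T) / values.shape[1]
        norm = (np.linalg.norm(Vs, axis=1)[:, None] / np.sqrt(values.shape[1])) * \
               (np.linalg.norm(En, axis=1)[None, :] / np.sqrt(values.shape[1]))
        kme_vals = np.clip(kme_vals / np.maximum(norm, 1e-300), -1.0, 1.0)
        kme = pd.DataFrame(kme_vals, index=matrix.index,
                           columns=[f"kME{m}" for m in eig_df.index])
    else:
        kme = pd.DataFrame(index=matrix.index)
    return ModuleAssignment(pd.Series(labels, index=matrix.index),
                            eig_df, kme, beta, merge_threshold)


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), C])
    beta, _, _, _ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def module_trait(eigengenes: pd.DataFrame, traits: pd.DataFrame,
                 adjust_for: pd.DataFrame | None = None,
                 max_missing: float = 0.5) -> pd.DataFrame:
    """Biweight midcorrelation of each module eigengene with each trait.

    Traits are z-scored; with ``adjust_for`` both sides are residualized
    on the covariates first. Traits missing in more than ``max_missing``
    of samples are skipped. Returns a tidy table with correlation, p and
    significance stars (0.05/0.01/0.001).
    """
    rows = []
    samples = eigengenes.columns
    C = None
    if adjust_for is not None:
        C = adjust_for.loc[samples].to_numpy(dtype=float)
    for trait in traits.columns:
        tv = traits.loc[samples, trait].to_numpy(dtype=float)
        ok = np.isfinite(tv)
        if ok.mean() < 1.0 - max_missing:
            warnings.warn(f"trait {trait!r} missing in more than "
                          f"{max_missing:.0%} of samples; skipped")
            continue
        tz = (tv - np.nanmean(tv)) / np.nanstd(tv)
        for mod in eigengenes.index:
            ev = eigengenes.loc[mod].to_numpy(dtype=float)
            e_use, t_use = ev[ok], tz[ok]
            if C is not None:
                Cok = C[ok]
                e_use = _residualize(e_use, Cok)
                t_use = _residualize(t_use, Cok)
            r, p = bicor(e_use, t_use)
            stars = "***" if p < 0.001 else "**" if p < 0.01 else \
                    "*" if p < 0.05 else ""
            rows.append(dict(module=mod, trait=trait, bicor=r, p=p,
                             stars=stars))
    return pd.DataFrame(rows)


class CoexpressionNetwork(BaseEstimator):
    """Estimator wrapper: fit signed co-expression modules on one ome.

    Parameters follow :func:`pick_soft_power` and :func:`build_modules`;
    ``beta=None`` selects the soft power from the grid at fit time.

    Attributes (after ``fit``): ``labels_``, ``eigengenes_``, ``kme_``,
    ``beta_``, ``power_table_``.
    """

    def __init__(self, beta=None, powers=tuple(range(1, 21)),
                 fit_target: float = 0.8, merge_threshold: float = 0.3,
                 min_module_size: int = 30, cut_height_quantile: float = 0.5):
        self.beta = beta
        self.powers = powers
        self.fit_target = fit_target
        self.merge_threshold = merge_threshold
        self.min_module_size = min_module_size
        self.cut_height_quantile = cut_height_quantile

    def fit(self, X: pd.DataFrame, y=None):
        """X: feature (rows) x sample (columns) matrix, complete values."""
        if self.beta is None:
            self.beta_, self.power_table_, self.fit_reached_ = pick_soft_power(
                X, self.powers, self.fit_target)
        else:
            self.beta_, self.power_table_, self.fit_reached_ = self.beta, None, True
        assignment = build_modules(X, self.beta_, self.merge_threshold,
                                   self.min_module_size,
                                   self.cut_height_quantile)
        self.assignment_ = assignment
        self.labels_ = assignment.labels
        self.eigengenes_ = assignment.eigengenes
        self.kme_ = assignment.kme
        return self
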