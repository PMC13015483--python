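"""Feature filtering, imputation, normalization and technical-effect removal.

Implements the pipeline's quality-control rules:

* metabolomics cleaning: duplicate-ID averaging, nonpositive-to-missing
  conversion, >20% missingness filter, KNN (k=10, sample-space) or
  half-minimum imputation depending on feature count, log2(x+1);
* a conditional median-MAD sample normalization gated on Kruskal-Wallis
  association of sample medians / upper quartiles with sex and
  sex-stratified group (p < 0.01 blocks normalization);
* principal-component outlier flagging with 5x-IQR boxplot whiskers;
* cross-platform redundancy resolution by lowest reference-standard CV;
* the RNA low-expression filter (0.5 CPM / 10% of samples), TMM log-CPM
  normalization, and the proteomics 30%-quantified filter;
* technical-covariate residualization with a protected biological design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer

__all__ = [
    "QCReport", "clean_metabolites", "conditional_median_mad_normalize",
    "flag_pc_outliers", "resolve_platform_redundancy",
    "filter_low_expression", "filter_proteomics_quantified", "tmm_log_cpm",
    "regress_technical", "MetaboliteCleaner", "LowExpressionFilter",
    "QuantifiedFractionFilter", "TechnicalEffectRemover",
]


@dataclass
class QCReport:
    """Per-step bookkeeping of what was removed, flagged or decided."""

    steps: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    def add(self, step: str, n_in: int, n_removed: int, **extra):
        if n_in - n_removed < 0:
            raise ValueError("removed more than present")
        self.steps.append(dict(step=step, n_in=n_in, n_removed=n_removed,
                               n_out=n_in - n_removed, **extra))

    def to_json(self) -> str:
        return json.dumps(dict(steps=self.steps, flags=self.flags),
                          default=str, indent=2)


def clean_metabolites(matrix: pd.DataFrame, max_missing: float = 0.20,
                      knn_min_features: int = 12, knn_k: int = 10):
    """Metabolomics cleaning pipeline on a raw-scale feature x sample matrix.

    Steps, in order: average rows sharing a feature ID; convert negative
    and zero values to missing; remove features missing in more than
    ``max_missing`` of samples; impute (KNN with k=``knn_k`` over samples
    when more than ``knn_min_features`` features remain, otherwise
    per-feature half-minimum); log2(x + 1).

    Returns (cleaned matrix, QCReport).
    """
    report = QCReport()
    n0 = matrix.shape[0]
    m = matrix.groupby(level=0).mean()
    report.add("average_duplicate_ids", n0, n0 - m.shape[0])

    vals = m.to_numpy(dtype=float)
    nonpos = np.sum(vals <= 0.0)
    vals = np.where(vals <= 0.0, np.nan, vals)
    report.add("nonpositive_to_missing", m.shape[0], 0,
               n_values_converted=int(nonpos))

    miss_frac = np.mean(np.isnan(vals), axis=1)
    keep = miss_frac <= max_missing
    report.add("missingness_filter", m.shape[0], int((~keep).sum()),
               max_missing=max_missing)
    m = m.loc[keep]
    vals = vals[keep]
    if m.shape[0] == 0:
        raise ValueError("all features removed by the missingness filter")

    if np.isnan(vals).any():
        if m.shape[0] > knn_min_features:
            imputer = KNNImputer(n_neighbors=min(knn_k, m.shape[1] - 1))
            vals = imputer.fit_transform(vals.T).T  # neighbors are samples
            method = "knn"
        else:
            half_min = np.nanmin(vals, axis=1) / 2.0
            idx = np.where(np.isnan(vals))
            vals[idx] = half_min[idx[0]]
            method = "half_minimum"
    else:
        method = "none"
    report.add("imputation", m.shape[0], 0, method=method)
    report.flags["imputation_method"] = method

    out = pd.DataFrame(np.log2(vals + 1.0), index=m.index, columns=m.columns)
    report.add("log2_transform", m.shape[0], 0)
    return out, report


def conditional_median_mad_normalize(matrix: pd.DataFrame,
                                     design: pd.DataFrame,
                                     gate_p: float = 0.01):
    """Per-sample median-center / MAD-scale, gated on design association.

    Kruskal-Wallis tests associate sample medians and upper quartiles with
    sex and with sex-stratified group; if any test has p < ``gate_p`` the
    matrix is returned unchanged (normalization would absorb biology).
    Samples with MAD 0 are centered but left at unit scale.

    Returns (matrix, QCReport) with the gating p-values recorded.
    """
    report = QCReport()
    d = design.loc[list(matrix.columns)]
    vals = matrix.to_numpy(dtype=float)
    medians = np.nanmedian(vals, axis=0)
    upperq = np.nanquantile(vals, 0.75, axis=0)

    factors = {"sex": d["sex"].astype(str)}
    factors["sex_group"] = d["sex"].astype(str) + "/" + d["group"].astype(str)
    gate_ps = {}
    for stat_name, stat in (("median", medians), ("upper_quartile", upperq)):
        for fac_name, fac in factors.items():
            levels = [stat[(fac == lev).to_numpy()] for lev in fac.unique()]
            levels = [l for l in levels if len(l)]
            if len(levels) < 2:
                warnings.warn(f"gate factor {fac_name!r} has fewer than two "
                              "levels; gate skipped")
                continue
            gate_ps[f"{stat_name}~{fac_name}"] = float(
                stats.kruskal(*levels).pvalue)
    normalize = all(p >= gate_p for p in gate_ps.values())
    report.flags["gate_p_values"] = gate_ps
    report.flags["normalized"] = normalize
    if not normalize:
        report.add("median_mad_normalize", matrix.shape[0], 0, applied=False)
        return matrix.copy(), report

    mad = np.nanmedian(np.abs(vals - medians[None, :]), axis=0)
    scale = np.where(mad > 0, mad, 1.0)
    out = pd.DataFrame((vals - medians[None, :]) / scale[None, :],
                       index=matrix.index, columns=matrix.columns)
    report.add("median_mad_normalize", matrix.shape[0], 0, applied=True,
               n_zero_mad_samples=int((mad == 0).sum()))
    return out, report


def flag_pc_outliers(matrix: pd.DataFrame, iqr_mult: float = 5.0,
                     min_var_explained: float = 0.01) -> list:
    """Samples outside the boxplot whiskers on any retained principal component.

    Retained components explain at least ``min_var_explained`` of
    variance; whiskers extend ``iqr_mult`` interquartile ranges beyond
    the quartiles. Requires a complete (imputed) matrix.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("matrix must be complete (imputed) for PCA")
    n = matrix.shape[1]
    if n < 3:
        warnings.warn("fewer than 3 samples; no outlier flagging")
        return []
    X = vals.T  # samples x features
    pca = PCA(n_components=min(n - 1, matrix.shape[0]))
    scores = pca.fit_transform(X - X.mean(axis=0))
    retained = pca.explained_variance_ratio_ >= min_var_explained
    flagged = set()
    for j in np.flatnonzero(retained):
        s = scores[:, j]
        q1, q3 = np.quantile(s, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_mult * iqr, q3 + iqr_mult * iqr
        for i in np.flatnonzero((s < lo) | (s > hi)):
            flagged.add(matrix.columns[i])
    return sorted(flagged)


def resolve_platform_redundancy(features: pd.DataFrame,
                                standards_cv: pd.DataFrame) -> pd.DataFrame:
    """Keep one platform per RefMet ID: the lowest mean reference-standard CV.

    ``features`` has columns (refmet_id, platform); ``standards_cv`` has
    (platform, standard, cv). Ties and missing CV entries resolve to the
    lexicographically first platform (logged / warned).

    Returns the features table with ``keep`` and ``reason`` columns.
    """
    mean_cv = standards_cv.groupby("platform")["cv"].mean()
    out = features.copy()
    out["keep"] = True
    out["reason"] = "single_platform"
    for refmet, sub in features.groupby("refmet_id"):
        platforms = sorted(sub["platform"].unique())
        if len(platforms) < 2:
            continue
        cvs = {p: mean_cv.get(p) for p in platforms}
        if any(v is None or np.isnan(v) for v in cvs.values()):
            warnings.warn(f"missing standards CV for refmet {refmet!r}; "
                          "keeping lexicographically first platform")
            winner, reason = platforms[0], "missing_cv_fallback"
        else:
            best = min(cvs.values())
            tied = sorted(p for p, v in cvs.items() if v == best)
            winner = tied[0]
            reason = "tie_lexicographic" if len(tied) > 1 else "lowest_cv"
        mask = out["refmet_id"] == refmet
        out.loc[mask, "keep"] = out.loc[mask, "platform"] == winner
        out.loc[mask, "reason"] = reason
    return out


def _cpm(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size sample")
    return counts / lib * 1e6


def filter_low_expression(counts: pd.DataFrame, cpm_threshold: float = 0.5,
                          sample_frac: float = 0.10,
                          rule: str = "literal") -> pd.DataFrame:
    """Remove lowly expressed genes from a raw count matrix.

    ``rule="literal"`` (default) removes a gene having CPM <=
    ``cpm_threshold`` in at least ``sample_frac`` of samples.
    ``rule="conventional"`` keeps a gene only if CPM > threshold in at
    least ``sample_frac`` of samples (the common filterByExpr-style
    reading; far less aggressive).
    """
    cpm = _cpm(counts.to_numpy(dtype=float))
    low_frac = np.mean(cpm <= cpm_threshold, axis=1)
    if rule == "literal":
        keep = low_frac < sample_frac
    elif rule == "conventional":
        keep = (1.0 - low_frac) >= sample_frac
    else:
        raise ValueError("rule must be 'literal' or 'conventional'")
    return counts.loc[keep]


def filter_proteomics_quantified(matrix: pd.DataFrame,
                                 min_frac: float = 0.30) -> pd.DataFrame:
    """Remove features quantified in fewer than ``min_frac`` of samples.

    The boundary is inclusive: a feature quantified in exactly 30% of
    samples is kept.
    """
    frac = matrix.notna().mean(axis=1)
    return matrix.loc[frac >= min_frac]


def tmm_log_cpm(counts: pd.DataFrame, trim_m: float = 0.3,
                trim_a: float = 0.05) -> pd.DataFrame:
    """Trimmed-mean-of-M-values scaling factors followed by log2 CPM.

    The reference sample is the one whose upper quartile is closest to the
    mean upper quartile; per sample, log-ratios (M) and average log
    abundances (A) over doubly-positive genes are trimmed (30% / 5%) and
    the precision-weighted mean M gives the scaling factor.
    """
    vals = counts.to_numpy(dtype=float)
    lib = vals.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size sample")
    frac = vals / lib
    uq = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(vals.shape[1])
    pr = frac[:, ref]
    for j in range(vals.shape[1]):
        if j == ref:
            continue
        pj = frac[:, j]
        ok = (pj > 0) & (pr > 0)
        M = np.log2(pj[ok] / pr[ok])
        A = 0.5 * np.log2(pj[ok] * pr[ok])
        w = (1.0 - pj[ok]) / (lib[j] * pj[ok]) + (1.0 - pr[ok]) / (lib[ref] * pr[ok])
        keepM = (M >= np.quantile(M, trim_m)) & (M <= np.quantile(M, 1 - trim_m))
        keepA = (A >= np.quantile(A, trim_a)) & (A <= np.quantile(A, 1 - trim_a))
        keep = keepM & keepA
        if keep.sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    eff_lib = lib * factors
    logcpm = np.log2((vals + 0.5) / (eff_lib + 1.0)[None, :] * 1e6)
    return pd.DataFrame(logcpm, index=counts.index, columns=counts.columns)


def regress_technical(matrix: pd.DataFrame, technical: pd.DataFrame,
                      protected: pd.DataFrame) -> pd.DataFrame:
    """Remove technical-covariate effects estimated jointly with the biology.

    Technical and protected (biological) covariates enter one joint linear
    model per feature; only the technical contribution is subtracted, so
    protected effects survive residualization. Technical columns that are
    collinear with the protected design are skipped with a warning (the
    confounded-batch case).
    """
    samples = list(matrix.columns)
    P_cols, P_names = [np.ones(len(samples))], ["intercept"]
    for c in protected.columns:
        col = protected.loc[samples, c]
        if col.dtype.kind in "if":
            P_cols.append(col.to_numpy(float))
            P_names.append(c)
        else:
            for lev in sorted(col.astype(str).unique())[1:]:
                P_cols.append((col.astype(str) == lev).to_numpy(float))
                P_names.append(f"{c}:{lev}")
    P = np.column_stack(P_cols)

    T_cols, T_names = [], []
    for c in technical.columns:
        col = technical.loc[samples, c]
        cand_cols, cand_names = [], []
        if col.dtype.kind in "if":
            cand_cols.append(col.to_numpy(float))
            cand_names.append(c)
        else:
            for lev in sorted(col.astype(str).unique())[1:]:
                cand_cols.append((col.astype(str) == lev).to_numpy(float))
                cand_names.append(f"{c}:{lev}")
        base_rank = np.linalg.matrix_rank(np.column_stack([P] + T_cols)
                                          if T_cols else P)
        trial = np.column_stack([P] + T_cols + cand_cols)
        if np.linalg.matrix_rank(trial) < base_rank + len(cand_cols):
            warnings.warn(f"technical covariate {c!r} is collinear with the "
                          "protected design; skipped")
            continue
        T_cols.extend(cand_cols)
        T_names.extend(cand_names)
    if not T_cols:
        return matrix.copy()
    T = np.column_stack(T_cols)
    X = np.column_stack([P, T])
    Y = matrix.to_numpy(dtype=float).T  # samples x features
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    tech_part = T @ beta[P.shape[1]:]
    return pd.DataFrame((Y - tech_part).T, index=matrix.index,
                        columns=matrix.columns)


# --- thin sklearn-style transformer wrappers ------------------------------

class _MatrixTransformer(BaseEstimator, TransformerMixin):
    def fit(self, X, y=None):
        return self


class MetaboliteCleaner(_MatrixTransformer):
    """Transformer wrapper around :func:`clean_metabolites`."""

    def __init__(self, max_missing: float = 0.20, knn_min_features: int = 12,
                 knn_k: int = 10):
        self.max_missing = max_missing
        self.knn_min_features = knn_min_features
        self.knn_k = knn_k

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, self.report_ = clean_metabolites(
            X, self.max_missing, self.knn_min_features, self.knn_k)
        return out


class LowExpressionFilter(_MatrixTransformer):
    """Transformer wrapper around :func:`filter_low_expression`."""

    def __init__(self, cpm_threshold: float = 0.5, sample_frac: float = 0.10,
                 rule: str = "literal"):
        self.cpm_threshold = cpm_threshold
        self.sample_frac = sample_frac
        self.rule = rule

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return filter_low_expression(X, self.cpm_threshold, self.sample_frac,
                                     self.rule)


class QuantifiedFractionFilter(_MatrixTransformer):
    """Transformer wrapper around :func:`filter_proteomics_quantified`."""

    def __init__(self, min_frac: float = 0.30):
        self.min_frac = min_frac

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return filter_proteomics_quantified(X, self.min_frac)


class TechnicalEffectRemover(_MatrixTransformer):
    """Transformer wrapper around :func:`regress_technical`."""

    def __init__(self, technical: pd.DataFrame, protected: pd.DataFrame):
        self.technical = technical
        self.protected = protected

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return regress_technical(X, self.technical, self.protected)
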