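"""Per-feature repeated-measures differential analysis.

A cell-means linear mixed model (one mean per group x timepoint cell,
participant random intercept, configurable demographic covariates) is fit
per feature; exercise effects are tested with three contrast families:

* ``difference_in_changes`` ("delta-delta"): the change from pre to a post
  timepoint in an exercise group minus the same change in the
  non-exercising control group, isolating exercise from circadian,
  fasting and biopsy effects.
* ``group_specific``: the within-group pre-to-post change.
* ``modality``: endurance-minus-resistance difference of changes.

P-values are Benjamini-Hochberg adjusted within each (family, group, ome,
timepoint) stratum. Features must have at least 3 participants with
paired pre/post values in every involved group to be testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .lmm import MixedFit, fit_random_intercept
from .simulate import GROUPS, TIMEPOINTS

__all__ = [
    "FeatureFit", "build_design_matrix", "fit_feature", "contrast",
    "make_contrast_vector", "min_pairs_filter", "adjust_stratified",
    "sex_difference", "estimate_precision_weights", "build_zscore_matrix",
    "run_differential", "Z_CAP",
]

#: cap on |z| when p underflows (Phi^-1 overflows near p = 1e-310)
Z_CAP = 38.0

DEFAULT_COVARIATES = ("age", "sex", "bmi", "site")


def build_design_matrix(design: pd.DataFrame, covariates=DEFAULT_COVARIATES):
    """Cell-means fixed-effect design matrix.

    One indicator column per observed group x timepoint cell plus centered /
    dummy-coded covariate columns. Collinear covariate columns are dropped
    with a warning; cell columns are never dropped.

    Returns (X, columns) where cell columns are named ``cell:GROUP:TIMEPOINT``.
    """
    cells = design["group"].astype(str) + ":" + design["timepoint"].astype(str)
    cell_levels = [f"{g}:{t}" for g in GROUPS for t in TIMEPOINTS
                   if f"{g}:{t}" in set(cells)]
    X_cols, names = [], []
    for lev in cell_levels:
        X_cols.append((cells == lev).to_numpy(float))
        names.append(f"cell:{lev}")
    for cov in covariates:
        if cov not in design.columns:
            continue
        col = design[cov]
        if col.dtype.kind in "if":
            v = col.to_numpy(float)
            X_cols.append(v - np.nanmean(v))
            names.append(cov)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # drop-first coding
                X_cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}:{lev}")
    X = np.column_stack(X_cols)

    n_cells = len(cell_levels)
    keep = list(range(n_cells))
    rank = np.linalg.matrix_rank(X[:, :n_cells])
    for j in range(n_cells, X.shape[1]):
        r_new = np.linalg.matrix_rank(X[:, keep + [j]])
        if r_new > rank:
            keep.append(j)
            rank = r_new
        else:
            warnings.warn(
                f"covariate column {names[j]!r} is collinear with the design "
                "and was dropped", stacklevel=2,
            )
    return X[:, keep], [names[j] for j in keep]


@dataclass
class FeatureFit:
    """Mixed-model fit for one feature on its non-missing observations."""

    feature_id: str
    fit: MixedFit
    columns: list
    design: pd.DataFrame          # the rows actually used

    @property
    def cell_means(self) -> dict[str, float]:
        return {c[5:]: float(b) for c, b in zip(self.columns, self.fit.beta)
                if c.startswith("cell:")}


def fit_feature(y, design: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                weights=None, feature_id="feature") -> FeatureFit:
    """Fit the cell-means random-intercept model to one feature.

    Missing values in ``y`` are dropped (with their design rows). Requires
    at least two participants with repeated measures.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    d = design[mask]
    yv = y[mask]
    w = None if weights is None else np.asarray(weights, float)[mask]
    n_rep = (d.groupby("participant_id").size() >= 2).sum()
    if n_rep < 2:
        raise ValueError(
            f"{feature_id}: need >= 2 participants with repeated measures, "
            f"got {n_rep}"
        )
    X, cols = build_design_matrix(d, covariates)
    fit = fit_random_intercept(yv, X, d["participant_id"].to_numpy(), weights=w,
                               columns=cols)
    return FeatureFit(feature_id, fit, cols, d)


def make_contrast_vector(columns: list, family: str, group=None, timepoint=None):
    """Contrast vector over the design columns for one named comparison.

    Returns None if any required cell is absent (untestable).
    """
    idx = {c: i for i, c in enumerate(columns)}
    c = np.zeros(len(columns))

    def cell(g, t):
        return idx.get(f"cell:{g}:{t}")

    if family == "difference_in_changes":
        need = [(group, timepoint, 1), (group, "pre", -1),
                ("CON", timepoint, -1), ("CON", "pre", 1)]
    elif family == "group_specific":
        need = [(group, timepoint, 1), (group, "pre", -1)]
    elif family == "modality":
        need = [("EE", timepoint, 1), ("EE", "pre", -1),
                ("RE", timepoint, -1), ("RE", "pre", 1)]
    else:
        raise ValueError(f"unknown contrast family {family!r}")
    for g, t, sign in need:
        j = cell(g, t)
        if j is None:
            return None
        c[j] += sign
    return c


def contrast(ff: FeatureFit, family: str, group=None, timepoint=None) -> dict:
    """Test one contrast on a fitted feature; returns a tidy result row."""
    cvec = make_contrast_vector(ff.columns, family, group, timepoint)
    name_group = group if family != "modality" else "EE-RE"
    row = dict(feature_id=ff.feature_id, family=family, group=name_group,
               timepoint=timepoint,
               contrast=f"{family}:{name_group}:{timepoint}")
    if cvec is None:
        row.update(estimate=np.nan, se=np.nan, tstat=np.nan, df=np.nan,
                   p=np.nan, testable=False)
        return row
    est, se, t, df, p = ff.fit.contrast(cvec)
    row.update(estimate=est, se=se, tstat=t, df=df, p=p, testable=True)
    return row


def min_pairs_filter(design: pd.DataFrame, missing: pd.DataFrame,
                     min_pairs: int = 3) -> pd.DataFrame:
    """Feature x contrast testability mask from the minimum-pairs rule.

    A feature is testable for a contrast iff every group involved has at
    least ``min_pairs`` participants with non-missing pre AND post values.

    Parameters
    ----------
    missing : DataFrame (features x samples) of booleans, True = missing.
    """
    d = design.set_index("sample_id") if design.index.name != "sample_id" else design
    contrasts = list_contrasts(design)
    pre_ids = d.index[d["timepoint"] == "pre"]
    # per participant: its pre sample and its post sample
    pre_of = d.loc[pre_ids].set_index("participant_id")["sample_id"]
    post = d[d["timepoint"] != "pre"]
    obs = ~missing

    cols = {}
    for name, family, group, tp in contrasts:
        if family == "difference_in_changes":
            involved = [group, "CON"]
        elif family == "group_specific":
            involved = [group]
        else:
            involved = ["EE", "RE"]
        ok = np.ones(len(missing), dtype=bool)
        for g in involved:
            pp = post[(post["group"] == g) & (post["timepoint"] == tp)]
            pairs_ok = np.zeros(len(missing), dtype=int)
            for _, r in pp.iterrows():
                pre_s = pre_of.get(r["participant_id"])
                if pre_s is None or pre_s not in obs.columns:
                    continue
                pairs_ok += (obs[pre_s] & obs[r["sample_id"]]).to_numpy(int)
            ok &= pairs_ok >= min_pairs
        cols[name] = ok
    return pd.DataFrame(cols, index=missing.index)


def list_contrasts(design: pd.DataFrame,
                   families=("difference_in_changes", "group_specific",
                             "modality")):
    """Enumerate the (name, family, group, timepoint) tuples the design supports."""
    post_tps = [t for t in TIMEPOINTS if t != "pre"
                and (design["timepoint"] == t).any()]
    out = []
    for family in families:
        for tp in post_tps:
            if family == "difference_in_changes":
                for g in ("EE", "RE"):
                    out.append((f"{family}:{g}:{tp}", family, g, tp))
            elif family == "group_specific":
                for g in GROUPS:
                    out.append((f"{family}:{g}:{tp}", family, g, tp))
            else:
                out.append((f"{family}:EE-RE:{tp}", family, None, tp))
    return out


def adjust_stratified(results: pd.DataFrame, alpha: float = 0.05,
                      ome: str | None = None) -> pd.DataFrame:
    """BH adjustment within each (family, group, ome, timepoint) stratum."""
    res = results.copy()
    if "ome" not in res.columns:
        res["ome"] = ome if ome is not None else "na"
    res["adj_p"] = np.nan
    for _, idx in res.groupby(["family", "group", "ome", "timepoint"],
                              dropna=False).groups.items():
        sub = res.loc[idx]
        ok = sub["p"].notna()
        if ok.any():
            adj = multipletests(sub.loc[ok, "p"], method="fdr_bh")[1]
            res.loc[sub.index[ok], "adj_p"] = adj
    res["significant"] = res["adj_p"] < alpha
    return res


def _trigamma_inverse(y: float, iters: int = 30) -> float:
    """Solve polygamma(1, x) = y for x > 0 by Newton iteration."""
    from scipy.special import polygamma
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(iters):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = max(x + dif, 1e-8)
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _squeeze_variances(s2: np.ndarray, df: np.ndarray):
    """Empirical-Bayes shrinkage of residual variances across features.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    variances by moment matching on the log scale and returns the
    posterior variances and the prior df. d0 = inf collapses every
    variance to the common value.
    """
    from scipy.special import digamma, polygamma
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    df = np.asarray(df, dtype=float)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - np.mean(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s0 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0 = float(np.exp(np.mean(e)))
        post = np.full_like(s2, s0)
    return post, d0


def run_differential(matrix: pd.DataFrame, design: pd.DataFrame,
                     families=("difference_in_changes", "group_specific",
                               "modality"),
                     covariates=DEFAULT_COVARIATES, weights=None,
                     ome: str | None = None, min_pairs: int = 3,
                     alpha: float = 0.05,
                     moderate_var: bool = False) -> pd.DataFrame:
    """Fit and test every feature x contrast; returns the tidy result table.

    With ``moderate_var`` the per-feature residual variances are shrunk
    toward a common prior (empirical Bayes) before contrast testing:
    standard errors are rescaled by sqrt(posterior/observed variance) and
    the prior df is added to the test df. Off by default.
    """
    d = design.loc[list(matrix.columns)]
    contrasts = list_contrasts(d, families)
    testable = min_pairs_filter(d, matrix.isna(), min_pairs=min_pairs)
    rows = []
    sigma2, resid_df = {}, {}
    for fid, y in matrix.iterrows():
        yv = y.to_numpy(float)
        if not np.isfinite(yv).sum():
            continue
        w = None if weights is None else weights.loc[fid].to_numpy(float)
        try:
            ff = fit_feature(yv, d, covariates=covariates, weights=w,
                             feature_id=fid)
        except ValueError:
            continue
        sigma2[fid] = ff.fit.sigma2
        resid_df[fid] = ff.fit.n_obs - len(ff.columns)
        for name, family, group, tp in contrasts:
            if name in testable.columns and not testable.loc[fid, name]:
                continue
            rows.append(contrast(ff, family, group, tp))
    res = pd.DataFrame(rows)
    if moderate_var and len(sigma2) >= 10 and len(res):
        fids = list(sigma2)
        post, d0 = _squeeze_variances([sigma2[f] for f in fids],
                                      [resid_df[f] for f in fids])
        scale = pd.Series(np.sqrt(post / np.array([sigma2[f] for f in fids])),
                          index=fids)
        sc = res["feature_id"].map(scale).to_numpy()
        ok = res["p"].notna() & np.isfinite(sc)
        res.loc[ok, "se"] = res.loc[ok, "se"] * sc[ok]
        res.loc[ok, "tstat"] = res.loc[ok, "estimate"] / res.loc[ok, "se"]
        res.loc[ok, "df"] = res.loc[ok, "df"] + d0  # inf -> normal reference
        res.loc[ok, "p"] = 2.0 * stats.t.sf(np.abs(res.loc[ok, "tstat"]),
                                            res.loc[ok, "df"])
    if len(res):
        res = adjust_stratified(res, alpha=alpha, ome=ome)
    return res


def sex_difference(matrix_pre: pd.DataFrame, sex: pd.Series,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Baseline male-vs-female linear model per feature, BH across features.

    Positive estimates mean higher in males (male minus female).
    """
    sex = sex.loc[matrix_pre.columns]
    is_m = (sex == "M").to_numpy()
    if is_m.all() or (~is_m).all():
        raise ValueError("both sexes must be present")
    rows = []
    for fid, y in matrix_pre.iterrows():
        yv = y.to_numpy(float)
        ok = np.isfinite(yv)
        m, f = yv[ok & is_m], yv[ok & ~is_m]
        if len(m) < 2 or len(f) < 2:
            rows.append(dict(feature_id=fid, estimate=np.nan, se=np.nan,
                             tstat=np.nan, df=np.nan, p=np.nan))
            continue
        t, p = stats.ttest_ind(m, f, equal_var=True)
        n1, n2 = len(m), len(f)
        sp = np.sqrt(((n1 - 1) * m.var(ddof=1) + (n2 - 1) * f.var(ddof=1))
                     / (n1 + n2 - 2))
        se = sp * np.sqrt(1 / n1 + 1 / n2)
        rows.append(dict(feature_id=fid, estimate=m.mean() - f.mean(), se=se,
                         tstat=float(t), df=n1 + n2 - 2, p=float(p)))
    res = pd.DataFrame(rows)
    ok = res["p"].notna()
    res["adj_p"] = np.nan
    if ok.any():
        res.loc[ok, "adj_p"] = multipletests(res.loc[ok, "p"],
                                             method="fdr_bh")[1]
    res["significant"] = res["adj_p"] < alpha
    return res


def estimate_precision_weights(counts: pd.DataFrame, design: pd.DataFrame,
                               covariates=DEFAULT_COVARIATES,
                               span: float = 0.5) -> pd.DataFrame:
    """Per-observation precision weights from the log-CPM mean-variance trend.

    The mean-variance relationship of count data is modeled on the scale of
    sqrt residual standard deviation versus average log2 count: log-CPM is
    computed with a 0.5 offset, a per-feature linear model is fit on the
    cell-means design, a lowess curve of sqrt-SD on mean log2 count is
    estimated, and each observation's weight is the inverse fourth power of
    the trend value at its fitted log2 count.
    """
    vals = counts.to_numpy(float)
    if vals.shape[0] < 10:
        warnings.warn("fewer than 10 features: mean-variance trend is "
                      "unreliable, returning unit weights")
        return pd.DataFrame(np.ones_like(vals), index=counts.index,
                            columns=counts.columns)
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate weights")
    lib = vals.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size sample")
    logcpm = np.log2((vals + 0.5) / (lib + 1.0) * 1e6)
    d = design.loc[list(counts.columns)]
    X, _ = build_design_matrix(d, covariates)
    coef, _, _, _ = np.linalg.lstsq(X, logcpm.T, rcond=None)
    fitted = (X @ coef).T
    resid = logcpm - fitted
    dof = max(vals.shape[1] - np.linalg.matrix_rank(X), 1)
    sd = np.sqrt((resid**2).sum(axis=1) / dof)
    mean_logcount = logcpm.mean(axis=1) + np.log2(np.exp(np.mean(np.log(lib + 1.0)))) - np.log2(1e6)
    lo = lowess(np.sqrt(sd), mean_logcount, frac=span, return_sorted=True)
    lo_x, lo_y = lo[:, 0], np.maximum(lo[:, 1], 1e-4)
    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, lo_x, lo_y)
    w = pred**-4.0
    return pd.DataFrame(w, index=counts.index, columns=counts.columns)


def build_zscore_matrix(results: pd.DataFrame, mapping=None,
                        phospho_expand: bool = False,
                        z_cap: float = Z_CAP) -> pd.DataFrame:
    """Signed standard-normal deviate matrix (identifiers x contrasts).

    z = sign(estimate) * Phi^-1(1 - p/2). Features mapping to the same
    identifier are collapsed to the single most extreme z (maximum |z|)
    per contrast. With ``phospho_expand``, multi-site identifiers like
    ``PROT_S1;S2`` are first split into one row per single site carrying
    identical values, then collapsed per site by max |z|.

    ``mapping`` maps feature_id -> identifier (dict or Series); unmapped
    features are dropped.
    """
    res = results[results["p"].notna()].copy()
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(res["p"].to_numpy() / 2.0)
    z = np.clip(z, None, z_cap)
    res["z"] = np.sign(res["estimate"].to_numpy()) * z
    res.loc[res["estimate"] == 0, "z"] = 0.0

    if mapping is not None:
        mp = pd.Series(mapping)
        res["identifier"] = res["feature_id"].map(mp)
        res = res[res["identifier"].notna()]
    else:
        res["identifier"] = res["feature_id"]

    if phospho_expand:
        expanded = []
        for _, r in res.iterrows():
            ident = r["identifier"]
            if "_" in ident and ";" in ident.split("_")[-1]:
                prot, sites = ident.rsplit("_", 1)
                for site in sites.split(";"):
                    r2 = r.copy()
                    r2["identifier"] = f"{prot}_{site}"
                    expanded.append(r2)
            else:
                expanded.append(r)
        res = pd.DataFrame(expanded)

    def most_extreme(s: pd.Series) -> float:
        return s.iloc[np.argmax(np.abs(s.to_numpy()))]

    zmat = (res.groupby(["identifier", "contrast"])["z"]
            .apply(most_extreme).unstack("contrast"))
    zmat.index.name = "identifier"
    return zmat
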