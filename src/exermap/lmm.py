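"""Repeated-measures model engines.

A lightweight random-intercept linear mixed model (REML, profiled
variance ratio, Satterthwaite contrast df) plus a Gaussian GEE with AR(1)
working correlation and sandwich standard errors, and an unstructured-
covariance GLS for the paired pre/post design. These power both the
per-feature differential analysis and the type-I-error/power simulation,
where tens of thousands of fits must complete in minutes; correctness is
cross-checked against statsmodels in the test suite.

The random-intercept model is y = X b + Z u + e with u ~ N(0, tau2 I) on
participants and e ~ N(0, sigma2 D), D = diag(1/w) for optional precision
weights. All clusters share the profiled variance ratio
theta = tau2/sigma2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["MixedFit", "GEEFit", "fit_random_intercept", "fit_gee_ar1",
           "fit_mmrm_by_profile", "fit_ols"]


def _group_slices(groups: np.ndarray):
    """Stable sort of observations by cluster; returns order and boundaries."""
    order = np.argsort(groups, kind="stable")
    g = np.asarray(groups)[order]
    starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
    return order, starts


@dataclass
class MixedFit:
    """Fitted random-intercept mixed model."""

    beta: np.ndarray
    cov_beta: np.ndarray          # Var(beta_hat) at the REML estimates
    sigma2: float                 # residual variance
    tau2: float                   # random-intercept variance
    df_resid: float
    n_obs: int
    n_groups: int
    singular: bool                # tau2 hit the zero boundary
    columns: list = field(default_factory=list)
    _satt: object = None          # callable c -> Satterthwaite df

    def contrast(self, c: np.ndarray):
        """Test c'beta = 0. Returns (estimate, se, tstat, df, p)."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov_beta @ c))
        if se == 0.0:
            return est, se, np.nan, np.nan, np.nan
        t = est / se
        df = float(self._satt(c)) if self._satt is not None else self.df_resid
        df = max(df, 1.0)
        p = 2.0 * stats.t.sf(abs(t), df)
        return est, se, t, df, p


def fit_random_intercept(y, X, groups, weights=None, columns=None) -> MixedFit:
    """REML fit of the random-intercept model with profiled variance ratio.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design (full column rank after cleaning)
    groups : (n,) cluster labels (participants)
    weights : (n,) optional precision weights; residual variance is sigma2/w
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("precision weights must be positive")

    order, starts = _group_slices(groups)
    ys, Xs, ws = y[order], X[order], w[order]
    G = len(starts)
    # per-cluster sufficient statistics for the Woodbury identity:
    # Vi^{-1} = Di^{-1} - theta (Di^{-1} 1)(1' Di^{-1}) / (1 + theta s_i)
    # with Di^{-1} = diag(w) and s_i = sum of w in cluster i
    Xw = Xs * ws[:, None]
    yw = ys * ws
    XtWX = Xs.T @ Xw
    XtWy = Xs.T @ yw
    ytWy = float(ys @ yw)
    Sx = np.add.reduceat(Xw, starts, axis=0)          # (G, p) cluster sums of w*x
    Sy = np.add.reduceat(yw, starts)                  # (G,)
    s = np.add.reduceat(ws, starts)                   # (G,)
    sum_log_w = float(np.sum(np.log(ws)))

    def gls(theta):
        f = theta / (1.0 + theta * s)                 # (G,)
        A = XtWX - np.einsum("g,gi,gj->ij", f, Sx, Sx)
        b = XtWy - Sx.T @ (f * Sy)
        q = ytWy - float(f @ Sy**2)
        beta = np.linalg.solve(A, b)
        rss = q - float(b @ beta)
        return A, beta, max(rss, 1e-300)

    def reml_crit(theta):
        A, _, rss = gls(theta)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        logdet_V = float(np.sum(np.log1p(theta * s))) - sum_log_w
        return (n - p) * np.log(rss / (n - p)) + logdet_V + logdet_A

    res = optimize.minimize_scalar(
        lambda lt: reml_crit(np.exp(lt)), bounds=(-13.0, 9.0), method="bounded",
        options={"xatol": 1e-8},
    )
    theta = float(np.exp(res.x))
    singular = False
    if reml_crit(0.0) <= res.fun or theta < 1e-5:
        theta, singular = 0.0, True

    A, beta, rss = gls(theta)
    sigma2 = rss / (n - p)
    tau2 = theta * sigma2
    cov_beta = sigma2 * np.linalg.inv(A)

    if singular:
        # zero random-intercept variance: (weighted) OLS point estimates with
        # cluster-robust (CR1) covariance, flagged
        r = ys - Xs @ beta
        Ainv = np.linalg.inv(XtWX)
        U = np.add.reduceat(Xw * r[:, None], starts, axis=0)
        meat = U.T @ U
        cr1 = G / max(G - 1, 1) * (n - 1) / max(n - p, 1)
        cov_beta = cr1 * Ainv @ meat @ Ainv
        fit = MixedFit(beta, cov_beta, sigma2, 0.0, df_resid=max(G - 1, 1),
                       n_obs=n, n_groups=G, singular=True,
                       columns=list(columns) if columns is not None else [])
        fit._satt = lambda c: max(G - 1, 1)
        return fit

    def cov_fun(s2, t2):
        th = t2 / s2
        f = th / (1.0 + th * s)
        Ath = XtWX - np.einsum("g,gi,gj->ij", f, Sx, Sx)
        return s2 * np.linalg.inv(Ath)

    def reml_nll(s2, t2):
        """-2 REML log-likelihood (up to a constant) in (sigma2, tau2)."""
        th = t2 / s2
        Ath, _, rss_th = gls(th)
        logdet_V = n * np.log(s2) + float(np.sum(np.log1p(th * s))) - sum_log_w
        sign, logdet_A = np.linalg.slogdet(Ath / s2)
        return logdet_V + logdet_A + rss_th / s2

    # Satterthwaite: df = 2 g^2 / (grad' H^{-1} grad), H the observed
    # information of the REML criterion in (sigma2, tau2)
    t2_eff = max(tau2, 1e-8 * sigma2)
    hs, ht = 1e-4 * sigma2, 1e-4 * max(t2_eff, 1e-4 * sigma2)

    def hessian():
        f0 = reml_nll(sigma2, t2_eff)
        fpp = reml_nll(sigma2 + hs, t2_eff + ht)
        fpm = reml_nll(sigma2 + hs, t2_eff - ht)
        fmp = reml_nll(sigma2 - hs, t2_eff + ht)
        fmm = reml_nll(sigma2 - hs, t2_eff - ht)
        fp0 = reml_nll(sigma2 + hs, t2_eff)
        fm0 = reml_nll(sigma2 - hs, t2_eff)
        f0p = reml_nll(sigma2, t2_eff + ht)
        f0m = reml_nll(sigma2, t2_eff - ht)
        h11 = (fp0 - 2 * f0 + fm0) / hs**2
        h22 = (f0p - 2 * f0 + f0m) / ht**2
        h12 = (fpp - fpm - fmp + fmm) / (4 * hs * ht)
        return 0.5 * np.array([[h11, h12], [h12, h22]])

    H = hessian()

    def satt(c):
        c = np.asarray(c, dtype=float)
        g0 = float(c @ cov_fun(sigma2, t2_eff) @ c)
        g_s = (float(c @ cov_fun(sigma2 + hs, t2_eff) @ c)
               - float(c @ cov_fun(sigma2 - hs, t2_eff) @ c)) / (2 * hs)
        g_t = (float(c @ cov_fun(sigma2, t2_eff + ht) @ c)
               - float(c @ cov_fun(sigma2, t2_eff - ht) @ c)) / (2 * ht)
        grad = np.array([g_s, g_t])
        try:
            denom = float(grad @ np.linalg.solve(H, grad))
        except np.linalg.LinAlgError:
            denom = np.nan
        if not np.isfinite(denom) or denom <= 0:
            return n - p
        return min(2.0 * g0**2 / denom, n - p)

    fit = MixedFit(beta, cov_beta, sigma2, tau2, df_resid=n - p, n_obs=n,
                   n_groups=G, singular=False,
                   columns=list(columns) if columns is not None else [])
    fit._satt = satt
    return fit


@dataclass
class GEEFit:
    """Fitted Gaussian GEE with AR(1) working correlation."""

    beta: np.ndarray
    cov_beta: np.ndarray          # robust sandwich covariance
    alpha: float                  # AR(1) parameter
    scale: float
    n_obs: int
    n_groups: int
    converged: bool

    def contrast(self, c: np.ndarray):
        """Wald z-test of c'beta = 0 (normal reference, GEE convention)."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov_beta @ c))
        if se == 0.0:
            return est, se, np.nan, np.nan, np.nan
        z = est / se
        p = 2.0 * stats.norm.sf(abs(z))
        return est, se, z, np.inf, p


def fit_gee_ar1(y, X, groups, times, maxiter=40, tol=1e-7) -> GEEFit:
    """Gaussian identity-link GEE with AR(1) working correlation.

    ``times`` are integer/real time positions; the working correlation of
    two observations at lag d is alpha^|d|. Robust (sandwich) covariance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    n, p = X.shape
    order, starts = _group_slices(np.asarray(groups))
    ys, Xs, ts = y[order], X[order], times[order]
    ends = np.r_[starts[1:], n]
    G = len(starts)
    clusters = [(Xs[a:b], ys[a:b], ts[a:b]) for a, b in zip(starts, ends)]

    beta = np.linalg.lstsq(Xs, ys, rcond=None)[0]
    alpha = 0.0
    converged = False
    for _ in range(maxiter):
        r = ys - Xs @ beta
        scale = float(r @ r) / (n - p)
        e = r / np.sqrt(scale)
        # scalar least squares for alpha on within-cluster residual products
        prods, lags = [], []
        for (Xi, yi, ti), a, b in zip(clusters, starts, ends):
            m = b - a
            if m < 2:
                continue
            ei = e[a:b]
            for i in range(m):
                for j in range(i + 1, m):
                    prods.append(ei[i] * ei[j])
                    lags.append(abs(ti[i] - ti[j]))
        prods = np.array(prods)
        lags = np.array(lags)
        if len(prods):
            res = optimize.minimize_scalar(
                lambda a_: float(np.sum((prods - a_ ** lags) ** 2)),
                bounds=(0.0, 0.999), method="bounded",
            )
            alpha = float(res.x)
        B = np.zeros((p, p))
        bvec = np.zeros(p)
        for Xi, yi, ti in clusters:
            Ri = alpha ** np.abs(ti[:, None] - ti[None, :])
            Ri_inv = np.linalg.inv(Ri)
            XtRi = Xi.T @ Ri_inv
            B += XtRi @ Xi
            bvec += XtRi @ yi
        beta_new = np.linalg.solve(B, bvec)
        if np.max(np.abs(beta_new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new

    r = ys - Xs @ beta
    scale = float(r @ r) / (n - p)
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    for (Xi, yi, ti), a, b in zip(clusters, starts, ends):
        Ri = alpha ** np.abs(ti[:, None] - ti[None, :])
        Vi_inv = np.linalg.inv(scale * Ri)
        XtVi = Xi.T @ Vi_inv
        B += XtVi @ Xi
        ui = XtVi @ r[a:b]
        M += np.outer(ui, ui)
    B_inv = np.linalg.inv(B)
    cov = B_inv @ M @ B_inv
    return GEEFit(beta, cov, alpha, scale, n, G, converged)


def fit_mmrm_by_profile(y, X, groups, profile, timepoint, maxiter=8):
    """GLS with an unstructured covariance over observed timepoint pairs.

    With each participant observed at pre plus one profile-specific post
    timepoint, the estimable part of the unstructured covariance is a 2x2
    block per temporal profile (pre variance shared). Iterated GLS;
    contrast tests use a t reference with df = clusters - estimated
    covariance parameters.

    Returns (beta, cov_beta, df).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    profile = np.asarray(profile)
    timepoint = np.asarray(timepoint)
    n, p = X.shape
    order, starts = _group_slices(np.asarray(groups))
    ys, Xs = y[order], X[order]
    prs, tps = profile[order], timepoint[order]
    ends = np.r_[starts[1:], n]
    G = len(starts)

    beta = np.linalg.lstsq(Xs, ys, rcond=None)[0]
    profs = sorted(set(prs))
    for _ in range(maxiter):
        r = ys - Xs @ beta
        # pooled pre variance; per-profile post variance and pre-post covariance
        pre_mask = tps == "pre"
        v_pre = float(np.mean(r[pre_mask] ** 2))
        cov_blocks = {}
        for prof in profs:
            rp_pre, rp_post = [], []
            for a, b in zip(starts, ends):
                if prs[a] != prof or b - a != 2:
                    continue
                i_pre = a if tps[a] == "pre" else a + 1
                i_post = a + 1 if tps[a] == "pre" else a
                rp_pre.append(r[i_pre])
                rp_post.append(r[i_post])
            rp_pre, rp_post = np.array(rp_pre), np.array(rp_post)
            v_post = float(np.mean(rp_post**2)) if len(rp_post) else v_pre
            c_pp = float(np.mean(rp_pre * rp_post)) if len(rp_post) else 0.0
            # keep the block positive definite
            bound = 0.99 * np.sqrt(v_pre * v_post)
            c_pp = float(np.clip(c_pp, -bound, bound))
            cov_blocks[prof] = (v_post, c_pp)
        B = np.zeros((p, p))
        bvec = np.zeros(p)
        for a, b in zip(starts, ends):
            Xi, yi = Xs[a:b], ys[a:b]
            if b - a == 1:
                v = v_pre if tps[a] == "pre" else cov_blocks[prs[a]][0]
                Vi_inv = np.array([[1.0 / v]])
            else:
                v_post, c_pp = cov_blocks[prs[a]]
                if tps[a] == "pre":
                    Vi = np.array([[v_pre, c_pp], [c_pp, v_post]])
                else:
                    Vi = np.array([[v_post, c_pp], [c_pp, v_pre]])
                Vi_inv = np.linalg.inv(Vi)
            XtVi = Xi.T @ Vi_inv
            B += XtVi @ Xi
            bvec += XtVi @ yi
        beta = np.linalg.solve(B, bvec)
    cov_beta = np.linalg.inv(B)
    n_cov_params = 1 + 2 * len(profs)
    df = max(G - n_cov_params, 2)
    return beta, cov_beta, df


def fit_ols(y, X):
    """OLS fit; returns (beta, cov_beta, df) with the residual-df t reference."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    sigma2 = float(r @ r) / (n - rank)
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return beta, cov, n - rank
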