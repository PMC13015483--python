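"""Moment-matched non-normal random sampling.

Generates multivariate data with specified mean, covariance, marginal
skewness and excess kurtosis via a third-order polynomial transform of a
Gaussian copula (the Fleishman power method per marginal, combined with
the Vale-Maurelli intermediate-correlation construction). This is the
generator behind both the synthetic multi-omic cohorts and the
repeated-measures simulation study.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

__all__ = [
    "fleishman_coefficients",
    "intermediate_correlation",
    "moment_matched_sample",
    "InfeasibleMomentsError",
]


class InfeasibleMomentsError(ValueError):
    """Requested (skewness, excess kurtosis) pair has no polynomial transform.

    Any distribution satisfies kurtosis >= skewness^2 - 2; the third-order
    polynomial family is feasible only on a slightly smaller region.
    """


def _fleishman_system(coef: np.ndarray, skew: float, ekurt: float) -> np.ndarray:
    b, c, d = coef
    var = b * b + 6.0 * b * d + 2.0 * c * c + 15.0 * d * d
    sk = 2.0 * c * (b * b + 24.0 * b * d + 105.0 * d * d + 2.0)
    ku = 24.0 * (
        b * d
        + c * c * (1.0 + b * b + 28.0 * b * d)
        + d * d * (12.0 + 48.0 * b * d + 141.0 * c * c + 225.0 * d * d)
    )
    return np.array([var - 1.0, sk - skew, ku - ekurt])


def fleishman_coefficients(skew: float, ekurt: float) -> tuple[float, float, float, float]:
    """Solve for (a, b, c, d) with Y = a + bZ + cZ^2 + dZ^3 standardized.

    Y has mean 0, variance 1, the requested skewness and excess kurtosis.

    Raises
    ------
    InfeasibleMomentsError
        If no real solution exists (violated bound reported in the message).
    """
    if ekurt < skew**2 - 2.0:
        raise InfeasibleMomentsError(
            f"excess kurtosis {ekurt} violates the universal bound "
            f"kurt >= skew^2 - 2 = {skew**2 - 2.0:.4f}"
        )
    # multiple starts: the system has spurious roots for extreme moments
    starts = [(1.0, 0.0, 0.0), (0.9, 0.1 * np.sign(skew or 1.0), 0.03), (0.8, 0.2 * np.sign(skew or 1.0), 0.1)]
    for x0 in starts:
        sol, info, ier, _ = optimize.fsolve(
            _fleishman_system, x0, args=(skew, ekurt), full_output=True, xtol=1e-12
        )
        if ier == 1 and np.max(np.abs(info["fvec"])) < 1e-9:
            b, c, d = sol
            return (-c, b, c, d)
    raise InfeasibleMomentsError(
        f"no third-order polynomial transform exists for skew={skew}, "
        f"excess kurtosis={ekurt}; the pair lies outside the Fleishman-feasible "
        "region (approximately kurt >= 1.59*skew^2 - 1.13)"
    )


def _pairwise_corr_poly(rho: float, ci: np.ndarray, cj: np.ndarray) -> float:
    """Correlation of two Fleishman variates given latent Gaussian corr rho."""
    _, bi, c2i, di = ci
    _, bj, c2j, dj = cj
    return (
        rho * (bi * bj + 3.0 * bi * dj + 3.0 * di * bj + 9.0 * di * dj)
        + rho**2 * (2.0 * c2i * c2j)
        + rho**3 * (6.0 * di * dj)
    )


def intermediate_correlation(target: float, ci, cj) -> float:
    """Latent Gaussian correlation that yields `target` after transformation."""
    ci = np.asarray(ci, dtype=float)
    cj = np.asarray(cj, dtype=float)
    if abs(target) < 1e-12:
        return 0.0
    f = lambda r: _pairwise_corr_poly(r, ci, cj) - target
    lo, hi = -0.9999, 0.9999
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:  # unattainable; clamp to the boundary
        return hi if abs(fhi) < abs(flo) else lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def _nearest_psd(a: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    w, v = np.linalg.eigh((a + a.T) / 2.0)
    w = np.clip(w, eps, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    return out / np.outer(d, d)


def moment_matched_sample(
    mean,
    cov,
    skew,
    kurt,
    n: int,
    seed=None,
) -> np.ndarray:
    """Draw n observations of a random vector with the given first four moments.

    Parameters
    ----------
    mean, skew, kurt : array-like, shape (p,)
        Target means, marginal skewnesses, and marginal *excess* kurtoses.
    cov : array-like, shape (p, p)
        Target covariance matrix (symmetric PSD).
    n : int
        Number of rows to draw.
    seed : int, Generator or None
        Randomness source.

    Returns
    -------
    ndarray of shape (n, p)
    """
    rng = np.random.default_rng(seed)
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    skew = np.broadcast_to(np.asarray(skew, dtype=float), mean.shape)
    kurt = np.broadcast_to(np.asarray(kurt, dtype=float), mean.shape)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    p = mean.size
    if cov.shape != (p, p):
        raise ValueError(f"cov shape {cov.shape} does not match mean length {p}")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("cov must be symmetric")
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        raise ValueError("cov must have positive diagonal")
    corr = cov / np.outer(sd, sd)
    if np.min(np.linalg.eigvalsh((corr + corr.T) / 2)) < -1e-8:
        raise ValueError("cov must be positive semi-definite")

    coefs = [fleishman_coefficients(skew[j], kurt[j]) for j in range(p)]

    inter = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            inter[i, j] = inter[j, i] = intermediate_correlation(
                corr[i, j], coefs[i], coefs[j]
            )
    if np.min(np.linalg.eigvalsh(inter)) < 1e-10:
        inter = _nearest_psd(inter)

    try:
        z = rng.multivariate_normal(np.zeros(p), inter, size=n, method="cholesky")
    except np.linalg.LinAlgError:
        z = rng.multivariate_normal(np.zeros(p), inter, size=n, method="eigh")
    out = np.empty_like(z)
    for j, (a, b, c, d) in enumerate(coefs):
        zj = z[:, j]
        out[:, j] = a + zj * (b + zj * (c + zj * d))
    return mean + out * sd
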