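"""Type-I-error and power simulation for repeated-measures strategies.

Recreates the model-selection experiment behind the differential
pipeline: moment-matched non-normal pre/post data are generated under the
study's temporal-profile design (every participant contributes a
pre-exercise value plus one post value at their randomized timepoint),
and candidate analysis strategies are scored on the fraction of
difference-in-changes contrasts rejected at alpha under the null
(type I error) and under a planted effect (power).

Strategies
----------
``paired_t``            two-sample pooled t-test on within-participant changes
``ols``                 ordinary least squares ignoring the repeated measures
``lmm_ri``              random-intercept mixed model, Satterthwaite df
``lmm_ri_weighted``     the same model with precision weights (the
                        weighted-LMM representation of count pipelines);
                        with unit weights it coincides with ``lmm_ri``
``mmrm_unstructured``   GLS with an unstructured covariance over observed
                        timepoint pairs
``gee_ar1``             Gaussian GEE, AR(1) working correlation, sandwich SEs
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import make_contrast_vector
from .lmm import fit_gee_ar1, fit_mmrm_by_profile, fit_ols, fit_random_intercept
from .moments import moment_matched_sample
from .simulate import DEFAULT_PROFILE_WEIGHTS, PROFILE_TO_TIMEPOINT, generate_cohort

__all__ = ["SimulationSpec", "ALL_STRATEGIES", "evaluate_strategies",
           "summarize_moments"]

ALL_STRATEGIES = ("paired_t", "ols", "lmm_ri_weighted", "lmm_ri",
                  "mmrm_unstructured", "gee_ar1")

#: integer time positions used by the AR(1) working correlation
_TIME_INDEX = {"pre": 0.0, "45min": 1.0, "4hr": 2.0, "24hr": 3.0}


@dataclass
class SimulationSpec:
    """Simulation configuration.

    Defaults mirror the adipose acute-exercise cohort: group sizes EE=63,
    RE=73, CON=37; temporal-profile missingness in the real randomization
    proportions (each participant observed at pre plus one post
    timepoint); within-participant correlation 0.5; marginal skewness 1
    and excess kurtosis 3. Sample sizes are kept at the cohort's actual
    values because the small-sample behavior of sandwich-variance methods
    is exactly what the experiment measures; only the replication count is
    reduced relative to the original multi-million-instance study.
    """

    n_per_group: dict = field(default_factory=lambda: {"EE": 63, "RE": 73, "CON": 37})
    profile_weights: tuple = DEFAULT_PROFILE_WEIGHTS
    within_cor: float = 0.5
    skew: float = 1.0
    kurt: float = 3.0
    effect: float = 1.0        # alternative difference-in-changes effect (SD units)
    n_reps: int = 2000
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not -1.0 < self.within_cor < 1.0:
            raise ValueError("within_cor must lie in (-1, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _build_static_design(spec: SimulationSpec, rng):
    """Cohort layout shared by all replicates."""
    design = generate_cohort(spec.n_per_group, spec.profile_weights,
                             seed=rng.integers(2**31))
    design = design.reset_index(drop=True)
    cells = design["group"].astype(str) + ":" + design["timepoint"].astype(str)
    cell_levels = sorted(set(cells))
    X = np.column_stack([(cells == lev).to_numpy(float) for lev in cell_levels])
    columns = [f"cell:{lev}" for lev in cell_levels]
    contrasts = []
    for g in ("EE", "RE"):
        for tp in ("45min", "4hr", "24hr"):
            cvec = make_contrast_vector(columns, "difference_in_changes", g, tp)
            if cvec is not None:
                contrasts.append((f"dd:{g}:{tp}", g, tp, cvec))
    info = dict(
        design=design,
        X=X,
        columns=columns,
        groups=design["participant_id"].to_numpy(),
        times=design["timepoint"].map(_TIME_INDEX).to_numpy(float),
        profile=design["profile"].to_numpy(),
        timepoint=design["timepoint"].to_numpy(),
        is_post=(design["timepoint"] != "pre").to_numpy(),
        is_exercise=design["group"].isin(["EE", "RE"]).to_numpy(),
        contrasts=contrasts,
    )
    return info


def _simulate_responses(spec: SimulationSpec, info, rng, effect: float):
    """(n_reps, n_obs) response array under the given planted dd effect."""
    design = info["design"]
    participants = design["participant_id"].unique()
    n_part = len(participants)
    cov = np.array([[1.0, spec.within_cor], [spec.within_cor, 1.0]])
    draws = moment_matched_sample(
        np.zeros(2), cov, [spec.skew, spec.skew], [spec.kurt, spec.kurt],
        n=spec.n_reps * n_part, seed=rng,
    ).reshape(spec.n_reps, n_part, 2)
    # map participant x {pre,post} onto design rows
    p_index = {p: i for i, p in enumerate(participants)}
    row_part = np.array([p_index[p] for p in design["participant_id"]])
    row_slot = info["is_post"].astype(int)
    y = draws[:, row_part, row_slot]
    if effect != 0.0:
        y[:, info["is_post"] & info["is_exercise"]] += effect
    return y


def _paired_t_pvals(y_rep, info, contrasts):
    design = info["design"]
    out = []
    delta_cache = {}
    for name, g, tp, _ in contrasts:
        prof = {v: k for k, v in PROFILE_TO_TIMEPOINT.items()}[tp]
        key = (g, prof)
        pvals = []
        for grp in (g, "CON"):
            mask = (design["group"] == grp) & (design["profile"] == prof)
            sub = design[mask]
            pre_rows = sub.index[sub["timepoint"] == "pre"].to_numpy()
            post_rows = sub.index[sub["timepoint"] == tp].to_numpy()
            # rows are participant-ordered within the cohort table
            delta_cache[(grp, prof)] = (y_rep[post_rows] - y_rep[pre_rows])
        d1, d0 = delta_cache[(g, prof)], delta_cache[("CON", prof)]
        if len(d1) < 2 or len(d0) < 2:
            out.append(np.nan)
            continue
        _, p = stats.ttest_ind(d1, d0, equal_var=True)
        out.append(float(p))
    return out


def _strategy_pvalues(strategy, y_rep, info, weights=None):
    """P-values for every difference-in-changes contrast in one replicate."""
    contrasts = info["contrasts"]
    if strategy == "paired_t":
        return _paired_t_pvals(y_rep, info, contrasts)
    if strategy == "ols":
        beta, cov, df = fit_ols(y_rep, info["X"])
        out = []
        for _, _, _, c in contrasts:
            se = np.sqrt(c @ cov @ c)
            t = (c @ beta) / se
            out.append(2.0 * stats.t.sf(abs(t), df))
        return out
    if strategy in ("lmm_ri", "lmm_ri_weighted"):
        fit = fit_random_intercept(y_rep, info["X"], info["groups"],
                                   weights=weights)
        return [fit.contrast(c)[4] for _, _, _, c in contrasts]
    if strategy == "mmrm_unstructured":
        beta, cov, df = fit_mmrm_by_profile(y_rep, info["X"], info["groups"],
                                            info["profile"], info["timepoint"])
        out = []
        for _, _, _, c in contrasts:
            se = np.sqrt(c @ cov @ c)
            t = (c @ beta) / se
            out.append(2.0 * stats.t.sf(abs(t), df))
        return out
    if strategy == "gee_ar1":
        fit = fit_gee_ar1(y_rep, info["X"], info["groups"], info["times"])
        if not fit.converged:
            return None
        return [fit.contrast(c)[4] for _, _, _, c in contrasts]
    raise ValueError(f"unknown strategy {strategy!r}")


def _rejection_rate(spec, info, y, strategy):
    n_rej = 0
    n_tests = 0
    n_failed = 0
    for r in range(y.shape[0]):
        try:
            pvals = _strategy_pvalues(strategy, y[r], info)
        except (np.linalg.LinAlgError, ValueError):
            pvals = None
        if pvals is None:
            n_failed += 1
            continue
        pv = np.asarray(pvals, dtype=float)
        pv = pv[np.isfinite(pv)]
        n_tests += pv.size
        n_rej += int(np.sum(pv < spec.alpha))
    rate = n_rej / n_tests if n_tests else np.nan
    return rate, n_tests, y.shape[0] - n_failed, n_failed


def evaluate_strategies(spec: SimulationSpec,
                        strategies=ALL_STRATEGIES,
                        run_power: bool = True) -> pd.DataFrame:
    """Run the simulation and score each strategy.

    Returns a DataFrame with one row per strategy: empirical
    ``type_I_error`` (rejection fraction over the six pooled
    difference-in-changes contrasts under the null), ``power`` (under the
    planted effect, if ``run_power``), Monte-Carlo standard errors, and
    convergence counts. Strategies with > 5% failed replicates are flagged
    ``unstable``.
    """
    spec.validate()
    unknown = set(strategies) - set(ALL_STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    info = _build_static_design(spec, rng)
    y_null = _simulate_responses(spec, info, rng, effect=0.0)
    y_alt = (_simulate_responses(spec, info, rng, effect=spec.effect)
             if run_power and spec.effect != 0 else None)

    rows = []
    for strat in strategies:
        t1, n_t1, conv_null, failed_null = _rejection_rate(spec, info, y_null, strat)
        se1 = np.sqrt(t1 * (1 - t1) / n_t1) if n_t1 else np.nan
        row = dict(strategy=strat, type_I_error=t1, type_I_mc_se=se1,
                   n_tests_null=n_t1, n_converged_null=conv_null,
                   unstable=failed_null > 0.05 * spec.n_reps)
        if y_alt is not None:
            pw, n_pw, conv_alt, failed_alt = _rejection_rate(spec, info, y_alt, strat)
            row.update(power=pw,
                       power_mc_se=np.sqrt(pw * (1 - pw) / n_pw) if n_pw else np.nan,
                       n_converged_alt=conv_alt)
            row["unstable"] = row["unstable"] or failed_alt > 0.05 * spec.n_reps
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_moments(matrix: pd.DataFrame, design: pd.DataFrame,
                      min_cell: int = 4) -> SimulationSpec:
    """Summarize observed data into a SimulationSpec.

    Pre/post pairs are collected per participant; the pooled
    within-participant correlation and the pooled marginal skewness and
    excess kurtosis (within sex-by-group subgroups, variance-standardized)
    are packaged with the design's group sizes.
    """
    d = design.loc[list(matrix.columns)]
    pre_of, post_of = {}, {}
    for pid, sub in d.groupby("participant_id"):
        pre = sub[sub["timepoint"] == "pre"]
        post = sub[sub["timepoint"] != "pre"]
        if len(pre) == 1 and len(post) == 1:
            pre_of[pid] = pre["sample_id"].iloc[0]
            post_of[pid] = post["sample_id"].iloc[0]
    pids = list(pre_of)
    if len(pids) < min_cell:
        raise ValueError("insufficient paired participants to summarize moments")

    cors, skews, kurts = [], [], []
    groups_of = d.drop_duplicates("participant_id").set_index("participant_id")
    for (sex, grp), sub in groups_of.groupby(["sex", "group"]):
        sub_pids = [p for p in sub.index if p in pre_of]
        if len(sub_pids) < min_cell:
            continue
        pre_vals = matrix[[pre_of[p] for p in sub_pids]].to_numpy(float)
        post_vals = matrix[[post_of[p] for p in sub_pids]].to_numpy(float)
        for f in range(pre_vals.shape[0]):
            a, b = pre_vals[f], post_vals[f]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < min_cell:
                continue
            a, b = a[ok], b[ok]
            if a.std() == 0 or b.std() == 0:
                raise ValueError(
                    f"zero variance in cell sex={sex}, group={grp}, feature {f}")
            cors.append(np.corrcoef(a, b)[0, 1])
            pooled = np.concatenate([a - a.mean(), b - b.mean()])
            skews.append(stats.skew(pooled, bias=False))
            kurts.append(stats.kurtosis(pooled, bias=False))
    if not cors:
        raise ValueError("no subgroup had enough complete pairs")
    n_per_group = groups_of["group"].value_counts().to_dict()
    return SimulationSpec(
        n_per_group=n_per_group,
        within_cor=float(np.mean(cors)),
        skew=float(np.mean(skews)),
        kurt=float(np.mean(kurts)),
    )
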