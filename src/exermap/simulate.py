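"""Synthetic acute-exercise cohorts and multi-omic matrices.

Emulates the statistical structure of a 3-group (endurance EE, resistance
RE, non-exercising control CON) x 4-timepoint (pre, 45min, 4hr, 24hr)
repeated-measures design in which every participant contributes a
pre-exercise sample plus exactly one post-exercise sample determined by
their randomized temporal profile (early -> 45min, middle -> 4hr,
late -> 24hr). Generated features carry planted difference-in-changes
effects, sex effects, correlated co-expression blocks, trajectory-cluster
archetypes, secreted-feature flags and missingness, all recorded in a
ground-truth table for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .moments import fleishman_coefficients

__all__ = [
    "GROUPS", "TIMEPOINTS", "PROFILES", "PROFILE_TO_TIMEPOINT",
    "EffectSpec", "generate_cohort", "generate_omics", "generate_two_tissue",
]

GROUPS = ("EE", "RE", "CON")
TIMEPOINTS = ("pre", "45min", "4hr", "24hr")
PROFILES = ("early", "middle", "late")
PROFILE_TO_TIMEPOINT = {"early": "45min", "middle": "4hr", "late": "24hr"}

#: temporal-profile randomization fractions of the real cohort (43/80/50 of 173)
DEFAULT_PROFILE_WEIGHTS = (43 / 173, 80 / 173, 50 / 173)


def _largest_remainder(n: int, weights) -> np.ndarray:
    """Integer allocation of n into len(weights) parts, largest-remainder rule."""
    w = np.asarray(weights, dtype=float)
    raw = n * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def generate_cohort(
    n_per_group: dict[str, int],
    profile_weights=DEFAULT_PROFILE_WEIGHTS,
    seed=None,
    p_female: float = 0.72,
    n_sites: int = 3,
) -> pd.DataFrame:
    """Generate a sample-design table for a synthetic acute-exercise cohort.

    Each participant contributes two samples: ``pre`` and the single post
    timepoint implied by their temporal profile.

    Parameters
    ----------
    n_per_group : dict
        Participants per group, keys from {"EE", "RE", "CON"}.
    profile_weights : length-3 sequence
        Fractions of participants randomized to the early/middle/late
        profiles (must sum to 1); allocated within each group by the
        largest-remainder rule.
    seed : int, Generator or None
    p_female : float
        Probability a participant is female (the study cohort was 72% female).
    n_sites : int
        Number of clinical sites, assigned round-robin.

    Returns
    -------
    DataFrame with one row per sample, indexed by sample_id.
    """
    for g, n in n_per_group.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
        if n < 0:
            raise ValueError(f"negative participant count for group {g!r}: {n}")
    w = np.asarray(profile_weights, dtype=float)
    if w.size != 3 or not np.isclose(w.sum(), 1.0):
        raise ValueError("profile_weights must be 3 fractions summing to 1")

    rng = np.random.default_rng(seed)
    rows = []
    pid_counter = 0
    for group in GROUPS:
        n = int(n_per_group.get(group, 0))
        if n == 0:
            continue
        alloc = _largest_remainder(n, w)
        profiles = np.repeat(PROFILES, alloc)
        rng.shuffle(profiles)
        for prof in profiles:
            pid_counter += 1
            pid = f"P{pid_counter:04d}"
            age = float(np.clip(rng.normal(41.0, 15.0), 18.0, 75.0))
            sex = "F" if rng.random() < p_female else "M"
            bmi = float(np.clip(rng.normal(27.1, 4.0), 18.0, 42.0))
            site = f"site{(pid_counter % n_sites) + 1}"
            batch = f"batch{(pid_counter % (2 * n_sites)) + 1}"
            for tp in ("pre", PROFILE_TO_TIMEPOINT[prof]):
                rows.append(
                    dict(sample_id=f"{pid}_{tp}", participant_id=pid, group=group,
                         timepoint=tp, profile=prof, age=round(age, 1), sex=sex,
                         bmi=round(bmi, 1), site=site, batch=batch)
                )
    design = pd.DataFrame(rows)
    if len(design):
        design = design.set_index("sample_id", drop=False)
    return design


@dataclass
class EffectSpec:
    """Planted-effect configuration for :func:`generate_omics`.

    Defaults emulate a desk-scale version of the study conditions: modest
    numbers of features per ome, non-normal marginals (skew 1, excess
    kurtosis 3), within-participant correlation 0.5, correlated
    co-expression blocks and a handful of temporal archetypes.
    """

    n_features_per_ome: int = 1000
    frac_dd_affected: float = 0.1
    dd_effect: float = 1.0          # standardized (post-pre)_ex - (post-pre)_con shift
    sex_effect: float = 1.0         # standardized male-minus-female shift
    frac_sex_affected: float = 0.05
    n_modules: int = 4
    module_size: int = 50
    module_cor: float = 0.8
    n_clusters: int = 4
    trajectory_shapes: bool = True  # scale dd effects by archetype timecourses
    skew: float = 1.0
    kurt: float = 3.0               # excess kurtosis
    participant_cor: float = 0.5    # within-participant (pre, post) correlation
    missing_frac: float = 0.0
    frac_secreted: float = 0.1
    omes: tuple = ("transcript", "protein", "metabolite")
    seed: int = 0

    def validate(self, ) -> None:
        for name in ("frac_dd_affected", "frac_sex_affected", "missing_frac",
                     "frac_secreted"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 <= self.module_cor < 1.0:
            raise ValueError("module_cor must lie in [0, 1)")
        if self.n_modules * self.module_size > self.n_features_per_ome:
            raise ValueError(
                f"n_modules*module_size = {self.n_modules * self.module_size} "
                f"exceeds n_features_per_ome = {self.n_features_per_ome}"
            )
        if self.kurt < self.skew**2 - 2.0:
            raise ValueError("kurt violates the bound kurt >= skew^2 - 2")


def _cluster_archetypes(n_clusters: int) -> np.ndarray:
    """Distinct temporal response shapes over the three post timepoints.

    Rows are unit-max-magnitude multipliers for (45min, 4hr, 24hr).
    """
    bank = np.array([
        [1.0, 0.6, 0.2],      # early-transient up
        [-1.0, -0.6, -0.2],   # early-transient down
        [0.2, 1.0, 0.4],      # mid-peak up
        [-0.2, -1.0, -0.4],   # mid-peak down
        [0.2, 0.6, 1.0],      # late-rising up
        [-0.2, -0.6, -1.0],   # late-rising down
        [1.0, -0.4, -1.0],    # biphasic
        [-1.0, 0.4, 1.0],     # inverse biphasic
    ])
    if n_clusters > len(bank):
        raise ValueError(f"at most {len(bank)} trajectory archetypes supported")
    return bank[:n_clusters]


def generate_omics(design: pd.DataFrame, spec: EffectSpec):
    """Generate one feature-by-sample matrix per ome plus a ground-truth table.

    Affected features carry the difference-in-changes effect only in the
    exercise groups' post samples, scaled by their trajectory archetype at
    the sample's timepoint. Module blocks share a per-sample latent factor
    giving the requested within-block correlation. Transcript matrices are
    returned as counts via negative-binomial quantile mapping of the latent
    Gaussian values; other omes are continuous (log2-like scale).

    Returns
    -------
    (matrices, truth) : (dict[str, DataFrame], DataFrame)
    """
    spec.validate()
    if len(design) == 0:
        raise ValueError("empty design")
    rng = np.random.default_rng(spec.seed)
    samples = design["sample_id"].to_numpy()
    n_samples = len(samples)
    participants = design["participant_id"].to_numpy()
    is_post = (design["timepoint"] != "pre").to_numpy()
    is_exercise = design["group"].isin(["EE", "RE"]).to_numpy()
    is_male = (design["sex"] == "M").to_numpy()
    tp_index = {"45min": 0, "4hr": 1, "24hr": 2}
    post_tp = np.array([tp_index.get(t, -1) for t in design["timepoint"]])

    uniq_p, p_idx = np.unique(participants, return_inverse=True)
    archetypes = _cluster_archetypes(spec.n_clusters)
    a_coef, b_coef, c_coef, d_coef = fleishman_coefficients(spec.skew, spec.kurt)

    matrices: dict[str, pd.DataFrame] = {}
    truth_rows = []
    p = spec.n_features_per_ome
    rho_m = spec.module_cor
    rho_p = spec.participant_cor

    for ome in spec.omes:
        # latent standard-normal structure: participant intercept + module
        # factor + idiosyncratic noise, combined to unit marginal variance
        part_eff = rng.standard_normal((p, len(uniq_p)))[:, p_idx]
        module_label = np.zeros(p, dtype=int)
        for m in range(spec.n_modules):
            lo = m * spec.module_size
            module_label[lo:lo + spec.module_size] = m + 1
        mod_factor = rng.standard_normal((spec.n_modules, n_samples))
        noise = rng.standard_normal((p, n_samples))

        resid_var = 1.0 - rho_p
        z = np.sqrt(rho_p) * part_eff
        in_mod = module_label > 0
        # within-block correlation rho_m comes out of the non-participant part
        z[in_mod] += np.sqrt(resid_var) * (
            np.sqrt(rho_m) * mod_factor[module_label[in_mod] - 1]
            + np.sqrt(1.0 - rho_m) * noise[in_mod]
        )
        z[~in_mod] += np.sqrt(resid_var) * noise[~in_mod]

        # non-normal marginals via the polynomial transform (variance 1)
        x = a_coef + z * (b_coef + z * (c_coef + z * d_coef))

        n_dd = int(round(spec.frac_dd_affected * p))
        dd_idx = rng.choice(p, size=n_dd, replace=False) if n_dd else np.array([], int)
        dd_sign = rng.choice([-1.0, 1.0], size=n_dd)
        cluster_label = np.full(p, -1, dtype=int)
        if n_dd:
            cluster_label[dd_idx] = rng.integers(0, spec.n_clusters, size=n_dd)
        affect_mask = is_post & is_exercise
        for k, f in enumerate(dd_idx):
            if spec.trajectory_shapes:
                shape = archetypes[cluster_label[f]]
                x[f, affect_mask] += (
                    spec.dd_effect * dd_sign[k] * shape[post_tp[affect_mask]]
                )
            else:
                x[f, affect_mask] += spec.dd_effect * dd_sign[k]

        n_sex = int(round(spec.frac_sex_affected * p))
        sex_idx = rng.choice(p, size=n_sex, replace=False) if n_sex else np.array([], int)
        if n_sex:
            x[np.ix_(sex_idx, np.where(is_male)[0])] += spec.sex_effect

        secreted = rng.random(p) < spec.frac_secreted
        feat_ids = np.array([f"{ome[:3].upper()}{i:05d}" for i in range(p)])

        if ome == "transcript":
            # NB quantile mapping: preserves structure, adds a mean-variance trend
            log_mu = rng.uniform(np.log(5.0), np.log(2000.0), size=p)
            mu = np.exp(log_mu)[:, None]
            disp = 0.2
            u = stats.norm.cdf(np.clip((x - x.mean(axis=1, keepdims=True)) / 1.0, -8, 8))
            u = np.clip(u, 1e-10, 1.0 - 1e-10)
            r = 1.0 / disp
            vals = stats.nbinom.ppf(u, r, r / (r + mu)).astype(float)
        else:
            vals = x.copy()
            if spec.missing_frac > 0:
                miss = rng.random(vals.shape) < spec.missing_frac
                vals[miss] = np.nan

        matrices[ome] = pd.DataFrame(vals, index=feat_ids, columns=samples)

        effect = np.zeros(p)
        effect[dd_idx] = spec.dd_effect * dd_sign
        is_sex = np.zeros(p, dtype=bool)
        is_sex[sex_idx] = True
        truth_rows.append(pd.DataFrame(dict(
            feature_id=feat_ids, ome=ome,
            is_dd_affected=np.isin(np.arange(p), dd_idx),
            dd_signed_effect=effect,
            module_label=np.where(module_label > 0, module_label.astype(str), "none"),
            cluster_label=np.where(cluster_label >= 0, cluster_label.astype(str), "none"),
            is_secreted=secreted,
            is_sex_affected=is_sex,
        )))

    truth = pd.concat(truth_rows, ignore_index=True)
    return matrices, truth


def generate_two_tissue(
    n_animals: int,
    n_origin_genes: int,
    n_target_genes: int,
    driver_strength: float,
    seed=None,
    affected_fraction: float = 0.5,
):
    """Two-tissue expression pair with one planted endocrine driver gene.

    The first origin gene correlates (|r| = driver_strength) with
    ``affected_fraction`` of target genes; all other origin-target pairs are
    independent. Sex is a balanced covariate with no planted effect.

    Returns
    -------
    dict with keys ``origin`` (gene x sample DataFrame), ``target``,
    ``sex`` (Series of {"F", "M"}), ``truth`` (dict naming the driver).
    """
    if n_animals < 6:
        raise ValueError("n_animals must be >= 6")
    if driver_strength != 0 and not 0.0 < driver_strength < 1.0:
        raise ValueError("driver_strength must lie in (0, 1) (or be exactly 0)")
    rng = np.random.default_rng(seed)
    origin = rng.standard_normal((n_origin_genes, n_animals))
    target = rng.standard_normal((n_target_genes, n_animals))
    n_aff = int(round(affected_fraction * n_target_genes))
    if driver_strength > 0 and n_aff:
        driver = origin[0]
        driver_std = (driver - driver.mean()) / driver.std()
        idx = rng.choice(n_target_genes, size=n_aff, replace=False)
        target[idx] = (
            driver_strength * driver_std
            + np.sqrt(1.0 - driver_strength**2) * rng.standard_normal((n_aff, n_animals))
        )
    else:
        idx = np.array([], dtype=int)
    animals = [f"A{i:03d}" for i in range(n_animals)]
    sex = pd.Series(
        ["F" if i < n_animals // 2 else "M" for i in range(n_animals)],
        index=animals, name="sex",
    )
    o_ids = [f"OG{i:04d}" for i in range(n_origin_genes)]
    t_ids = [f"TG{i:04d}" for i in range(n_target_genes)]
    return dict(
        origin=pd.DataFrame(origin, index=o_ids, columns=animals),
        target=pd.DataFrame(target, index=t_ids, columns=animals),
        sex=sex,
        truth=dict(driver_gene=o_ids[0], affected_targets=[t_ids[i] for i in idx]),
    )
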