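"""Secreted-factor (exerkine) candidate filtering and endocrine connectivity.

Candidate secreted factors are differentially-regulated transcripts or
proteins that overlap a curated secretome reference (plasma-detected
proteins plus a secreted-protein atlas). Confidence of extracellular
localization is the maximum compartment score over the four
extracellular categories. Endocrine connectivity of an origin-tissue
secretory gene is quantified by the Ssec score: the mean of
-ln(p-value) of its biweight midcorrelations against every gene in a
target tissue (sum normalized by the target gene count); under
independence p-values are uniform so the null normalized Ssec has mean
1. Rank shifts of candidate genes between conditions are compared with
Wilcoxon signed-rank and paired t-tests, and per-gene target-tissue
correlation profiles are tested for pathway enrichment with the
pre-ranked competitive engine.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import SetCollection, camera_pr
from .networks import bicor_matrix

__all__ = ["build_secretome", "extracellular_score", "ssec",
           "rank_shift_test", "gene_correlation_enrichment",
           "EXTRACELLULAR_CATEGORIES"]

EXTRACELLULAR_CATEGORIES = (
    "Extracellular region", "Extracellular space",
    "Extracellular exosome", "Extracellular vesicle",
)


def build_secretome(candidates, plasma_panel, secreted_atlas,
                    compartment_scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Filter differential features to secretome-overlapping candidates.

    The secretome reference is the union of the plasma-detected panel and
    the secreted-protein atlas; candidates are the (deduplicated)
    intersection of the differential gene symbols with that reference.

    Parameters
    ----------
    candidates : iterable of differential transcript/protein gene symbols.
    plasma_panel, secreted_atlas : iterables of gene symbols.
    compartment_scores : optional DataFrame with columns
        (gene, category, score) used to attach extracellular scores.

    Returns
    -------
    DataFrame with columns gene, in_plasma_panel, in_secreted_atlas,
    extracellular_score — one row per unique candidate gene.
    """
    plasma = set(plasma_panel)
    atlas = set(secreted_atlas)
    reference = plasma | atlas
    if not reference:
        raise ValueError("empty secretome reference")
    genes = sorted(set(candidates) & reference)
    rows = []
    for g in genes:
        score = 0.0
        if compartment_scores is not None:
            sub = compartment_scores[compartment_scores["gene"] == g]
            score = extracellular_score(
                dict(zip(sub["category"], sub["score"])))
        rows.append(dict(gene=g, in_plasma_panel=g in plasma,
                         in_secreted_atlas=g in atlas,
                         extracellular_score=score))
    return pd.DataFrame(rows, columns=["gene", "in_plasma_panel",
                                       "in_secreted_atlas",
                                       "extracellular_score"])


def extracellular_score(compartment_rows: dict) -> float:
    """Maximum localization-confidence score over the extracellular categories.

    ``compartment_rows`` maps category name -> score in [0, 5]; categories
    outside the four extracellular ones are ignored; no extracellular
    entry yields 0.
    """
    vals = []
    for cat, score in compartment_rows.items():
        if not 0.0 <= float(score) <= 5.0:
            raise ValueError(f"compartment score {score} outside [0, 5]")
        if cat in EXTRACELLULAR_CATEGORIES:
            vals.append(float(score))
    return max(vals) if vals else 0.0


def ssec(origin: pd.DataFrame, target: pd.DataFrame,
         adjust: pd.Series | None = None, log_base: str = "natural",
         condition: str = "na", target_tissue: str = "target") -> pd.DataFrame:
    """Endocrine-connectivity (Ssec) scores of origin genes against a target tissue.

    For each origin gene g, raw Ssec = sum over target genes j of
    -ln p(bicor(g, j)); normalized Ssec divides by the number of target
    genes. With ``adjust`` (e.g. sex, coded or categorical) both matrices
    are residualized on an intercept + covariate model before
    correlating. Ranks are assigned in decreasing normalized Ssec
    (rank 1 = most connected).

    ``log_base``: "natural" (default) or "10"; the choice rescales all
    scores by a constant and leaves ranks unchanged.
    """
    shared = [s for s in origin.columns if s in set(target.columns)]
    if len(shared) < 6:
        raise ValueError("origin and target must share at least 6 samples")
    O = origin[shared].to_numpy(dtype=float)
    T = target[shared].to_numpy(dtype=float)

    o_keep = O.std(axis=1) > 0
    t_keep = T.std(axis=1) > 0
    n_excluded = int((~o_keep).sum() + (~t_keep).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} constant gene(s) excluded")
    O, T = O[o_keep], T[t_keep]
    o_ids = origin.index[o_keep]

    if adjust is not None:
        a = adjust.loc[shared]
        if a.dtype.kind not in "if":
            a = pd.get_dummies(a, drop_first=True).iloc[:, 0].astype(float)
        X = np.column_stack([np.ones(len(shared)), a.to_numpy(dtype=float)])
        H = X @ np.linalg.pinv(X)
        O = O - O @ H.T
        T = T - T @ H.T

    _, P = bicor_matrix(O, T)
    P = np.clip(P, 1e-300, 1.0)
    raw = -np.log(P).sum(axis=1)
    if log_base == "10":
        raw = raw / np.log(10.0)
    elif log_base != "natural":
        raise ValueError("log_base must be 'natural' or '10'")
    n_target = T.shape[0]
    norm = raw / n_target
    out = pd.DataFrame(dict(
        origin_gene=o_ids, target_tissue=target_tissue, condition=condition,
        ssec_raw=raw, ssec=norm, n_target_genes=n_target,
    ))
    out["rank"] = out["ssec"].rank(ascending=False, method="first").astype(int)
    return out.set_index("origin_gene", drop=False)


def rank_shift_test(ssec_a: pd.DataFrame, ssec_b: pd.DataFrame,
                    candidates) -> dict:
    """Paired tests comparing candidate-gene Ssec ranks between two conditions.

    Returns Wilcoxon signed-rank and paired t p-values plus the per-gene
    rank deltas (condition B minus condition A; negative = moved toward
    rank 1 in B). With fewer than 5 candidates the Wilcoxon test uses the
    exact null distribution.
    """
    candidates = [g for g in candidates]
    missing = [g for g in candidates
               if g not in ssec_a.index or g not in ssec_b.index]
    if missing:
        raise ValueError(f"candidates absent from a table: {missing[:5]}")
    ra = ssec_a.loc[candidates, "rank"].to_numpy(dtype=float)
    rb = ssec_b.loc[candidates, "rank"].to_numpy(dtype=float)
    deltas = rb - ra
    if np.all(deltas == 0.0):
        wil_p = 1.0
    else:
        mode = "exact" if len(candidates) < 5 else "auto"
        wil_p = float(stats.wilcoxon(ra, rb, mode=mode).pvalue)
    if np.allclose(deltas, deltas[0]) and deltas.std() == 0:
        # constant shift: zero variance, the paired t is degenerate
        t_p = 0.0 if deltas[0] != 0 else 1.0
    else:
        t_p = float(stats.ttest_rel(ra, rb).pvalue)
    return dict(
        wilcoxon_p=wil_p, paired_t_p=t_p,
        rank_deltas=pd.Series(deltas, index=candidates, name="rank_delta"),
        mean_delta=float(deltas.mean()),
    )


def gene_correlation_enrichment(origin_gene: pd.Series, target: pd.DataFrame,
                                sets: SetCollection,
                                inter_feature_cor: float = 0.01) -> pd.DataFrame:
    """Pathway enrichment of one origin gene's target-tissue correlation profile.

    The origin gene is biweight-midcorrelated with every target gene, the
    correlation vector is z-scored, and the pre-ranked competitive test is
    applied. If the origin gene itself appears among the target genes its
    self-correlation row is excluded first.
    """
    tgt = target
    if origin_gene.name in tgt.index:
        warnings.warn(f"origin gene {origin_gene.name!r} present in target "
                      "matrix; excluded")
        tgt = tgt.drop(index=origin_gene.name)
    shared = [s for s in tgt.columns if s in origin_gene.index]
    r, _ = bicor_matrix(origin_gene.loc[shared].to_numpy(dtype=float)[None, :],
                        tgt[shared].to_numpy(dtype=float))
    rv = r[0]
    z = (rv - rv.mean()) / rv.std()
    return camera_pr(pd.Series(z, index=tgt.index), sets,
                     inter_feature_cor=inter_feature_cor)
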