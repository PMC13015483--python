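"""Set-based enrichment: competitive pre-ranked testing and over-representation.

One engine serves pathway collections, cell-type marker sets, RefMet
metabolite classes and kinase-substrate sets:

* :func:`camera_pr` — the pre-ranked correlation-adjusted mean-rank
  competitive test on a vector of signed z-scores. For a set of size m in
  a universe of size n it compares the in-set mean against the out-of-set
  mean with a pooled-SD two-sample t statistic whose in-set variance is
  inflated by VIF = 1 + (m-1)*rho, rho the assumed mean inter-feature
  correlation.
* :func:`ora` — upper-tail hypergeometric over-representation of a
  selected feature list.

Sets are filtered to >= 5 members present in the universe; gene-set
collections additionally require >= 70% retention of their original
membership. BH adjustment is applied within a collection; the default
significance threshold is 0.05, raised to 0.1 for kinase collections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["SetCollection", "filter_sets", "camera_pr", "ora"]

#: provenance classes whose significance threshold is 0.1 rather than 0.05
KINASE_PROVENANCES = {"kinase", "ptm_signature"}
#: provenance classes subject to the 70% retention rule (gene sets)
GENE_SET_PROVENANCES = {"pathway", "cell_marker", "kinase", "ptm_signature"}


@dataclass
class SetCollection:
    """A named collection of feature sets with filter state."""

    name: str
    sets: dict = field(default_factory=dict)          # set name -> member list
    provenance: str = "pathway"
    original_sizes: dict = field(default_factory=dict)
    filtered: bool = False
    dropped: dict = field(default_factory=dict)       # set name -> reason

    def __post_init__(self):
        if not self.original_sizes:
            self.original_sizes = {k: len(set(v)) for k, v in self.sets.items()}

    @property
    def alpha(self) -> float:
        return 0.1 if self.provenance in KINASE_PROVENANCES else 0.05


def filter_sets(collection: SetCollection, universe, min_size: int = 5,
                min_retention: float = 0.70,
                apply_retention: bool | None = None) -> SetCollection:
    """Intersect sets with the universe and apply size/retention filters.

    ``apply_retention`` defaults to True for gene-set provenances
    (pathway, cell_marker, kinase, ptm_signature) and False for
    metabolite-class collections.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if apply_retention is None:
        apply_retention = collection.provenance in GENE_SET_PROVENANCES
    kept, dropped = {}, {}
    for name, members in collection.sets.items():
        orig = collection.original_sizes.get(name, len(set(members)))
        present = sorted(set(members) & universe)
        if len(present) < min_size:
            dropped[name] = f"size {len(present)} < {min_size}"
            continue
        if apply_retention and orig > 0 and len(present) / orig < min_retention:
            dropped[name] = (f"retention {len(present)}/{orig} "
                             f"< {min_retention:.0%}")
            continue
        kept[name] = present
    return SetCollection(collection.name, kept, collection.provenance,
                         original_sizes=dict(collection.original_sizes),
                         filtered=True, dropped=dropped)


def camera_pr(z: pd.Series, collection: SetCollection,
              inter_feature_cor: float = 0.01) -> pd.DataFrame:
    """Pre-ranked competitive set test on a z-score vector.

    Parameters
    ----------
    z : Series indexed by identifier (the universe), finite values.
    collection : filtered SetCollection.
    inter_feature_cor : assumed mean correlation rho among in-set
        statistics; variance inflation VIF = 1 + (m-1)*rho. rho=0 recovers
        the classical pooled two-sample t-test.

    Returns
    -------
    DataFrame with columns set, n_members, delta, tstat, p, z_std, adj_p,
    significant. z_std is the signed standard-normal deviate
    sign(delta) * Phi^-1(1 - p/2); positive values indicate upregulation.
    """
    zv = z.to_numpy(dtype=float)
    if not np.all(np.isfinite(zv)):
        raise ValueError("z contains non-finite values")
    n = zv.size
    pos = {g: i for i, g in enumerate(z.index)}
    rows = []
    for name, members in collection.sets.items():
        idx = [pos[g] for g in members if g in pos]
        m = len(idx)
        if m == 0 or m == n:
            warnings.warn(f"set {name!r} is empty or spans the whole universe; "
                          "skipped")
            continue
        in_mask = np.zeros(n, dtype=bool)
        in_mask[idx] = True
        zin, zout = zv[in_mask], zv[~in_mask]
        delta = zin.mean() - zout.mean()
        df = n - 2
        sp2 = ((m - 1) * zin.var(ddof=1) + (n - m - 1) * zout.var(ddof=1)) / df
        vif = 1.0 + (m - 1) * inter_feature_cor
        denom = np.sqrt(sp2) * np.sqrt(vif / m + 1.0 / (n - m))
        if denom == 0:
            t, p = 0.0, 1.0
        else:
            t = delta / denom
            p = 2.0 * stats.t.sf(abs(t), df)
        z_std = float(np.sign(delta) * min(stats.norm.isf(p / 2.0), 38.0)) if p > 0 \
            else float(np.sign(delta) * 38.0)
        if delta == 0:
            z_std = 0.0
        rows.append(dict(set=name, n_members=m, delta=delta, tstat=t, p=p,
                         z_std=z_std))
    res = pd.DataFrame(rows)
    if len(res):
        res["adj_p"] = multipletests(res["p"], method="fdr_bh")[1]
        res["significant"] = res["adj_p"] < collection.alpha
    return res


def ora(selected, universe, collection: SetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` within each set.

    P(overlap >= observed) for drawing len(selected) identifiers from a
    universe of size N containing the set's members. BH within collection.
    """
    universe = set(universe)
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected identifiers must be a subset of the universe")
    N = len(universe)
    n_sel = len(selected)
    rows = []
    for name, members in collection.sets.items():
        mem = set(members) & universe
        K = len(mem)
        if K == 0:
            continue
        k = len(mem & selected)
        p = 1.0 if n_sel == 0 else float(stats.hypergeom.sf(k - 1, N, K, n_sel))
        expected = n_sel * K / N
        rows.append(dict(set=name, n_members=K, overlap=k, expected=expected,
                         enrichment=(k / expected if expected > 0 else np.nan),
                         p=min(p, 1.0)))
    res = pd.DataFrame(rows)
    if len(res):
        res["adj_p"] = multipletests(res["p"], method="fdr_bh")[1]
        res["significant"] = res["adj_p"] < collection.alpha
    return res
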