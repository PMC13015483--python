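"""End-to-end orchestration of the analysis stages on synthetic or user data."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .differential import build_zscore_matrix, run_differential, sex_difference
from .endocrine import ssec
from .enrichment import SetCollection, camera_pr, filter_sets
from .networks import CoexpressionNetwork
from .preprocess import clean_metabolites, filter_low_expression, tmm_log_cpm
from .simeval import SimulationSpec, evaluate_strategies
from .simulate import EffectSpec, generate_cohort, generate_omics, generate_two_tissue
from .trajectories import FuzzyCMeans, stack_and_scale

__all__ = ["DEFAULT_CONFIG", "run"]

STAGES = ("simulate", "preprocess", "da", "simeval", "enrich", "wgcna",
          "fcm", "ssec")

DEFAULT_CONFIG = dict(
    stages=list(STAGES),
    seed=0,
    simulate=dict(n_per_group=dict(EE=20, RE=20, CON=20),
                  n_features_per_ome=400, frac_dd_affected=0.1,
                  dd_effect=1.5, missing_frac=0.05),
    simeval=dict(n_reps=200, strategies=["paired_t", "ols", "lmm_ri"]),
    enrich=dict(n_sets=25, set_size=20),
    wgcna=dict(min_module_size=20),
    fcm=dict(n_clusters=4),
    ssec=dict(n_animals=20, n_origin_genes=100, n_target_genes=200,
              driver_strength=0.8),
)


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()[:16]


def run(config: dict | None = None, outdir: str | Path = "exermap_run") -> dict:
    """Execute the configured stages in dependency order on synthetic data.

    Writes per-stage TSV outputs under ``outdir`` and returns (and writes)
    a manifest recording versions, seeds, and output hashes.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and k in cfg and isinstance(cfg[k], dict):
                cfg[k] = {**cfg[k], **v}
            else:
                cfg[k] = v
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    manifest = dict(version=__version__, seed=seed, stages={}, config=cfg)
    state: dict = {}

    def record(stage, **outputs):
        entry = dict(elapsed_s=round(time.time() - t0, 2))
        for name, obj in outputs.items():
            if isinstance(obj, pd.DataFrame):
                entry[f"{name}_hash"] = _hash_df(obj)
                entry[f"{name}_shape"] = list(obj.shape)
        manifest["stages"][stage] = entry

    def need(stage, key):
        if key not in state:
            raise RuntimeError(f"stage {stage!r} requires output {key!r}; "
                               "run its upstream stage first")
        return state[key]

    if "simulate" in stages:
        t0 = time.time()
        sc = cfg["simulate"]
        design = generate_cohort(sc["n_per_group"], seed=rng.integers(2**31))
        spec = EffectSpec(seed=int(rng.integers(2**31)),
                          **{k: v for k, v in sc.items() if k != "n_per_group"})
        matrices, truth = generate_omics(design, spec)
        io.write_design(design, outdir / "design.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for ome, m in matrices.items():
            io.write_matrix(m, outdir / f"{ome}_raw.tsv")
        state.update(design=design, matrices=matrices, truth=truth)
        record("simulate", design=design, truth=truth)

    if "preprocess" in stages:
        t0 = time.time()
        matrices = need("preprocess", "matrices")
        processed = {}
        for ome, m in matrices.items():
            if ome == "transcript":
                filtered = filter_low_expression(m, rule="conventional")
                processed[ome] = tmm_log_cpm(filtered)
            elif ome == "metabolite":
                raw = 2.0 ** m  # generator emits log-like values
                processed[ome], _ = clean_metabolites(raw)
            else:
                processed[ome] = m
            io.write_matrix(processed[ome], outdir / f"{ome}_processed.tsv")
        state["processed"] = processed
        record("preprocess", **processed)

    if "da" in stages:
        t0 = time.time()
        design = need("da", "design")
        processed = state.get("processed") or need("da", "matrices")
        results = {}
        for ome, m in processed.items():
            res = run_differential(m, design, covariates=("age", "sex", "bmi"),
                                   ome=ome)
            res.to_csv(outdir / f"da_{ome}.tsv", sep="\t", index=False)
            results[ome] = res
        state["da"] = results
        zmats = {ome: build_zscore_matrix(
            r[r["family"] == "difference_in_changes"]) for ome, r in
            results.items() if len(r)}
        state["zmats"] = zmats
        pre = design[design["timepoint"] == "pre"]["sample_id"]
        first = next(iter(processed.values()))
        sexres = sex_difference(first[list(pre)],
                                design.set_index("sample_id")["sex"])
        sexres.to_csv(outdir / "sex_difference.tsv", sep="\t", index=False)
        record("da", **results)

    if "simeval" in stages:
        t0 = time.time()
        sv = cfg["simeval"]
        spec = SimulationSpec(n_reps=int(sv.get("n_reps", 200)),
                              seed=int(rng.integers(2**31)))
        report = evaluate_strategies(spec, strategies=tuple(sv["strategies"]))
        report.to_csv(outdir / "simeval.tsv", sep="\t", index=False)
        state["simeval"] = report
        record("simeval", report=report)

    if "enrich" in stages:
        t0 = time.time()
        zmats = need("enrich", "zmats")
        ec = cfg["enrich"]
        zm = next(iter(zmats.values()))
        col = zm.columns[0]
        z = zm[col].dropna()
        universe = list(z.index)
        sets = {}
        for i in range(int(ec["n_sets"])):
            sets[f"SET_{i:03d}"] = list(
                rng.choice(universe, size=min(int(ec["set_size"]),
                                              len(universe)), replace=False))
        coll = filter_sets(SetCollection("synthetic_pathways", sets,
                                         provenance="pathway"), universe)
        enr = camera_pr(z, coll)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        state["enrich"] = enr
        record("enrich", enr=enr)

    if "wgcna" in stages:
        t0 = time.time()
        design = need("wgcna", "design")
        processed = state.get("processed") or need("wgcna", "matrices")
        ome = "protein" if "protein" in processed else next(iter(processed))
        m = processed[ome]
        pre = [s for s in m.columns
               if design.loc[s, "timepoint"] == "pre"]
        sub = m[pre].dropna(axis=0)
        net = CoexpressionNetwork(**cfg["wgcna"]).fit(sub)
        net.labels_.rename("module").to_frame().to_csv(
            outdir / "modules.tsv", sep="\t")
        net.eigengenes_.to_csv(outdir / "eigengenes.tsv", sep="\t")
        state["wgcna"] = net
        record("wgcna", eigengenes=net.eigengenes_)

    if "fcm" in stages:
        t0 = time.time()
        zmats = need("fcm", "zmats")
        stacked = stack_and_scale([z.fillna(0.0) for z in zmats.values()])
        model = FuzzyCMeans(n_clusters=int(cfg["fcm"]["n_clusters"]),
                            random_state=int(rng.integers(2**31)))
        model.fit(stacked.to_numpy())
        pd.DataFrame(model.membership_, index=stacked.index).to_csv(
            outdir / "fcm_membership.tsv", sep="\t")
        pd.DataFrame(model.cluster_centers_, columns=stacked.columns).to_csv(
            outdir / "fcm_centroids.tsv", sep="\t", index_label="cluster")
        state["fcm"] = model
        record("fcm")

    if "ssec" in stages:
        t0 = time.time()
        sc = cfg["ssec"]
        two = generate_two_tissue(int(sc["n_animals"]),
                                  int(sc["n_origin_genes"]),
                                  int(sc["n_target_genes"]),
                                  float(sc["driver_strength"]),
                                  seed=int(rng.integers(2**31)))
        table = ssec(two["origin"], two["target"], adjust=two["sex"])
        table.to_csv(outdir / "ssec.tsv", sep="\t", index=False)
        state["ssec"] = table
        record("ssec", table=table)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
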