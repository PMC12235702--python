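"""End-to-end orchestration: one config, one output directory, one manifest.

``run_all`` drives every stage in order — simulate (or load) inputs, synergy
scoring, PCA QC, per-contrast differential expression, ORA on the
down-regulated lists and preranked GSEA on the full rankings — and writes a
run manifest recording the package version, the config echo, input file
digests, per-stage row counts and every random seed, so a rerun with the
same config reproduces identical outputs for all deterministic stages.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import dep as dep_mod
from . import enrichment, io, qc, simulate, synergy

__all__ = ["run_all", "load_config", "DEFAULT_CONFIG", "PipelineError"]

logger = logging.getLogger(__name__)

#: All thresholds surfaced as named keys, defaulting to the study's values.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synergy": {"additivity_band": 5.0, "mode": "product"},
    "dep": {
        "p_threshold": 0.05,
        "fc_threshold": 0.58,
        "sd_multiplier": 1.96,
        "normalization": "median_center",
        "test": "student",
    },
    "ora": {"p_threshold": 0.05},
    "gsea": {
        "n_perm": 1000,
        "fdr_threshold": 0.25,
        "p_threshold": 0.05,
        "weight_exponent": 1.0,
        "min_size": 5,
        "max_size": 500,
    },
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and completed stages."""

    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed after {completed}: {cause}")
        self.stage = stage
        self.completed = completed
        self.cause = cause


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_config(user)


def _merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: dict | str, out_dir: str) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    ``config`` is a dict or a YAML path.  It must contain either a
    ``simulate`` block (synthetic inputs are generated into
    ``out_dir/inputs``) or an ``inputs`` block with paths to a
    dose-response matrix, a proteinGroups table, a design table and a GMT
    collection.
    """
    if isinstance(config, (str, os.PathLike)):
        config = load_config(config)
    else:
        config = _merge_config(config)
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("synprot")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "pipeline_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "inputs": {},
        "stages": {},
        "seeds": {"root": config.get("seed", 0)},
    }
    completed: list[str] = []

    def _stage(name):
        def deco(fn):
            def run(*a, **kw):
                logger.info("stage %s: start", name)
                try:
                    out = fn(*a, **kw)
                except Exception as exc:
                    manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                    _write_manifest(manifest, out_dir)
                    root.removeHandler(handler)
                    handler.close()
                    raise PipelineError(name, completed, exc) from exc
                completed.append(name)
                logger.info("stage %s: done", name)
                return out
            return run
        return deco

    seed = int(config.get("seed", 0))

    @_stage("simulate")
    def do_simulate():
        sim_cfg = dict(config["simulate"])
        sim_cfg.setdefault("seed", seed)
        sc = simulate.SynthConfig(**sim_cfg)
        in_dir = os.path.join(out_dir, "inputs")
        os.makedirs(in_dir, exist_ok=True)
        drm, true_delta = simulate.synth_dose_response(sc)
        dr_path = os.path.join(in_dir, "dose_response.csv")
        _write_dose_response(drm, dr_path)
        np.savetxt(os.path.join(in_dir, "true_delta.csv"), true_delta, delimiter=",")
        table, truth = simulate.synth_tmt(sc)
        pg_path = os.path.join(in_dir, "proteinGroups.txt")
        raw = io.ProteinQuantTable(intensities=table.intensities,
                                   gene_symbols=table.gene_symbols)
        io.write_protein_groups(raw, pg_path)
        design = pd.DataFrame({"condition": table.condition, "batch": table.batch})
        design.index.name = "sample"
        design_path = os.path.join(in_dir, "design.csv")
        design.reset_index().to_csv(design_path, index=False)
        truth.to_csv(os.path.join(in_dir, "tmt_truth.csv"))
        sets, set_truth = simulate.synth_gene_sets(sc, truth)
        gmt_path = os.path.join(in_dir, "gene_sets.gmt")
        io.write_gmt(sets, gmt_path)
        set_truth.to_csv(os.path.join(in_dir, "gene_set_truth.csv"), index=False)
        manifest["seeds"]["simulate"] = sc.seed
        manifest["stages"]["simulate"] = {
            "status": "ok", "n_proteins": sc.n_proteins, "n_sets": sc.n_sets,
        }
        return {"dose_response": dr_path, "protein_groups": pg_path,
                "design": design_path, "gene_sets": gmt_path}

    if "simulate" in config:
        inputs = do_simulate()
    elif "inputs" in config:
        inputs = dict(config["inputs"])
    else:
        raise ValueError("config must contain a 'simulate' or an 'inputs' block")

    for key, path in inputs.items():
        if not os.path.exists(path):
            raise FileNotFoundError(f"input {key!r} not found: {path}")
        manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    @_stage("synergy")
    def do_synergy():
        syn_dir = os.path.join(out_dir, "synergy")
        drm = synergy.read_dose_response_csv(inputs["dose_response"])
        params = config["synergy"]
        result = synergy.run_synergy(drm, additivity_band=params["additivity_band"],
                                     mode=params["mode"])
        paths = synergy.write_synergy_tables(result, syn_dir)
        synergy.plot_delta_heatmap(result, os.path.join(syn_dir, "delta_heatmap.png"))
        manifest["stages"]["synergy"] = {
            "status": "ok", "n_cells": int(result.delta.size),
            "additivity_band": params["additivity_band"], "mode": params["mode"],
            "n_synergy": int((result.labels == "synergy").sum()),
            "n_antagonism": int((result.labels == "antagonism").sum()),
        }
        return result

    @_stage("load_tmt")
    def do_load():
        table = io.read_protein_groups(inputs["protein_groups"])
        design = io.read_design(inputs["design"])
        table = table.with_design(design)
        manifest["stages"]["load_tmt"] = {
            "status": "ok", "n_proteins": table.n_proteins,
            "n_samples": len(table.sample_names),
            "filtered_counts": table.filtered_counts,
        }
        return table

    @_stage("normalize")
    def do_normalize(table):
        norm = dep_mod.log2_transform_and_normalize(table,
                                                    config["dep"]["normalization"])
        manifest["stages"]["normalize"] = {"status": "ok",
                                           "method": config["dep"]["normalization"]}
        return norm

    @_stage("qc_pca")
    def do_pca(norm):
        result = qc.pca_samples(norm, n_components=3)
        coords = qc.pca_coordinates_table(result, norm)
        qc_dir = os.path.join(out_dir, "qc")
        io.write_result_csv(coords, os.path.join(qc_dir, "pca_coordinates.csv"),
                            {"variance_explained":
                             [round(float(v), 6) for v in result.variance_explained]},
                            index=True)
        manifest["stages"]["qc_pca"] = {
            "status": "ok",
            "n_proteins_used": result.n_proteins_used,
            "n_proteins_dropped": result.n_proteins_dropped,
            "variance_explained": [float(v) for v in result.variance_explained],
        }
        return result

    @_stage("dep")
    def do_dep(norm):
        dep_dir = os.path.join(out_dir, "dep")
        params = config["dep"]
        results = {}
        counts = {}
        available = set(zip(norm.condition, norm.batch))
        for name, numer, denom, batch in dep_mod.STANDARD_CONTRASTS:
            if (numer, batch) not in available or (denom, batch) not in available:
                logger.info("skipping contrast %s: conditions absent in batch %s",
                            name, batch)
                continue
            spec = dep_mod.ComparisonSpec(name, numer, denom, batch)
            res = dep_mod.compare_groups(norm, spec, params["p_threshold"],
                                         params["fc_threshold"], params["test"])
            results[name] = res
            safe = name.replace("/", "_")
            io.write_result_csv(res.table, os.path.join(dep_dir, f"{safe}.csv"),
                                {"contrast": name, "batch": batch,
                                 "p_threshold": params["p_threshold"],
                                 "fc_threshold": params["fc_threshold"],
                                 "test": params["test"]}, index=True)
            io.write_result_csv(dep_mod.volcano_table(res),
                                os.path.join(dep_dir, f"{safe}_volcano.csv"),
                                {"contrast": name}, index=True)
            up, down = dep_mod.filter_deps(res)
            io.write_gene_list([g for g in up["gene_symbol"] if g],
                               os.path.join(dep_dir, f"{safe}_dep_up.txt"))
            io.write_gene_list([g for g in down["gene_symbol"] if g],
                               os.path.join(dep_dir, f"{safe}_dep_down.txt"))
            counts[name] = {"n_dep": res.n_dep, "n_up": len(up), "n_down": len(down)}
        if not results:
            raise ValueError("no contrast could be computed from the design")
        manifest["stages"]["dep"] = {"status": "ok", "contrasts": counts,
                                     **{k: params[k] for k in
                                        ("p_threshold", "fc_threshold", "test")}}
        return results

    @_stage("ora")
    def do_ora(norm, dep_results):
        ora_dir = os.path.join(out_dir, "ora")
        sets = io.read_gmt(inputs["gene_sets"])
        params = config["ora"]
        sd_mult = config["dep"]["sd_multiplier"]
        summary = {}
        for name, res in dep_results.items():
            tested = res.table[np.isfinite(res.table["p_value"])]
            universe = [g for g in tested["gene_symbol"].unique() if g]
            down = dep_mod.filter_sd_down(res, sd_multiplier=sd_mult,
                                          p_threshold=config["dep"]["p_threshold"])
            query = [g for g in down["gene_symbol"].unique() if g]
            if not query:
                logger.info("ORA %s: empty down-regulated list, skipped", name)
                summary[name] = {"n_query": 0, "n_significant": None}
                continue
            result = enrichment.ora_hypergeometric(query, sets, universe,
                                                   p_threshold=params["p_threshold"])
            safe = name.replace("/", "_")
            io.write_result_csv(result.table, os.path.join(ora_dir, f"{safe}_ora.csv"),
                                {"contrast": name, "sd_multiplier": sd_mult,
                                 "significance": f"nominal_p < {params['p_threshold']}",
                                 "universe_size": result.universe_size,
                                 "query_size": len(query)})
            summary[name] = {"n_query": len(query),
                             "n_significant": int(result.table["significant"].sum())}
        manifest["stages"]["ora"] = {"status": "ok", "contrasts": summary}
        return summary

    @_stage("gsea")
    def do_gsea(dep_results):
        gsea_dir = os.path.join(out_dir, "gsea")
        os.makedirs(gsea_dir, exist_ok=True)
        sets = io.read_gmt(inputs["gene_sets"])
        params = config["gsea"]
        summary = {}
        for i, (name, res) in enumerate(sorted(dep_results.items())):
            tested = res.table[np.isfinite(res.table["log2_fc"])]
            ranked = (pd.DataFrame({"gene": tested["gene_symbol"],
                                    "score": tested["log2_fc"]})
                      .loc[lambda d: d["gene"] != ""]
                      .drop_duplicates("gene", keep="first")
                      .sort_values("score", ascending=False, kind="stable")
                      .reset_index(drop=True))
            safe = name.replace("/", "_")
            io.write_rnk(ranked, os.path.join(gsea_dir, f"{safe}.rnk"))
            contrast_seed = (seed * 1000 + 7 * i) % (2**31 - 1)
            manifest["seeds"][f"gsea:{name}"] = contrast_seed
            result = enrichment.gsea_significance(
                ranked, sets, n_perm=params["n_perm"], seed=contrast_seed,
                weight_exponent=params["weight_exponent"],
                min_size=params["min_size"], max_size=params["max_size"],
                fdr_threshold=params["fdr_threshold"],
                p_threshold=params["p_threshold"])
            io.write_result_csv(result.table, os.path.join(gsea_dir, f"{safe}_gsea.csv"),
                                {"contrast": name, "n_perm": params["n_perm"],
                                 "seed": contrast_seed,
                                 "significance": f"FDR < {params['fdr_threshold']} and "
                                                 f"nominal_p < {params['p_threshold']}"})
            summary[name] = {"n_sets_tested": len(result.table),
                             "n_significant": int(result.table["significant"].sum()),
                             "n_skipped": len(result.skipped)}
        manifest["stages"]["gsea"] = {"status": "ok", "contrasts": summary,
                                      "n_perm": params["n_perm"]}
        return summary

    try:
        if "dose_response" in inputs:
            do_synergy()
        table = do_load()
        norm = do_normalize(table)
        do_pca(norm)
        dep_results = do_dep(norm)
        if "gene_sets" in inputs:
            do_ora(norm, dep_results)
            do_gsea(dep_results)
        _write_manifest(manifest, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return manifest


def _write_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")


def _write_dose_response(drm, path) -> None:
    df = pd.DataFrame(drm.viability, index=list(drm.drug_s_concs),
                      columns=list(drm.drug_p_concs))
    df.to_csv(path, index_label=f"{drm.drug_s_name}/{drm.drug_p_name}")
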