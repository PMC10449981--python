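"""End-to-end orchestration of the cross-trait analysis stages.

``run_pipeline`` executes the enabled stages in dependency order on a
simulated two-trait study —

    simulate -> munge -> ldsc -> gwaspw -> meta -> clump -> mr -> lcv -> genes

— writing one TSV per stage plus a JSON manifest (outputs, parameters,
per-stage wall time, seed).  A single global seed is expanded into per-stage
seeds by a fixed counter scheme (``(seed * 1000003 + stage_index) mod
2^31-1``), so a partial rerun with the same config reproduces every
deterministic output bit for bit.  A stage failure halts its dependents but
independent branches still run; the manifest records per-stage status.

Run from a shell with ``python -m xtrait.pipeline --config cfg.yaml``.
"""

from __future__ import annotations

import argparse
import json
import sys
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clump as clump_mod
from . import genes as genes_mod
from . import gwaspw, lcv, ldsc, meta, mr, simulate, sumstats
from .exceptions import ConfigurationError, XtraitError

STAGES = ["simulate", "munge", "ldsc", "gwaspw", "meta", "clump", "mr",
          "lcv", "genes"]
_DEPS = {
    "munge": ["simulate"], "ldsc": ["munge"], "gwaspw": ["munge"],
    "meta": ["munge"], "clump": ["meta"], "mr": ["munge"], "lcv": ["munge"],
    "genes": ["munge"],
}


@dataclass
class RunConfig:
    """Structured configuration for a pipeline run."""

    out_dir: str
    seed: int = 0
    stages: dict = dc_field(default_factory=dict)   # stage -> bool
    simulate: dict = dc_field(default_factory=dict)
    munge: dict = dc_field(default_factory=dict)
    ldsc: dict = dc_field(default_factory=dict)
    gwaspw: dict = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)
    clump: dict = dc_field(default_factory=dict)
    mr: dict = dc_field(default_factory=dict)
    lcv: dict = dc_field(default_factory=dict)
    genes: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "out_dir" not in raw:
            raise ConfigurationError("config must set out_dir")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1000003 + STAGES.index(stage)) % (2 ** 31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "outputs": {}}
    state: dict = {}
    failed: set = set()

    def _dep_failed(stage):
        return any(d in failed or (config.enabled(d) is False and d in _DEPS)
                   for d in _deps_closure(stage))

    def _deps_closure(stage):
        out = set()
        todo = list(_DEPS.get(stage, []))
        while todo:
            d = todo.pop()
            if d not in out:
                out.add(d)
                todo.extend(_DEPS.get(d, []))
        return out

    for stage in STAGES:
        if not config.enabled(stage):
            manifest["stages"][stage] = {"status": "disabled"}
            continue
        if any(d in failed for d in _deps_closure(stage)):
            manifest["stages"][stage] = {"status": "skipped_dependency"}
            continue
        t0 = time.perf_counter()
        try:
            outputs = _RUNNERS[stage](config, state, out_dir)
            manifest["stages"][stage] = {
                "status": "ok",
                "wall_time_s": round(time.perf_counter() - t0, 3),
                "params": getattr(config, stage, {}),
            }
            manifest["outputs"].update(outputs)
        except XtraitError as e:
            failed.add(stage)
            manifest["stages"][stage] = {
                "status": "error", "error": str(e),
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
    manifest["n_failed"] = len(failed)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# --- stage runners ---------------------------------------------------------

def _run_simulate(cfg: RunConfig, state, out_dir):
    p = {"n_blocks": 60, "block_size": 100, "ar1_rho": 0.9,
         "h2_1": 0.4, "h2_2": 0.4, "rg_true": 0.5, "prop_causal": 0.1,
         "n1": 50_000, "n2": 50_000, "n_s": 0, "rho_pheno": 0.0,
         "genes_per_block": 2, "gene_length": 50_000}
    p.update(cfg.simulate)
    seed = stage_seed(cfg.seed, "simulate")
    panel = simulate.make_panel(p["n_blocks"], p["block_size"], p["ar1_rho"],
                                seed=seed)
    g1, g2, truth = simulate.simulate_pair(
        panel, p["h2_1"], p["h2_2"], p["rg_true"], p["prop_causal"],
        p["n1"], p["n2"], p["n_s"], p["rho_pheno"], seed=seed + 1)
    gene_map = simulate.make_gene_map(panel, p["genes_per_block"],
                                      p["gene_length"])
    state.update(panel=panel, g1=g1, g2=g2, truth=truth, gene_map=gene_map)
    outs = {}
    for name, df in (("trait1_sumstats", g1.df), ("trait2_sumstats", g2.df),
                     ("regions", panel.regions), ("gene_map", gene_map)):
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        outs[name] = str(path)
    return outs


def _run_munge(cfg: RunConfig, state, out_dir):
    p = {"maf_min": 0.0, "exclude_mhc": False, "drop_ambiguous": False}
    p.update(cfg.munge)
    g1 = sumstats.munge(state["g1"], maf_min=p["maf_min"],
                        exclude_mhc=p["exclude_mhc"])
    g2 = sumstats.munge(state["g2"], maf_min=p["maf_min"],
                        exclude_mhc=p["exclude_mhc"])
    g1, g2 = sumstats.harmonize_pair(g1, g2,
                                     drop_ambiguous=p["drop_ambiguous"])
    state.update(m1=g1, m2=g2)
    return {}


def _run_ldsc(cfg: RunConfig, state, out_dir):
    p = {"n_blocks_jk": 200, "constrain_gcov_int": "auto"}
    p.update(cfg.ldsc)
    ld = ldsc.compute_ld_scores(state["panel"])
    est = ldsc.estimate_rg(state["m1"], state["m2"], ld,
                           n_blocks_jk=p["n_blocks_jk"],
                           constrain_gcov_int=p["constrain_gcov_int"])
    state["ld_scores"] = ld
    state["rg"] = est
    df = pd.DataFrame([vars(est)])
    path = out_dir / "rg_estimate.tsv"
    df.to_csv(path, sep="\t", index=False)
    return {"rg_estimate": str(path)}


def _run_gwaspw(cfg: RunConfig, state, out_dir):
    p = {"priors": "em"}
    p.update(cfg.gwaspw)
    df = gwaspw.analyze_regions(state["m1"], state["m2"],
                                state["panel"].regions, priors=p["priors"])
    state["region_ppa"] = df
    path = out_dir / "region_ppa.tsv"
    df.to_csv(path, sep="\t", index=False)
    return {"region_ppa": str(path)}


def _run_meta(cfg: RunConfig, state, out_dir):
    df = meta.meta_analyze_pair(state["m1"], state["m2"], **cfg.meta)
    df = meta.screen_novel_candidates(df)
    state["meta"] = df
    path = out_dir / "meta_results.tsv"
    df.to_csv(path, sep="\t", index=False)
    return {"meta_results": str(path)}


def _run_clump(cfg: RunConfig, state, out_dir):
    p = {"p_max": 5e-8, "r2_max": 0.6, "r2_lead": 0.1}
    p.update(cfg.clump)
    panel = state["panel"]
    ind = clump_mod.independent_significant(
        state["meta"], panel, p_max=p["p_max"], r2_max=p["r2_max"])
    leads = clump_mod.lead_snps(ind, panel, r2_lead=p["r2_lead"])
    known = {
        "trait1": state["m1"].df[state["m1"].df["p"] < 5e-8][
            ["snp_id", "chrom", "pos"]],
        "trait2": state["m2"].df[state["m2"].df["p"] < 5e-8][
            ["snp_id", "chrom", "pos"]],
    }
    leads = clump_mod.classify_novel(leads, known, panel,
                                     gene_map=state["gene_map"])
    df = clump_mod.leads_to_frame(leads)
    state["leads"] = df
    path = out_dir / "lead_snps.tsv"
    df.to_csv(path, sep="\t", index=False)
    return {"lead_snps": str(path)}


def _run_mr(cfg: RunConfig, state, out_dir):
    p = {"prune_r2": 0.05}
    p.update(cfg.mr)
    seed = stage_seed(cfg.seed, "mr")
    rows = []
    for exp_name, (exp, out) in {
        "trait1->trait2": (state["m1"], state["m2"]),
        "trait2->trait1": (state["m2"], state["m1"]),
    }.items():
        try:
            ivset = mr.select_instruments(exp, out, state["panel"],
                                          prune_r2=p["prune_r2"])
            res = mr.mr_all(ivset, seed=seed)
            rows.append(mr.mr_table(res, *exp_name.split("->")))
        except XtraitError as e:
            rows.append(pd.DataFrame([{"exposure": exp_name,
                                       "error": str(e)}]))
    df = pd.concat(rows, ignore_index=True)
    state["mr"] = df
    path = out_dir / "mr_results.tsv"
    df.to_csv(path, sep="\t", index=False)
    return {"mr_results": str(path)}


def _run_lcv(cfg: RunConfig, state, out_dir):
    p = {"n_jk_blocks": 100}
    p.update(cfg.lcv)
    try:
        res = lcv.estimate_gcp(state["m1"], state["m2"],
                               ld=state.get("ld_scores"),
                               n_jk_blocks=p["n_jk_blocks"])
        df = pd.DataFrame([{k: v for k, v in vars(res).items()
                            if k != "warnings"}])
    except XtraitError as e:
        df = pd.DataFrame([{"error": str(e)}])
    path = out_dir / "lcv_result.tsv"
    df.to_csv(path, sep="\t", index=False)
    return {"lcv_result": str(path)}


def _run_genes(cfg: RunConfig, state, out_dir):
    p = {"thresholds": [0.01, 0.05, 0.1]}
    p.update(cfg.genes)
    panel = state["panel"]
    gm = state["gene_map"]
    d1 = genes_mod.gene_analysis(state["m1"], gm, panel)
    d2 = genes_mod.gene_analysis(state["m2"], gm, panel)
    overlaps = []
    for thr in p["thresholds"]:
        try:
            r = genes_mod.overlap_binomial(d1, d2, thr, panel)
            overlaps.append(vars(r))
        except XtraitError as e:
            overlaps.append({"threshold": thr, "error": str(e)})
    m = d1.merge(d2, on="gene_id", suffixes=("_1", "_2"))
    fcp = pd.DataFrame({
        "gene_id": m["gene_id"],
        "p_fcp": genes_mod.fisher_combined(m["p_gates_1"], m["p_gates_2"]),
        "p1": m["p_gates_1"], "p2": m["p_gates_2"],
    })
    me = genes_mod.gec_effective_genes(
        pd.DataFrame({"best_snp_id": m["best_snp_id_1"],
                      "chrom": m["chrom_1"], "pos": m["start_1"]}),
        panel)
    fcp = genes_mod.shared_gene_screen(fcp, max(1.0, me))
    outs = {}
    for name, df in (("gene_results_trait1", d1), ("gene_results_trait2", d2),
                     ("gene_overlap", pd.DataFrame(overlaps)),
                     ("gene_fcp", fcp)):
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        outs[name] = str(path)
    return outs


_RUNNERS = {
    "simulate": _run_simulate, "munge": _run_munge, "ldsc": _run_ldsc,
    "gwaspw": _run_gwaspw, "meta": _run_meta, "clump": _run_clump,
    "mr": _run_mr, "lcv": _run_lcv, "genes": _run_genes,
}


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(
        prog="xtrait-pipeline",
        description="Run the cross-trait analysis pipeline from a YAML config")
    ap.add_argument("--config", required=True)
    args = ap.parse_args(argv)
    manifest = run_pipeline(RunConfig.from_yaml(args.config))
    bad = [s for s, v in manifest["stages"].items()
           if v.get("status") == "error"]
    for s in bad:
        print(f"stage {s} failed: {manifest['stages'][s]['error']}",
              file=sys.stderr)
    return 1 if bad else 0


if __name__ == "__main__":
    raise SystemExit(main())
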