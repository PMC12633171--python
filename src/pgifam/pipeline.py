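"""End-to-end orchestration: simulate -> gwas -> pgi -> impute -> fit ->
hetero -> correct, driven by a YAML config, with a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import atten, famfit, gwas, hetero, imputation, io, scoring, sim

log = logging.getLogger(__name__)

_STAGES = ("simulate", "gwas", "pgi", "impute", "fit", "hetero", "correct")


class ConfigError(ValueError):
    """Config fails schema validation."""


def validate_config(config: dict) -> dict:
    if "seed" not in config:
        raise ConfigError("config must set a global seed")
    stages = config.get("stages", list(_STAGES))
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    for key in ("weights_file",):
        if key in config and not Path(config[key]).exists():
            raise ConfigError(f"missing input file: {config[key]}")
    return {**config, "stages": stages}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages in dependency order.

    Returns (and writes) a manifest recording the seed, per-stage outputs
    and their content hashes.  Stage failure aborts with the partial
    manifest written to disk.
    """
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"seed": seed, "config": config, "stages": {}, "started": time.time()}
    manifest_path = out / "manifest.json"

    def record(stage: str, files: list[Path], extra: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(f): _sha256(f) for f in files},
            **(extra or {}),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    try:
        state: dict = {}
        simcfg = config.get("simulate", {})
        panel = sim.random_panel(
            n_snps=int(simcfg.get("n_snps", 500)),
            seed=seed,
            theta_mode=simcfg.get("theta_mode", "mixed"),
            theta_scale=float(simcfg.get("theta_scale", 0.3)),
        )
        state["panel"] = panel

        if "simulate" in config["stages"]:
            pop_cohort, pop_phen = sim.make_population(
                panel,
                int(simcfg.get("n_gwas", 4000)),
                float(simcfg.get("h2_direct", 0.3)),
                seed + 10,
                spousal_corr=float(simcfg.get("spousal_corr", 0.0)),
            )
            fam_cohort, fam_phen = sim.make_trio_cohort(
                panel,
                int(simcfg.get("n_families", 1000)),
                float(simcfg.get("h2_direct", 0.3)),
                seed + 20,
                n_children=int(simcfg.get("n_children", 1)),
            )
            state.update(
                pop_cohort=pop_cohort, pop_phen=pop_phen,
                fam_cohort=fam_cohort, fam_phen=fam_phen,
            )
            io.write_cohort(fam_cohort, panel, out / "families")
            io.write_tsv(fam_phen, out / "families.phen.tsv")
            record("simulate", [out / "families.dosage.tsv", out / "families.fam.tsv",
                                out / "families.bim.tsv", out / "families.phen.tsv"])

        if "gwas" in config["stages"]:
            ss = gwas.run_population_gwas(
                state["pop_cohort"], state["pop_phen"],
                rows=state["pop_cohort"].rows("proband"),
            )
            ss = atten.filter_by_neff(ss)
            state["sumstats"] = ss
            io.write_sumstats(ss, out / "sumstats.tsv")
            record("gwas", [out / "sumstats.tsv"], {"n_snps": int(ss.n_snps)})

        if "pgi" in config["stages"]:
            if "weights_file" in config:
                weights = io.read_weights(config["weights_file"])
            else:
                weights = gwas.make_weightset(state["sumstats"])
            state["weights"] = weights
            io.write_weights(weights, out / "weights.tsv")
            pgi = scoring.compute_pgi(state["fam_cohort"], weights)
            state["pgi"] = pgi
            io.write_tsv(pgi, out / "pgi.tsv")
            record("pgi", [out / "weights.tsv", out / "pgi.tsv"])

        if "impute" in config["stages"]:
            pgi_imp = imputation.impute_parental_pgi(
                state["fam_cohort"], state["weights"]
            )
            state["pgi_imputed"] = pgi_imp
            io.write_tsv(pgi_imp, out / "pgi_imputed.tsv")
            record("impute", [out / "pgi_imputed.tsv"],
                   {"design_counts": pgi_imp.attrs["design_counts"]})

        if "fit" in config["stages"]:
            pop_pgi = scoring.compute_pgi(state["pop_cohort"], state["weights"])
            psi = famfit.fit_population_association(state["pop_phen"], pop_pgi)
            delta = famfit.fit_causal_effect(state["fam_phen"], state["pgi"])
            ratio = famfit.ratio_with_delta_se(delta, psi)
            z, p = famfit.diff_test(delta, psi)
            results = {
                "psi": asdict(psi), "delta": asdict(delta),
                "ratio": asdict(ratio), "diff_z": z, "diff_p": p,
            }
            state["fit"] = results
            (out / "fit.json").write_text(json.dumps(results, indent=2, default=str))
            record("fit", [out / "fit.json"])

        if "hetero" in config["stages"]:
            het = hetero.fit_interaction(state["fam_phen"], state["pgi"])
            ratio = hetero.subgroup_ratio(het)
            res = {
                "base_effect": het.base_effect,
                "interaction": het.interaction,
                "ratio": asdict(ratio),
            }
            (out / "hetero.json").write_text(json.dumps(res, indent=2))
            record("hetero", [out / "hetero.json"])

        if "correct" in config["stages"]:
            rows = config.get("correct", {}).get("rows")
            reports = atten.table3_report(rows)
            txt = atten.render_report(reports)
            (out / "attenuation.txt").write_text(txt + "\n")
            io.write_tsv(
                pd.DataFrame([asdict(r) for r in reports]), out / "attenuation.tsv"
            )
            record("correct", [out / "attenuation.txt", out / "attenuation.tsv"])

        manifest["status"] = "ok"
    except Exception as exc:  # abort with partial manifest
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["finished"] = time.time()
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
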