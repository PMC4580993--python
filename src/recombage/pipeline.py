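"""Pipeline orchestration: run the analysis stages in dependency order
from a single configuration, with manifests and a plain-text report.

Stages: simulate -> filter -> counts -> lmm -> meta -> fit -> ppc ->
calibrate -> report. Every stage writes its outputs under the configured
output directory together with a manifest recording the stage name, the
seed, the package version, and SHA-256 checksums of the input files it
consumed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .calls import (
    aggregate_counts,
    binned_age_summary,
    filter_double_crossovers,
    threshold_calls,
)
from .checking import posterior_predictive_check, simulation_based_calibration
from .hierarchical import HierarchicalCrossoverModel, ModelSpec
from .lmm import fit_all_cohorts, fits_to_frame, meta_fixed_effects
from .simulate import (
    default_cohort_specs,
    default_generative_params,
    simulate_call_table,
    simulate_cohorts,
)

ALL_STAGES = ("simulate", "filter", "counts", "lmm", "meta", "fit", "ppc",
              "calibrate", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "outdir": "recombage_out",
    "seed": 0,
    "stages": list(ALL_STAGES),
    "simulate": {"scale": 0.25, "model_family": "negative_binomial",
                 "artifact_rate": 0.1, "low_conf_rate": 0.05},
    "filter": {"prob_threshold": 0.5, "double_crossover": True},
    "exclusions": {"min_meioses": 20},
    "models": [{"model_id": "M2star", "parent_sex": "F"}],
    "mcmc": {"n_chains": 4, "n_draws": 2000},
    "ppc": {"n_replicates": 200, "mode": "map_draw"},
    "calibrate": {"n_sims": 20, "levels": [0.9, 0.95], "n_chains": 2,
                  "n_draws": 1000},
    "inputs": {},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, inputs: list[Path],
                    outputs: list[Path], seed: int) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in order; returns artifact paths.

    Fails before running anything if a configured input file is missing;
    a stage failure raises :class:`PipelineError` naming the stage, with
    earlier outputs left in place.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    stages = [s for s in ALL_STAGES if s in set(cfg["stages"])]
    for name, p in (cfg.get("inputs") or {}).items():
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input {name!r} missing: {p}")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: dict = {"outdir": str(outdir)}
    state: dict = {}

    for stage in stages:
        try:
            _run_stage(stage, cfg, outdir, seed, state, artifacts)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise tagged with stage
            raise PipelineError(stage, str(exc)) from exc
    return artifacts


def _run_stage(stage, cfg, outdir: Path, seed: int, state: dict, artifacts: dict):
    if stage == "simulate":
        sc = cfg["simulate"]
        specs = default_cohort_specs(scale=float(sc.get("scale", 0.25)))
        params = default_generative_params(specs, model_family=sc["model_family"])
        meioses, truth = simulate_cohorts(specs, params, seed=seed)
        x_map = {s.cohort_id: int(s.snps_per_mb) for s in specs}
        calls, audit = simulate_call_table(
            meioses, truth, artifact_rate=float(sc.get("artifact_rate", 0.0)),
            low_conf_rate=float(sc.get("low_conf_rate", 0.0)),
            seed=seed, x_snps_by_cohort=x_map,
        )
        io.write_meiosis_table(meioses, outdir / "meioses_true.tsv")
        io.write_call_table(calls, outdir / "calls_raw.tsv")
        audit.to_csv(outdir / "injected_artifacts.tsv", sep="\t", index=False)
        io.write_fam(meioses, outdir / "pedigree.fam", outdir / "pedigree_ages.tsv")
        with open(outdir / "x_snps.json", "w") as fh:
            json.dump(x_map, fh, indent=2, sort_keys=True)
        state.update(calls=calls, meioses_template=meioses, x_map=x_map)
        _write_manifest(outdir, stage, [],
                        [outdir / "meioses_true.tsv", outdir / "calls_raw.tsv"], seed)
        artifacts["calls"] = str(outdir / "calls_raw.tsv")

    elif stage == "filter":
        inputs = []
        if "calls" not in state:
            p = Path(cfg["inputs"]["calls"])
            state["calls"] = io.read_call_table(p)
            inputs.append(p)
            with open(cfg["inputs"]["x_snps"]) as fh:
                state["x_map"] = json.load(fh)
            inputs.append(Path(cfg["inputs"]["x_snps"]))
        calls = state["calls"]
        n0 = len(calls)
        kept = threshold_calls(calls, float(cfg["filter"]["prob_threshold"]))
        low = calls[~calls.index.isin(kept.index)].assign(reason="low_prob")
        if cfg["filter"].get("double_crossover", True):
            kept, tight = filter_double_crossovers(kept, state["x_map"])
        else:
            tight = kept.iloc[0:0].assign(reason=pd.Series(dtype=str))
        audit = pd.concat([low, tight], ignore_index=True)
        io.write_call_table(kept, outdir / "calls_filtered.tsv")
        audit.to_csv(outdir / "filter_audit.tsv", sep="\t", index=False)
        state["calls_filtered"] = kept
        state["filter_log"] = {"in": n0, "after_threshold": n0 - len(low),
                               "after_double_crossover": len(kept)}
        _write_manifest(outdir, stage, inputs,
                        [outdir / "calls_filtered.tsv", outdir / "filter_audit.tsv"], seed)
        artifacts["calls_filtered"] = str(outdir / "calls_filtered.tsv")

    elif stage == "counts":
        inputs = []
        if "meioses_template" not in state:
            p = Path(cfg["inputs"]["meioses"])
            state["meioses_template"] = io.read_meiosis_table(p)
            inputs.append(p)
        counts = aggregate_counts(state["calls_filtered"], state["meioses_template"])
        io.write_meiosis_table(counts, outdir / "meiosis_counts.tsv")
        binned = binned_age_summary(counts)
        binned.to_csv(outdir / "binned_age_summary.tsv", sep="\t", index=False)
        state["counts"] = counts
        _write_manifest(outdir, stage, inputs, [outdir / "meiosis_counts.tsv"], seed)
        artifacts["counts"] = str(outdir / "meiosis_counts.tsv")

    elif stage == "lmm":
        counts = _need_counts(cfg, state)
        from .simulate import FULLY_INFORMATIVE_CONFIGS

        fully = counts[counts["configuration"].isin(FULLY_INFORMATIVE_CONFIGS)]
        fits = fit_all_cohorts(fully, min_meioses=int(cfg["exclusions"]["min_meioses"]))
        if not fits:
            raise ValueError("no cohort passed the LMM meiosis threshold")
        fits_to_frame(fits).to_csv(outdir / "lmm_fits.tsv", sep="\t", index=False)
        state["lmm_fits"] = fits
        _write_manifest(outdir, stage, [], [outdir / "lmm_fits.tsv"], seed)

    elif stage == "meta":
        meta = meta_fixed_effects(state["lmm_fits"])
        with open(outdir / "meta_result.json", "w") as fh:
            json.dump(meta.__dict__, fh, indent=2, sort_keys=True)
        state["meta"] = meta
        _write_manifest(outdir, stage, [], [outdir / "meta_result.json"], seed)

    elif stage == "fit":
        counts = _need_counts(cfg, state)
        mcmc = cfg["mcmc"]
        state["results"] = {}
        summaries = []
        for mdl in cfg["models"]:
            spec = ModelSpec(mdl["model_id"], mdl.get("parent_sex", "F"))
            model = HierarchicalCrossoverModel(
                counts, spec, min_meioses=int(cfg["exclusions"]["min_meioses"]))
            res = model.fit(n_chains=int(mcmc["n_chains"]),
                            n_draws=int(mcmc["n_draws"]), seed=seed)
            key = f"{spec.model_id}_{spec.parent_sex}"
            state["results"][key] = res
            beta = "beta_age" if spec.age_effect == "common" else "beta_age_global"
            row = res.summary_row(beta)
            row["model"] = spec.model_id
            row["parent_sex"] = spec.parent_sex
            summaries.append(row)
            res.to_tidy_frame().to_csv(outdir / f"draws_{key}.tsv", sep="\t",
                                       index=False)
        pd.DataFrame(summaries).to_csv(outdir / "posterior_summaries.tsv",
                                       sep="\t", index=False)
        _write_manifest(outdir, stage, [], [outdir / "posterior_summaries.tsv"], seed)

    elif stage == "ppc":
        pc = cfg["ppc"]
        frames = []
        for key, res in state["results"].items():
            ppc = posterior_predictive_check(
                res, n_replicates=int(pc["n_replicates"]), mode=pc["mode"],
                seed=seed)
            frame = ppc.stats_frame()
            frame["model"] = key
            frames.append(frame)
            state.setdefault("ppc", {})[key] = ppc
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "ppc_stats.tsv", sep="\t", index=False)
        _write_manifest(outdir, stage, [], [outdir / "ppc_stats.tsv"], seed)

    elif stage == "calibrate":
        counts = _need_counts(cfg, state)
        cal_cfg = cfg["calibrate"]
        spec = ModelSpec("M1", "F")
        template = HierarchicalCrossoverModel(
            counts, spec, min_meioses=int(cfg["exclusions"]["min_meioses"]))
        cal = simulation_based_calibration(
            template, n_sims=int(cal_cfg["n_sims"]),
            levels=tuple(cal_cfg["levels"]), seed=seed,
            n_chains=int(cal_cfg["n_chains"]), n_draws=int(cal_cfg["n_draws"]))
        cal.table.to_csv(outdir / "calibration.tsv", sep="\t", index=False)
        state["calibration"] = cal
        _write_manifest(outdir, stage, [], [outdir / "calibration.tsv"], seed)

    elif stage == "report":
        _write_report(cfg, outdir, seed, state)
        _write_manifest(outdir, stage, [], [outdir / "report.md"], seed)
        artifacts["report"] = str(outdir / "report.md")


def _need_counts(cfg, state) -> pd.DataFrame:
    if "counts" not in state:
        state["counts"] = io.read_meiosis_table(cfg["inputs"]["counts"])
    return state["counts"]


def make_table2(summaries: dict[tuple[str, str], pd.Series]) -> pd.DataFrame:
    """Posterior-summary table: one row per (parent, model).

    ``summaries`` maps (parent_sex, model_id) -> a summary row (quantiles
    and Pr(beta_age > 0)); multiplicative models are expected to pass
    exp(beta_age) quantiles, as produced by ``summary_row``.
    """
    if not summaries:
        raise ValueError("no posterior summaries supplied")
    rows = []
    for (parent, model_id), row in summaries.items():
        out = {"parent": "Maternal" if parent == "F" else "Paternal",
               "model": model_id}
        out.update({k: float(v) for k, v in row.items()})
        rows.append(out)
    return pd.DataFrame(rows)


def _write_report(cfg, outdir: Path, seed: int, state: dict) -> None:
    lines = [f"# recombage report (seed {seed}, version {__version__})", ""]
    if "filter_log" in state:
        log = state["filter_log"]
        lines += ["## Call filtering", "",
                  f"- calls in: {log['in']}",
                  f"- after P>{cfg['filter']['prob_threshold']} threshold: "
                  f"{log['after_threshold']}",
                  f"- after double-crossover filter: {log['after_double_crossover']}",
                  ""]
    if "counts" in state:
        counts = state["counts"]
        lines += ["## Binned parental-age means (vs 20-25y reference)", "",
                  binned_age_summary(counts).to_string(index=False), ""]
    if "meta" in state:
        m = state["meta"]
        lines += ["## Fixed-effects meta-analysis of per-cohort LMM slopes", "",
                  f"- beta_age = {m.beta_combined:.4f} (se {m.se_combined:.4f}, "
                  f"z = {m.z:.2f}, p = {m.p_value:.3g})",
                  f"- Cochran's Q = {m.cochran_q:.2f} on {m.q_df} df "
                  f"(p = {m.q_p_value:.3g})", ""]
    if state.get("results"):
        summaries = {}
        for key, res in state["results"].items():
            model_id, sex = key.rsplit("_", 1)
            beta = ("beta_age" if res.spec.age_effect == "common"
                    else "beta_age_global")
            summaries[(sex, model_id)] = res.summary_row(beta)
        lines += ["## Posterior summaries for the age effect", "",
                  make_table2(summaries).to_string(index=False), ""]
    if "ppc" in state:
        lines += ["## Posterior predictive checks", ""]
        for key, ppc in state["ppc"].items():
            lines += [f"### {key}", "", ppc.stats_frame().to_string(index=False), ""]
    if "calibration" in state:
        lines += ["## Calibration (prior-draw simulate-and-refit)", "",
                  state["calibration"].table.to_string(index=False), ""]
    (outdir / "report.md").write_text("\n".join(lines))
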