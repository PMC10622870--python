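"""End-to-end driver: simulate -> filter -> SDT/CBF -> ordinal BF -> DDM -> report.

Experiment presets live as YAML files shipped with the package; every
study constant (reference length, jitter range, penalty values, base-rate
ratio, trial counts, staircase schedule, fixation timings) sits in those
files rather than in code.  All stages are seeded from a single master
seed and the analysis report records seeds, config hash and package
version, so a run is reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bayes, sdt
from .ddm import (
    DDMModelSpec,
    MCMCConfig,
    convergence_report,
    filter_contaminants,
    fit_hierarchical,
    posterior_predictive,
)
from .io import write_trials
from .staircase import StaircaseConfig
from .synth import (
    DesignSpec,
    ObserverDDM,
    generate_dataset,
    make_sdt_cohort,
    payoff_scheme_for,
    study_design,
)

logger = logging.getLogger(__name__)

PRESETS = ("reproduction_experiment", "ddm_experiment_1",
           "ddm_experiment_2", "ddm_experiment_3")

REPORT_SCHEMA = {
    "required": {
        "package_version": str,
        "config_hash": str,
        "master_seed": int,
        "stages": dict,
    },
    "stage_required": {"status": str},
}


def load_preset(name: str, overrides: dict | None = None) -> dict:
    """Load a named experiment preset, optionally overriding top-level keys."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    text = resources.files("biasdissect.presets").joinpath(f"{name}.yaml").read_text()
    cfg = yaml.safe_load(text)
    if overrides:
        cfg = {**cfg, **overrides}
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    for key in ("name", "observer_model", "reference_px", "staircase", "groups"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    if cfg["observer_model"] not in ("sdt", "ddm"):
        raise ValueError("observer_model must be 'sdt' or 'ddm'")
    for g in cfg["groups"]:
        if "bias_source" not in g or "n_subjects" not in g:
            raise ValueError("each group needs bias_source and n_subjects")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _staircase_cfg(cfg: dict) -> StaircaseConfig:
    s = cfg["staircase"]
    return StaircaseConfig(start_step=s["start_step"],
                           n_reversals_total=s["n_reversals_total"],
                           n_reversals_used=s["n_reversals_used"],
                           target_rate=s["target_rate"])


def _ddm_observers(cfg: dict, groups: list[dict], n: int, rng) -> list[ObserverDDM]:
    """Observers whose z/dc maps span all the groups they will be run on."""
    base = cfg.get("ddm_group", {})
    sds = {"a": 0.1, "v": 0.1, "t0": 0.02, "z": 0.02, "dc": 0.05}
    out = []
    for _ in range(n):
        z_map: dict = {}
        dc_map: dict = {}
        for g in groups:
            src = g["bias_source"]
            arrows = g.get("arrowhead_px")
            arrows = arrows if isinstance(arrows, list) else [arrows]
            dcs = g.get("dc_contrast", 0.0)
            zs = g.get("z_contrast", 0.0)
            dcs = dcs if isinstance(dcs, list) else [dcs] * len(arrows)
            zs = zs if isinstance(zs, list) else [zs] * len(arrows)
            for arrow, dcc, zc in zip(arrows, dcs, zs):
                dz = rng.normal(zc / 2.0, sds["z"])
                ddc = rng.normal(dcc / 2.0, sds["dc"])
                for direction, sgn in (("long", 1.0), ("short", -1.0)):
                    key = (src, direction) if arrow is None else (src, direction, float(arrow))
                    z_map[key] = float(np.clip(0.5 + sgn * dz, 0.05, 0.95))
                    dc_map[key] = sgn * ddc
        out.append(ObserverDDM(
            a=max(0.5, rng.normal(base.get("a", 2.0), sds["a"])),
            v=rng.normal(base.get("v", 1.0), sds["v"]),
            t0=max(0.1, rng.normal(base.get("t0", 0.3), sds["t0"])),
            sv=base.get("sv", 0.0),
            z_map=z_map, dc_map=dc_map))
    return out


def _group_designs(cfg: dict, g: dict) -> list[DesignSpec]:
    jitter = tuple(cfg["jitter_px"]) if cfg.get("jitter_px") else None
    n_trials = cfg.get("trials_per_block", cfg.get("trials_per_cell", 300))
    task_mix = cfg.get("task_mix", 0.0)
    arrows = g.get("arrowhead_px")
    arrows = arrows if isinstance(arrows, list) else [arrows]
    designs = []
    block = 0
    for direction in ("short", "long"):
        for arrow in arrows:
            kwargs = dict(n_trials=n_trials, task_mix=task_mix,
                          jitter_px=jitter, block_index=block)
            if arrow is not None:
                kwargs["arrowhead_px"] = float(arrow)
            src = g["bias_source"]
            if src == "base_rate":
                kwargs["base_rate_ratio"] = cfg.get("base_rate_ratio", 3.0)
            if src == "payoff":
                kwargs["payoff_scheme"] = payoff_scheme_for(
                    direction, tuple(cfg.get("payoff_penalties", (5, 1))))
            designs.append(study_design(src, direction, **kwargs))
            block += 1
    return designs


def simulate_experiment(cfg: dict, seed: int = 0) -> pd.DataFrame:
    """Generate the full synthetic experiment a preset describes."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    stair = _staircase_cfg(cfg)
    frames = []
    offset = 0
    groups = cfg["groups"]
    within = cfg.get("within_subject", False)
    bundles: list[list[dict]]
    if cfg["observer_model"] == "ddm" and within:
        shared = [g for g in groups if not g.get("separate_group")]
        bundles = [shared] + [[g] for g in groups if g.get("separate_group")]
    else:
        bundles = [[g] for g in groups]
    for i, bundle in enumerate(bundles):
        n = bundle[0]["n_subjects"]
        designs = [d for g in bundle for d in _group_designs(cfg, g)]
        if cfg["observer_model"] == "sdt":
            obs_cfg = cfg.get("observer", {})
            observers = make_sdt_cohort(n, bundle[0]["bias_source"],
                                        seed=rng.integers(2**31 - 1), **obs_cfg)
            table = generate_dataset(designs, observers, seed=int(rng.integers(2**31 - 1)),
                                     reference_px=cfg["reference_px"], staircase_cfg=stair)
        else:
            observers = _ddm_observers(cfg, bundle, n, rng)
            table = generate_dataset(designs, observers, seed=int(rng.integers(2**31 - 1)),
                                     reference_px=cfg["reference_px"], staircase_cfg=stair)
        table["subject_id"] = table["subject_id"] + offset
        offset += n
        frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = seed
    out.attrs["config"] = cfg
    return out


def run_simulate(cfg: dict, seed: int, outdir) -> Path:
    """Simulate a preset and write trials.csv plus a metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = simulate_experiment(cfg, seed)
    path = outdir / "trials.csv"
    write_trials(table, path, metadata={
        "package_version": __version__, "config": cfg,
        "config_hash": config_hash(cfg), "master_seed": seed,
    })
    return path


def subject_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject d', criterion and (where present) mean reproduction error."""
    table = sdt.sdt_table(trials)
    per_subj = table.groupby("subject_id")[["d_prime", "criterion"]].mean().reset_index()
    if (trials["task"] == "reproduction").any():
        rep = sdt.reproduction_error(trials)
        rep = rep.groupby("subject_id")["reproduction_error_px"].mean().reset_index()
        per_subj = per_subj.merge(rep, on="subject_id", how="left")
    return per_subj


def analyze_effects(trials: pd.DataFrame, seed: int = 0) -> dict:
    """Long-minus-short effects per bias source plus the BF model comparison."""
    table = sdt.sdt_table(trials)
    out: dict = {"effects": {}}
    frames = {}
    for measure, per_cell in (("criterion", table),):
        diffs = {}
        for src, g in per_cell.groupby("bias_source"):
            eff = sdt.long_minus_short(g, measure)
            diffs[src] = eff.differences.to_numpy()
            out["effects"][f"{measure}:{src}"] = {
                "mean": eff.mean, "cohens_d": eff.cohens_d, "n": eff.n,
                "bf10": bayes.jzs_paired_bf(eff.differences.to_numpy()),
            }
        frames[measure] = diffs
    if (trials["task"] == "reproduction").any():
        rep = sdt.reproduction_error(trials)
        diffs = {}
        for src, g in rep.groupby("bias_source"):
            eff = sdt.long_minus_short(g, "reproduction_error_px")
            diffs[src] = eff.differences.to_numpy()
            out["effects"][f"reproduction:{src}"] = {
                "mean": eff.mean, "cohens_d": eff.cohens_d, "n": eff.n,
                "bf10": bayes.jzs_paired_bf(eff.differences.to_numpy()),
            }
        frames["reproduction"] = diffs
    out["model_comparison"] = {}
    for measure, diffs in frames.items():
        if len(diffs) < 2:
            continue
        data = bayes.EffectData(diffs)
        specs = bayes.preset_models(tuple(diffs)).values()
        comp = bayes.compare_models(list(specs), data, seed=seed)
        out["model_comparison"][measure] = comp.to_dict(orient="records")
    return out


def run_analyze(trials: pd.DataFrame, outdir, seed: int = 0,
                mcmc: MCMCConfig | None = None, ddm_spec: DDMModelSpec | None = None,
                n_ppc: int = 100, cfg: dict | None = None) -> dict:
    """Run the full analysis chain, skipping downstream stages on failure.

    Writes tidy CSV tables and a machine-readable ``report.json`` into
    ``outdir``; the returned dict is the report.  DDM stages run only when
    RTs are present.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "config_hash": config_hash(cfg or {}),
        "master_seed": int(seed),
        "stages": {},
    }

    def stage(name, fn, *deps):
        t0 = time.time()
        for d in deps:
            if report["stages"].get(d, {}).get("status") != "ok":
                report["stages"][name] = {"status": "skipped",
                                          "reason": f"upstream stage {d!r} not ok"}
                logger.info("stage %s skipped (%s not ok)", name, d)
                return None
        try:
            result = fn()
            report["stages"][name] = {"status": "ok",
                                      "wall_time_s": round(time.time() - t0, 3),
                                      "seed": int(seed)}
            logger.info("stage %s ok (%.2fs)", name, time.time() - t0)
            return result
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            report["stages"][name] = {"status": "failed", "reason": str(exc)}
            logger.warning("stage %s failed: %s", name, exc)
            return None

    def do_exclusion():
        summ = subject_summaries(trials)
        retained, log = sdt.exclusion_filter(summ)
        (outdir / "exclusions.json").write_text(json.dumps(log, indent=2, default=str))
        return trials[trials["subject_id"].isin(retained["subject_id"])]

    kept = stage("exclusion", do_exclusion)
    data = kept if kept is not None else trials

    def do_sdt():
        table = sdt.sdt_table(data)
        table.to_csv(outdir / "sdt_summary.csv", index=False)
        return table

    stage("sdt", do_sdt, "exclusion")

    def do_effects():
        res = analyze_effects(data, seed=seed)
        pd.DataFrame([{"effect": k, **v} for k, v in res["effects"].items()]
                     ).to_csv(outdir / "effects.csv", index=False)
        for measure, rows in res["model_comparison"].items():
            pd.DataFrame(rows).to_csv(outdir / f"model_comparison_{measure}.csv", index=False)
        return res

    res = stage("effects", do_effects, "sdt")
    if res:
        report["effects"] = res["effects"]
        report["model_comparison"] = res["model_comparison"]

    has_rt = data["rt_s"].notna().any()
    if not has_rt:
        for name in ("rt_filter", "cbf", "ddm_fit", "ppc"):
            report["stages"][name] = {"status": "skipped", "reason": "no reaction times in data"}
    else:
        def do_filter():
            dec = data[data["task"] == "decision"]
            kept_rt, log = filter_contaminants(dec)
            (outdir / "rt_filter.json").write_text(json.dumps(log, indent=2))
            return kept_rt

        dec = stage("rt_filter", do_filter, "exclusion")

        def do_cbf():
            cbf = sdt.conditional_bias_function(dec)
            cbf.to_csv(outdir / "conditional_bias.csv", index=False)
            return cbf

        stage("cbf", do_cbf, "rt_filter")

        def do_fit():
            fit = fit_hierarchical(dec, ddm_spec or DDMModelSpec(),
                                   mcmc or MCMCConfig(seed=seed))
            conv = convergence_report(fit.chains)
            summary = pd.DataFrame({
                "parameter": list(fit.chains.group_names),
                "mean": [fit.chains.flat(p).mean() for p in fit.chains.group_names],
                "sd": [fit.chains.flat(p).std() for p in fit.chains.group_names],
                "rhat": [conv.rhat[p] for p in fit.chains.group_names],
            })
            summary.to_csv(outdir / "ddm_posterior_summary.csv", index=False)
            (outdir / "ddm_convergence.json").write_text(json.dumps({
                "max_rhat": conv.max_rhat, "flagged": conv.flagged,
                "threshold": conv.threshold}, indent=2))
            np.savez_compressed(outdir / "ddm_chains.npz", **fit.chains.params)
            report["ddm_max_rhat"] = conv.max_rhat
            return fit

        fit = stage("ddm_fit", do_fit, "rt_filter")

        def do_ppc():
            ppc = posterior_predictive(fit, dec, n_sims=n_ppc, seed=seed)
            ppc.to_csv(outdir / "ppc.csv", index=False)
            return ppc

        stage("ppc", do_ppc, "ddm_fit")

    validate_report(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def validate_report(report: dict) -> None:
    """Check the report against the bundled schema; raises on violation."""
    for key, typ in REPORT_SCHEMA["required"].items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    for name, st in report["stages"].items():
        for key in REPORT_SCHEMA["stage_required"]:
            if key not in st:
                raise ValueError(f"stage {name!r} missing {key!r}")
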