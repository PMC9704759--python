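"""Configuration, CSV/JSON dialects, and the end-to-end pipeline.

The tidy CSV dialect has columns
``arm_id, phase{pre|post}, t_after_awakening_h, variable{SBP|DBP|C|Cm},
mean, se`` plus an optional ``ta_h`` column; when ``ta_h`` is absent the
dosing time of each post-treatment arm is taken from the run configuration's
``arms`` map.  Times are decimal hours after awakening; hh:mm strings appear
only in human-facing window reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import ClockConvention, InvalidParameterError
from .chrono import optimal_ta, scan_ta
from .fitting import ArmDataset, FitResult, fill_missing_se
from .pkpd import DrugConstants

log = logging.getLogger("chronopkpd")

CSV_COLUMNS = ["arm_id", "phase", "t_after_awakening_h", "variable",
               "mean", "se"]


def write_dataset(path, pre: ArmDataset | None, post: list[ArmDataset]):
    """Write pre/post arm datasets in the tidy CSV dialect (with ta_h)."""
    frames = []
    for phase, arms in (("pre", [pre] if pre is not None else []),
                        ("post", post)):
        for arm in arms:
            f = arm.observations.rename(columns={"t": "t_after_awakening_h"})
            f = f[["t_after_awakening_h", "variable", "mean", "se"]].copy()
            f.insert(0, "phase", phase)
            f.insert(0, "arm_id", arm.arm_id)
            f["ta_h"] = arm.ta
            frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dataset(path, ta_map: dict[str, float] | None = None,
                 se_fallback_frac: float = 0.02):
    """Read the tidy CSV dialect back into (pre_arms, post_arms).

    Missing/zero SEs are filled with ``se_fallback_frac`` of the mean (the
    summary-data convention).  Arm dosing times come from ``ta_h`` when
    present, else from ``ta_map``.
    """
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"dataset missing columns {missing}")
    pre, post = [], []
    for (arm_id, phase), g in df.groupby(["arm_id", "phase"], sort=False):
        if "ta_h" in g.columns and g["ta_h"].notna().all():
            ta = float(g["ta_h"].iloc[0])
        elif ta_map and arm_id in ta_map:
            ta = float(ta_map[arm_id])
        elif phase == "pre":
            ta = 0.0
        else:
            raise InvalidParameterError(
                f"no dosing time for arm {arm_id!r}: add ta_h or config arms")
        obs = g.rename(columns={"t_after_awakening_h": "t"})[
            ["variable", "t", "mean", "se"]].reset_index(drop=True)
        obs = fill_missing_se(obs, se_fallback_frac)
        arm = ArmDataset(arm_id=str(arm_id), ta=ta, observations=obs)
        (pre if phase == "pre" else post).append(arm)
    return pre, post


def fit_result_to_dict(r: FitResult) -> dict:
    return {
        "variant": {"circadian_set": sorted(r.variant.circadian_set),
                    "hill_free": r.variant.hill_free, "kind": r.variant.kind},
        "param_values": r.param_values,
        "Fobj": r.Fobj, "LogL": r.LogL, "AICc": r.AICc, "BIC": r.BIC,
        "n_pars": r.n_pars, "N_tot": r.N_tot,
        "converged": r.converged, "seed": r.seed,
        "model": r.params.to_dict(),
    }


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline configuration.

    The drug block carries literature constants (dose in mg in the file,
    converted once to ug on load); ``arms`` maps arm ids to dosing times in
    hours after awakening.
    """

    drug_name: str
    kind: str
    drug: DrugConstants
    arms: dict[str, float]
    clock: ClockConvention = field(default_factory=ClockConvention)
    seed: int = 0
    n_starts: int = 50
    grid_step: float = 0.25
    target_sbp: float = 130.0
    target_dbp: float = 80.0
    synth: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)

    d = raw.get("drug")
    if not d:
        raise InvalidParameterError("config needs a 'drug' block")
    kind = d.get("kind", "nonprodrug")
    if "dose_mg" in d:
        dose_ug = float(d["dose_mg"]) * 1000.0
        log.info("converted dose %.3g mg -> %.6g ug", d["dose_mg"], dose_ug)
    elif "dose_ug" in d:
        dose_ug = float(d["dose_ug"])
    else:
        raise InvalidParameterError("drug block needs dose_mg or dose_ug")
    drug = DrugConstants(dose=dose_ug, F=float(d["F"]), Vd=float(d["Vd"]),
                         IC50=float(d["IC50"]))
    arms = {str(k): float(v) for k, v in raw.get("arms", {}).items()}

    clock_raw = raw.get("clock", {})
    clock = ClockConvention(**clock_raw) if clock_raw else ClockConvention()

    fit = raw.get("fit", {})
    scan = raw.get("scan", {})
    return RunConfig(
        drug_name=d.get("name", "drug"), kind=kind, drug=drug, arms=arms,
        clock=clock, seed=int(fit.get("seed", 0)),
        n_starts=int(fit.get("n_starts", 50)),
        grid_step=float(scan.get("grid_step", 0.25)),
        target_sbp=float(scan.get("target_sbp", 130.0)),
        target_dbp=float(scan.get("target_dbp", 80.0)),
        synth=raw.get("synth", {}),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float)
                    + "\n")


def run_pipeline(config: RunConfig, data_dir, out_dir) -> dict:
    """Execute the full workflow: data -> baseline -> fit/select ->
    sensitivity/identifiability -> Ta scan -> optimal windows.

    Data are read from ``data_dir/data.csv`` when present, otherwise
    synthesized from the config's ``synth`` block.  Returns the manifest
    (stages, seed, file hashes); all outputs are plain CSV/JSON.
    """
    from . import __version__
    from .estimators import VariantSelector
    from .baseline import fit_baseline
    from .sensitivity import fit_identifiability, local_sens, normalize_sens, sens_summary
    from .synth import SynthScenario, generate, make_baseline_scenario, \
        nonprodrug_archetype, prodrug_archetype

    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = []

    # stage 1: data
    data_path = data_dir / "data.csv"
    if data_path.exists():
        pre_arms, post_arms = read_dataset(data_path, ta_map=config.arms)
        truth = None
    else:
        profile = config.synth.get("profile", "dipper")
        base_truth = make_baseline_scenario(profile, seed=config.seed)
        arch = (nonprodrug_archetype if config.kind == "nonprodrug"
                else prodrug_archetype)(base_truth)
        from dataclasses import replace as _replace
        arch = _replace(arch, drug=config.drug)
        scn = SynthScenario(
            true_model=arch,
            arms=tuple(config.arms.values()) or (0.0, 15.0),
            se_frac=float(config.synth.get("se_frac", 0.02)),
            seed=config.seed,
            include_concentrations=bool(
                config.synth.get("include_concentrations", False)),
            profile_kind=profile,
        )
        pre, post_arms, truth = generate(scn)
        pre_arms = [pre]
        data_path = out_dir / "data.csv"
        write_dataset(data_path, pre, post_arms)
    stages.append("data")

    # stage 2: baseline (fixed before the PK-PD stage)
    baseline, gof = fit_baseline(pre_arms[0], config.clock, seed=config.seed)
    _dump_json({"params": baseline.to_dict(), "sse": gof},
               out_dir / "baseline.json")
    stages.append("baseline")

    # stage 3: joint variant fitting + AICc selection
    sel = VariantSelector(kind=config.kind, drug=config.drug,
                          baseline=baseline, seed=config.seed,
                          n_starts=config.n_starts).fit(post_arms)
    sel.table_.to_csv(out_dir / "selection.csv", index=False)
    best = sel.best_result_
    _dump_json(fit_result_to_dict(best), out_dir / "best_fit.json")
    stages.append("select")

    # stage 4: sensitivity and identifiability of the selected model
    ident = fit_identifiability(best, post_arms)
    _dump_json({
        "ci": ident.ci_table().to_dict(orient="records"),
        "correlation": ident.correlation.tolist(),
        "params": ident.params,
        "high_corr_pairs": ident.high_corr_pairs,
        "singular": ident.singular,
    }, out_dir / "identifiability.json")
    times = np.arange(0.0, 24.0 * 3, 0.5)
    sens = local_sens(best.params, list(best.param_values), times,
                      Ta=list(config.arms.values())[0] if config.arms else 0.0,
                      n_doses=3)
    delta = sens_summary(normalize_sens(sens))
    delta.to_csv(out_dir / "sens_delta.csv")
    stages.append("sensid")

    # stage 5: dosing-time scan and optimal windows
    scan = scan_ta(best.params, grid_step=config.grid_step,
                   clock=config.clock)
    scan.df.to_csv(out_dir / "scan.csv", index=False)
    window = optimal_ta(scan, target_sbp=config.target_sbp,
                        target_dbp=config.target_dbp)
    _dump_json(window.report(config.clock), out_dir / "windows.json")
    stages.append("scan")

    manifest = {
        "stages": stages,
        "seed": config.seed,
        "drug": config.drug_name,
        "kind": config.kind,
        "versions": {
            "chronopkpd": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": {p.name: _sha256(p) for p in sorted(out_dir.iterdir())
                  if p.suffix in (".csv", ".json")
                  and p.name != "manifest.json"},
    }
    _dump_json(manifest, out_dir / "manifest.json")
    return manifest
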