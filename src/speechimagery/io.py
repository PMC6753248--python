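"""Configuration, file I/O and the staged analysis pipeline.

CSV carries trial-level data, psychometric curves, ANOVA tables and waveform
dumps; JSON carries parameter sets, gain profiles, fit results and
repetition effects.  ``run_pipeline`` executes the analysis stages in
dependency order (synthesize inputs, fit the MEG gains, fit the decision
rule, predict imagery-shifted curves, fit the /da/ scaling, run the
behavioral statistics), writing each stage's outputs together with the
resolved configuration and a content hash of its inputs so unchanged stages
are skipped on re-runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import (
    COLUMNS,
    BehavioralDataset,
    aggregate_curves,
    posthoc_level_tests,
    rm_anova,
)
from .fitting import FitResult, chisq_gof, fit_decision, fit_meg_gains, fit_scaling
from .network import GainProfile, NetworkParams
from .psychometrics import (
    DecisionParams,
    PsychometricCurve,
    ScalingParams,
    imagery_curves,
)
from .repetition import RepetitionEffects, TaskGains, simulate_repetition_effects
from .synth import SynthConfig, synth_behavior, synth_bl_curve, synth_meg_effects

__all__ = [
    "read_behavior",
    "write_behavior",
    "load_default_params",
    "read_json",
    "write_json",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("speechimagery")


def load_default_params() -> NetworkParams:
    """The packaged fixed-parameter set."""
    text = (resources.files("speechimagery") / "data" /
            "network_defaults.json").read_text()
    return NetworkParams(**json.loads(text))


def read_behavior(path: str | Path) -> BehavioralDataset:
    """Read and validate a trial-level CSV.

    Malformed rows are reported with their line numbers (header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    problems = []
    checks = [
        (~frame["condition"].isin(("AI", "HI", "BL")), "condition"),
        (~frame["token"].isin(("ba", "da", "none")), "token"),
        (~frame["level"].isin(range(1, 8)), "level"),
        (~frame["choice"].isin(("ba", "da")), "choice"),
        (pd.to_numeric(frame["rt_ms"], errors="coerce").fillna(-1) <= 0,
         "rt_ms"),
    ]
    for bad, column in checks:
        for idx in frame.index[bad][:10]:
            problems.append(f"line {idx + 2}: invalid {column} "
                            f"{frame.at[idx, column]!r}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return BehavioralDataset(frame)


def write_behavior(data: BehavioralDataset, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data.frame.to_csv(path, index=False)
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True)
                    + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _hash_payload(payload) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(payload), sort_keys=True).encode()
    ).hexdigest()


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = ("synth", "fit-meg", "fit-decision", "predict",
                               "fit-scaling", "analyze")
    meg_noise_sd: float = 0.02
    bl_binomial_n: int = 684
    #: modelled choice of the psychometric curves; 'da' makes curves rise
    #: with continuum level
    choice_convention: str = "da"
    n_participants: int = 19
    n_starts: int = 8
    params_overrides: dict = field(default_factory=dict)

    def network_params(self) -> NetworkParams:
        base = load_default_params()
        if self.params_overrides:
            base = dataclasses.replace(base, **self.params_overrides)
        return base


ALL_STAGES = ("synth", "fit-meg", "fit-decision", "predict", "fit-scaling",
              "analyze")
#: upstream stage required by each stage
_NEEDS = {
    "fit-meg": ("synth",),
    "fit-decision": ("synth",),
    "predict": ("fit-meg", "fit-decision"),
    "fit-scaling": ("fit-meg", "fit-decision", "synth"),
    "analyze": ("synth",),
}


def _stage_fresh(outdir: Path, stage: str, input_hash: str) -> bool:
    manifest = outdir / f"{stage}.manifest.json"
    if not manifest.exists():
        return False
    try:
        return json.loads(manifest.read_text())["input_hash"] == input_hash
    except (KeyError, json.JSONDecodeError):
        return False


def _finish_stage(outdir: Path, stage: str, input_hash: str,
                  outputs: list[str]) -> None:
    write_json({"input_hash": input_hash, "outputs": outputs},
               outdir / f"{stage}.manifest.json")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages in dependency order.

    Each stage writes its artifacts plus a manifest holding a content hash
    of everything it consumed; a stage whose inputs are unchanged on a
    re-run is skipped.  The resolved config is written next to the outputs.
    Returns the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(config, outdir / "run_config.json")
    params = config.network_params()
    requested = [s for s in ALL_STAGES if s in config.stages]
    for stage in requested:
        for need in _NEEDS.get(stage, ()):
            if need not in requested and \
                    not (outdir / f"{need}.manifest.json").exists():
                raise RuntimeError(
                    f"stage {stage!r} needs {need!r} which has not run")
    executed = []
    for stage in requested:
        upstream_files: dict[str, str] = {}
        for need in _NEEDS.get(stage, ()):
            manifest = json.loads(
                (outdir / f"{need}.manifest.json").read_text())
            for name in manifest["outputs"]:
                artifact = outdir / name
                upstream_files[name] = hashlib.sha256(
                    artifact.read_bytes()).hexdigest() \
                    if artifact.exists() else "missing"
        input_hash = _hash_payload([config, stage, upstream_files])
        if _stage_fresh(outdir, stage, input_hash):
            logger.info("stage %s: inputs unchanged, skipping", stage)
            continue
        logger.info("stage %s: running", stage)
        outputs = _run_stage(stage, config, params, outdir)
        _finish_stage(outdir, stage, input_hash, outputs)
        executed.append(stage)
    (outdir / "report.txt").write_text(
        "pipeline run complete\n"
        f"seed: {config.seed}\n"
        f"stages requested: {', '.join(requested)}\n"
        f"stages executed: {', '.join(executed) or '(all fresh)'}\n")
    return outdir


def _run_stage(stage: str, config: RunConfig, params: NetworkParams,
               outdir: Path) -> list[str]:
    from .repetition import TABLE_GAINS  # local import to avoid cycle noise

    if stage == "synth":
        data = synth_behavior(SynthConfig(
            n_participants=config.n_participants, seed=config.seed))
        write_behavior(data, outdir / "behavior.csv")
        effects = synth_meg_effects(TABLE_GAINS["AI"], TABLE_GAINS["HI"],
                                    noise_sd=config.meg_noise_sd,
                                    seed=config.seed, params=params)
        write_json(effects.to_dict(), outdir / "meg_effects.json")
        bl = synth_bl_curve(DecisionParams(), binomial_n=config.bl_binomial_n,
                            seed=config.seed, params=params)
        bl.to_frame().to_csv(outdir / "bl_curve.csv", index=False)
        return ["behavior.csv", "meg_effects.json", "bl_curve.csv"]

    if stage == "fit-meg":
        effects = RepetitionEffects(**read_json(outdir / "meg_effects.json"))
        fit = fit_meg_gains(effects, params, seed=config.seed,
                            n_starts=config.n_starts)
        write_json(fit, outdir / "fit_meg.json")
        return ["fit_meg.json"]

    if stage == "fit-decision":
        curve = pd.read_csv(outdir / "bl_curve.csv")
        fit = fit_decision(curve["p_choice_da"].to_numpy(), params,
                           seed=config.seed, n_starts=config.n_starts)
        write_json(fit, outdir / "fit_decision.json")
        return ["fit_decision.json"]

    if stage == "predict":
        meg = read_json(outdir / "fit_meg.json")["params"]
        dec = read_json(outdir / "fit_decision.json")["params"]
        ai = TaskGains(meg["g_repeated_AI"], meg["g_novel_AI"], meg["G_A_AI"])
        hi = TaskGains(meg["g_repeated_HI"], meg["g_novel_HI"], meg["G_A_HI"])
        decision = DecisionParams(dec["decision_noise"], dec["choice_bias"])
        frames = []
        for token in ("ba", "da"):
            curves = imagery_curves(ai, hi, decision, token, params)
            for name, curve in curves.items():
                frames.append(curve.to_frame().assign(imagery_token=token))
        pd.concat(frames).to_csv(outdir / "predicted_curves.csv", index=False)
        return ["predicted_curves.csv"]

    if stage == "fit-scaling":
        meg = read_json(outdir / "fit_meg.json")["params"]
        dec = read_json(outdir / "fit_decision.json")["params"]
        decision = DecisionParams(dec["decision_noise"], dec["choice_bias"])
        data = read_behavior(outdir / "behavior.csv")
        agg = aggregate_curves(data)
        out = {}
        for task in ("AI", "HI"):
            gains = TaskGains(meg[f"g_repeated_{task}"],
                              meg[f"g_novel_{task}"], meg[f"G_A_{task}"])
            emp = agg[(agg["condition"] == task) & (agg["token"] == "da")]
            fit = fit_scaling(emp.sort_values("level")["p_da"].to_numpy(),
                              gains, decision, "da", params,
                              seed=config.seed, n_starts=config.n_starts)
            out[task] = fit
        write_json(out, outdir / "fit_scaling.json")
        return ["fit_scaling.json"]

    if stage == "analyze":
        data = read_behavior(outdir / "behavior.csv")
        aggregate_curves(data).to_csv(outdir / "curves.csv", index=False)
        anova = rm_anova(data, dv="proportion", factors=["condition", "level"],
                         conditions=("AI", "HI"), token="ba")
        anova.to_csv(outdir / "anova_ai_hi_ba.csv", index=False)
        posthoc = posthoc_level_tests(data, ("AI", "HI"), "ba")
        posthoc.to_csv(outdir / "posthoc_ai_hi_ba.csv", index=False)
        return ["curves.csv", "anova_ai_hi_ba.csv", "posthoc_ai_hi_ba.csv"]

    raise ValueError(f"unknown stage {stage!r}")
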