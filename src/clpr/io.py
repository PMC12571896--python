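"""Trial-table CSV schema, validation, configuration and pipeline runner.

The trial CSV schema has one row per trial:

    agent_id, trial, hue_1..hue_8, category, mean_level, var_level,
    [mu, sigma,] choice, confidence, accuracy

Hues are boundary-relative in [-0.5, 0.5]; category and choice are -1/+1;
confidence is an integer 1-6; accuracy must equal (choice == category).
``mu``/``sigma`` (the generative cell parameters) are optional but kept by
the generators, since the variance-scaled metanoise models need sigma.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stimuli import HUE_COLUMNS, HUE_MAX, HUE_MIN

logger = logging.getLogger("clpr")

REQUIRED_COLUMNS = HUE_COLUMNS + [
    "category",
    "mean_level",
    "var_level",
    "choice",
    "confidence",
    "accuracy",
]


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema, reporting offending rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    if len(trials) == 0:
        raise ValueError("trial table contains no trials")

    def bad_rows(mask: pd.Series, what: str) -> None:
        if mask.any():
            rows = trials.index[mask].tolist()[:10]
            raise ValueError(f"{what} (rows {rows}{'...' if mask.sum() > 10 else ''})")

    hues = trials[HUE_COLUMNS]
    bad_rows(
        ((hues < HUE_MIN) | (hues > HUE_MAX)).any(axis=1),
        f"hues outside [{HUE_MIN}, {HUE_MAX}]",
    )
    bad_rows(~trials["category"].isin([-1, 1]), "category must be -1 or +1")
    bad_rows(~trials["choice"].isin([-1, 1]), "choice must be -1 or +1")
    conf = trials["confidence"]
    bad_rows(
        (conf != conf.astype(int)) | (conf < 1) | (conf > 6),
        "confidence must be an integer in 1..6",
    )
    bad_rows(
        trials["accuracy"] != (trials["choice"] == trials["category"]).astype(int),
        "accuracy inconsistent with (choice, category)",
    )
    return trials


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV."""
    trials = pd.read_csv(path)
    return validate_trials(trials)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table to CSV at full float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a YAML mapping")
    return config


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


KNOWN_STAGES = (
    "simulate",
    "fit",
    "compare",
    "analyze_rie",
    "recover_params",
    "recover_models",
    "context",
)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages in order and write reports.

    ``config`` keys: ``seed`` (master seed), ``stages`` (ordered list of
    stage names), plus one mapping of options per stage.  Every report
    embeds the resolved config so runs are reproducible end to end.
    Unknown stages or variants are rejected before any stage executes.
    """
    from .context import context_flip_test, simulate_context_study
    from .fitting import compare_models, fit_model
    from .model import ModelParams, simulate_dataset, variant_free_names
    from .recovery import model_recovery, parameter_recovery
    from .regression import contrast_table, fit_rank_regression
    from .stimuli import StimulusDesign, generate_design_set

    out_dir = Path(out_dir)
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stages: {unknown}; known: {KNOWN_STAGES}")
    for stage in stages:
        variant = config.get(stage, {}).get("variant")
        if variant is not None:
            variant_free_names(int(variant))  # raises on variants outside 1-7
    master = np.random.SeedSequence(config.get("seed", 0))
    stage_seeds = {s: child for s, child in zip(stages, master.spawn(len(stages)))}
    report: dict = {"config": config, "outputs": {}}
    trials = None

    for stage in stages:
        opts = dict(config.get(stage, {}))
        seed_int = int(stage_seeds[stage].generate_state(1)[0] % (2**31))
        logger.info("stage %s (seed %d)", stage, seed_int)
        if stage == "simulate":
            design = StimulusDesign(
                mean_levels=tuple(opts.get("mean_levels", (0.03, 0.06))),
                variance_levels=tuple(opts.get("variance_levels", (0.05, 0.15))),
                n_per_cell=int(opts.get("n_per_cell", 100)),
            )
            params = ModelParams.from_free(
                int(opts.get("variant", 4)), opts["params"]
            )
            rng = np.random.default_rng(stage_seeds[stage])
            stim = generate_design_set(design, rng)
            trials = simulate_dataset(stim, params, rng)
            trials.insert(0, "agent_id", 0)
            write_trials(trials, out_dir / "trials.csv")
            report["outputs"]["simulate"] = {"n_trials": len(trials), "seed": seed_int}
        elif stage == "fit":
            tab = _stage_trials(trials, opts)
            res = fit_model(
                tab,
                int(opts.get("variant", 4)),
                budget=int(opts.get("budget", 100)),
                seed=seed_int,
                max_pred_stimuli=opts.get("max_pred_stimuli", 250),
            )
            _write_json(res.to_dict(), out_dir / "fit.json")
            report["outputs"]["fit"] = res.to_dict()
        elif stage == "compare":
            tab = _stage_trials(trials, opts)
            comp = compare_models(
                tab,
                variants=opts.get("variants", [4, 6]),
                budget=int(opts.get("budget", 50)),
                seed=seed_int,
                max_pred_stimuli=opts.get("max_pred_stimuli", 250),
            )
            comp.table.to_csv(out_dir / "comparison.csv", index=False)
            report["outputs"]["compare"] = {
                "winner": comp.winner,
                "summary": comp.summary_table.to_dict(orient="records"),
            }
        elif stage == "analyze_rie":
            tab = _stage_trials(trials, opts)
            fits = fit_rank_regression(
                tab, dv=opts.get("dv", "confidence"), split_by=opts.get("split_by", "category")
            )
            table = contrast_table(fits, include_inlying=opts.get("dv") == "choice")
            table.to_csv(out_dir / "contrasts.csv", index=False)
            coef = pd.DataFrame(
                {f"split_{v}": fit.betas for v, fit in sorted(fits.items())},
                index=pd.RangeIndex(1, 9, name="hue_rank"),
            )
            coef.to_csv(out_dir / "rank_coefficients.csv")
            report["outputs"]["analyze_rie"] = table.to_dict(orient="records")
        elif stage == "recover_params":
            run = parameter_recovery(
                n_agents=int(opts.get("n_agents", 10)),
                trials_per_agent=int(opts.get("trials_per_agent", 2000)),
                budget=int(opts.get("budget", 30)),
                seed=seed_int,
                variant=int(opts.get("variant", 4)),
            )
            _write_json(run.to_dict(), out_dir / "parameter_recovery.json")
            run.scatter_frame().to_csv(out_dir / "recovery_scatter.csv", index=False)
            report["outputs"]["recover_params"] = run.to_dict()
        elif stage == "recover_models":
            confusion = model_recovery(
                n_datasets_per_model=int(opts.get("n_datasets_per_model", 5)),
                variants=opts.get("variants", [4, 6]),
                budget=int(opts.get("budget", 20)),
                seed=seed_int,
                trials_per_dataset=int(opts.get("trials_per_dataset", 2000)),
            )
            confusion.to_csv(out_dir / "model_recovery.csv")
            report["outputs"]["recover_models"] = confusion.to_dict()
        elif stage == "context":
            params = ModelParams.from_free(
                int(opts.get("variant", 4)), opts.get("params", (0.05, 0.15))
            )
            blue, red = simulate_context_study(
                params,
                offset=float(opts.get("offset", 0.1)),
                n_per_cell=int(opts.get("n_per_cell", 150)),
                seed=seed_int,
            )
            write_trials_context = blue.assign(context="blue"), red.assign(context="red")
            pd.concat(write_trials_context, ignore_index=True).to_csv(
                out_dir / "context_trials.csv", index=False
            )
            flip = context_flip_test(blue, red)
            _write_json(flip.to_dict(), out_dir / "context_flip.json")
            report["outputs"]["context"] = flip.to_dict()
    report["seeds"] = {s: int(c.generate_state(1)[0] % (2**31)) for s, c in stage_seeds.items()}
    _write_json(report, out_dir / "report.json")
    return report


def _stage_trials(trials, opts) -> pd.DataFrame:
    if "trials" in opts:
        return read_trials(opts["trials"])
    if trials is None:
        raise ValueError("stage needs trials: run simulate first or pass a 'trials' path")
    return trials
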