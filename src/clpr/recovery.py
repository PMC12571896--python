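"""Parameter-recovery and model-recovery harnesses.

Parameter recovery simulates agents with parameters drawn uniformly from
the fitting ranges, refits the generating variant, and correlates true
with recovered parameters (Pearson and Spearman).  Model recovery
cross-fits datasets generated under each candidate variant with every
candidate and tabulates how often the generating variant attains the
lowest AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import DEFAULT_BOUNDS, ConfidenceModel
from .model import ModelParams, simulate_dataset, variant_free_names
from .stimuli import StimulusDesign, generate_design_set

#: Uniform draw ranges for generative parameters (the fitting bounds).
DEFAULT_RANGES = dict(DEFAULT_BOUNDS)


def _design_for(trials_per_agent: int, design: StimulusDesign | None) -> StimulusDesign:
    if design is not None:
        return design
    base = StimulusDesign()
    n_per_cell = max(1, round(trials_per_agent / base.n_cells))
    return StimulusDesign(
        mean_levels=base.mean_levels,
        variance_levels=base.variance_levels,
        n_per_cell=n_per_cell,
    )


def _draw_params(variant: int, ranges: dict, rng: np.random.Generator) -> ModelParams:
    values = {name: rng.uniform(*ranges[name]) for name in variant_free_names(variant)}
    return ModelParams(variant=variant, **values)


@dataclass
class RecoveryRun:
    """True and fitted parameters per agent with recovery correlations."""

    true_params: pd.DataFrame
    fitted_params: pd.DataFrame
    pearson_r: dict[str, float]
    spearman_rho: dict[str, float]
    meta: dict = field(default_factory=dict)

    @property
    def n_agents(self) -> int:
        return len(self.true_params)

    def scatter_frame(self) -> pd.DataFrame:
        """Tidy true-vs-fitted table, one row per agent x parameter."""
        rows = []
        for name in self.true_params.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "agent": self.true_params.index,
                        "true": self.true_params[name].to_numpy(),
                        "fitted": self.fitted_params[name].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "n_agents": self.n_agents,
            "meta": self.meta,
        }


def correlate(true: pd.DataFrame, fitted: pd.DataFrame):
    """Pearson and Spearman correlations per parameter column."""
    pear = {
        c: float(stats.pearsonr(true[c], fitted[c]).statistic) for c in true.columns
    }
    spear = {
        c: float(stats.spearmanr(true[c], fitted[c]).statistic) for c in true.columns
    }
    return pear, spear


def parameter_recovery(
    n_agents: int = 100,
    trials_per_agent: int = 8000,
    ranges: dict[str, tuple[float, float]] | None = None,
    budget: int = 1000,
    seed: int | None = None,
    *,
    variant: int = 4,
    design: StimulusDesign | None = None,
    max_pred_stimuli: int | None = 250,
) -> RecoveryRun:
    """Simulate-and-refit recovery for one variant.

    Per agent: draw the variant's free parameters uniformly from
    ``ranges`` (defaults: compression U(1e-5, 0.2), decnoise U(1e-5, 0.3)),
    simulate ``trials_per_agent`` trials on the standard 2x2 design, refit
    the same variant by differential evolution, and record both parameter
    vectors.  Correlations are reported per free parameter.
    """
    if n_agents < 2:
        raise ValueError("need at least two agents to correlate parameters")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    design = _design_for(trials_per_agent, design)
    ss = np.random.SeedSequence(seed)
    names = variant_free_names(variant)
    true_rows, fit_rows = [], []
    for agent_ss in ss.spawn(n_agents):
        rng = np.random.default_rng(agent_ss)
        params = _draw_params(variant, ranges, rng)
        stim = generate_design_set(design, rng)
        sim = simulate_dataset(stim, params, rng)
        fit_seed = int(agent_ss.generate_state(1)[0] % (2**31))
        res = ConfidenceModel(sim, variant, max_pred_stimuli=max_pred_stimuli).fit(
            bounds=ranges, budget=budget, seed=fit_seed
        )
        true_rows.append({n: getattr(params, n) for n in names})
        fit_rows.append({n: getattr(res.params, n) for n in names})
    true_df = pd.DataFrame(true_rows)
    fit_df = pd.DataFrame(fit_rows)
    pear, spear = correlate(true_df, fit_df)
    return RecoveryRun(
        true_params=true_df,
        fitted_params=fit_df,
        pearson_r=pear,
        spearman_rho=spear,
        meta={
            "variant": variant,
            "n_agents": n_agents,
            "trials_per_agent": design.n_trials,
            "budget": budget,
            "seed": seed,
            "ranges": {n: tuple(ranges[n]) for n in names},
        },
    )


def model_recovery(
    n_datasets_per_model: int = 50,
    variants: Sequence[int] = (1, 2, 3, 4, 5, 6),
    budget: int = 1000,
    seed: int | None = None,
    *,
    trials_per_dataset: int = 4000,
    ranges: dict[str, tuple[float, float]] | None = None,
    design: StimulusDesign | None = None,
    max_pred_stimuli: int | None = 250,
) -> pd.DataFrame:
    """AIC confusion matrix across generating and fitting variants.

    Returns a DataFrame indexed by generating variant whose columns give
    P(lowest AIC = fitting variant); rows sum to 1.  Ties (rare) go to the
    variant with fewer free parameters, then the lower variant id.
    """
    variants = list(variants)
    if len(variants) < 1:
        raise ValueError("need at least one variant")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    design = _design_for(trials_per_dataset, design)
    ss = np.random.SeedSequence(seed)
    counts = pd.DataFrame(0.0, index=variants, columns=variants)
    children = iter(ss.spawn(len(variants) * n_datasets_per_model))
    for gen_variant in variants:
        for _ in range(n_datasets_per_model):
            child = next(children)
            rng = np.random.default_rng(child)
            params = _draw_params(gen_variant, ranges, rng)
            stim = generate_design_set(design, rng)
            sim = simulate_dataset(stim, params, rng)
            scores = []
            for fit_variant in variants:
                fit_seed = int(
                    np.random.default_rng((child.entropy, fit_variant)).integers(2**31)
                )
                res = ConfidenceModel(
                    sim, fit_variant, max_pred_stimuli=max_pred_stimuli
                ).fit(bounds=ranges, budget=budget, seed=fit_seed)
                scores.append((res.aic, res.k_free, fit_variant))
            winner = min(scores)[2]
            counts.loc[gen_variant, winner] += 1
    confusion = counts / n_datasets_per_model
    confusion.index.name = "generating"
    confusion.columns.name = "winner"
    return confusion
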