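"""Model fitting by differential evolution and AIC model comparison.

The fitting surface is the set of per-cell observed mean accuracies and
mean confidence ratings, one cell per (mean level, variance level)
condition.  A candidate parameter vector is scored by the summed squared
error between observed and predicted cell means

    SSE = sum_cells (oACC - pACC)^2 + sum_cells (oCJ - pCJ)^2

with confidence on its raw 1-6 scale by default, and models are compared
with AIC = 2k + n * ln(SSE / n), n counting one accuracy and one
confidence point per cell.

``ConfidenceModel`` / ``ConfidenceModelResults`` follow the statsmodels
model/results convention; :func:`fit_model` and :func:`compare_models`
are thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from statsmodels.iolib.table import SimpleTable

from . import oracles
from .model import (
    ConfidenceCriteria,
    ModelParams,
    simulate_dataset,
    variant_free_names,
)
from .stimuli import HUE_COLUMNS

#: Default optimisation bounds per free parameter.
DEFAULT_BOUNDS = {
    "d": (1e-5, 0.2),
    "decnoise": (1e-5, 0.3),
    "metanoise": (1e-5, 0.3),
    "scalemetanoise": (0.0, 10.0),
}

CELL_KEYS = ["mean_level", "var_level"]


def summarize_cells(trials: pd.DataFrame) -> pd.DataFrame:
    """Observed mean accuracy and confidence per (mean, variance) cell.

    Accuracy is 1 when the choice sign matches the category sign.  Cells
    pool the two stimulus categories (the task is color-symmetric).
    Raises if any cell of the crossed observed levels is empty.
    """
    required = CELL_KEYS + ["choice", "confidence", "category"]
    missing = [c for c in required if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks columns {missing}")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    t = trials.copy()
    t["accuracy"] = (t["choice"] == t["category"]).astype(float)
    cells = (
        t.groupby(CELL_KEYS)
        .agg(oACC=("accuracy", "mean"), oCJ=("confidence", "mean"), n_trials=("choice", "size"))
        .reset_index()
    )
    for k in t[CELL_KEYS[0]].unique():
        for j in t[CELL_KEYS[1]].unique():
            if not ((cells.mean_level == k) & (cells.var_level == j)).any():
                raise ValueError(f"empty design cell (mean_level={k}, var_level={j})")
    return cells.sort_values(CELL_KEYS).reset_index(drop=True)


def sse_cost(
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    *,
    normalize_confidence: bool = False,
) -> float:
    """Summed squared error between observed and predicted cell means.

    ``normalize_confidence`` maps confidence onto [0, 1] before squaring,
    removing the scale imbalance of mixing proportions with a 1-6 scale;
    the default keeps the raw scale of the printed cost function.
    """
    obs = observed.sort_values(CELL_KEYS).reset_index(drop=True)
    pred = predicted.sort_values(CELL_KEYS).reset_index(drop=True)
    if len(obs) != len(pred) or not (
        obs[CELL_KEYS].to_numpy() == pred[CELL_KEYS].to_numpy()
    ).all():
        raise ValueError("observed and predicted tables cover different cells")
    d_acc = obs["oACC"].to_numpy() - pred["pACC"].to_numpy()
    o_cj, p_cj = obs["oCJ"].to_numpy(), pred["pCJ"].to_numpy()
    if normalize_confidence:
        o_cj, p_cj = (o_cj - 1.0) / 5.0, (p_cj - 1.0) / 5.0
    d_cj = o_cj - p_cj
    return float(d_acc @ d_acc + d_cj @ d_cj)


def predict_cells(
    params: ModelParams,
    stimuli: pd.DataFrame,
    *,
    n_sim: int = 2000,
    seed: int | None = None,
    method: str | None = None,
    var_floor: float | None = None,
    criteria: ConfidenceCriteria | None = None,
) -> pd.DataFrame:
    """Predicted mean accuracy and confidence per cell for a stimulus table.

    Variants 1-6 default to the deterministic closed-form oracle; variant 7
    requires Monte-Carlo simulation (``n_sim`` responses per cell, fixed
    ``seed`` per evaluation so the objective stays reproducible).
    """
    if method is None:
        method = "simulation" if params.variant == 7 else "oracle"
    if method == "oracle":
        out = oracles.expected_cell_means(stimuli, params, var_floor, criteria)
        return out.sort_values(CELL_KEYS).reset_index(drop=True)
    if method != "simulation":
        raise ValueError("method must be 'oracle' or 'simulation'")
    cell_sizes = stimuli.groupby(CELL_KEYS).size()
    reps = max(1, int(np.ceil(n_sim / cell_sizes.min())))
    expanded = stimuli.loc[np.repeat(stimuli.index, reps)].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    sim = simulate_dataset(expanded, params, rng, criteria=criteria, var_floor=var_floor)
    pred = (
        sim.groupby(CELL_KEYS)
        .agg(pACC=("accuracy", "mean"), pCJ=("confidence", "mean"))
        .reset_index()
    )
    return pred.sort_values(CELL_KEYS).reset_index(drop=True)


def aic(sse: float, k_free: int, n_points: int) -> float:
    """AIC = 2k + n * ln(SSE / n) for a least-squares fit."""
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    if sse < 0:
        raise ValueError("SSE must be non-negative")
    if sse == 0:
        raise ValueError(
            "SSE of exactly zero makes the AIC diverge; report -inf as a sentinel"
        )
    return float(2 * k_free + n_points * np.log(sse / n_points))


class ConfidenceModel:
    """A c-LPR variant bound to a trial table, ready to be fitted.

    Parameters
    ----------
    trials
        Trial table with ``hue_1..hue_8``, ``category``, ``mean_level``,
        ``var_level``, ``sigma`` (element spread of the condition),
        ``choice`` and ``confidence``.
    variant
        Model variant 1-7.
    criteria
        Fixed confidence criteria (default the standard set).
    normalize_confidence
        Score confidence on [0, 1] instead of the raw 1-6 scale.
    predict_method
        'oracle' (default for variants 1-6) or 'simulation' (forced for
        variant 7).
    n_sim, sim_seed
        Simulated responses per cell and the fixed per-evaluation seed of
        the Monte-Carlo prediction path.
    max_pred_stimuli
        Optional cap on the number of stimuli per cell used by the oracle
        prediction (a deterministic head subsample); None uses all trials.

    Examples
    --------
    >>> model = ConfidenceModel(trials, variant=4)
    >>> res = model.fit(budget=100, seed=1)
    >>> print(res.summary())
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        variant: int = 4,
        *,
        criteria: ConfidenceCriteria | None = None,
        normalize_confidence: bool = False,
        predict_method: str | None = None,
        n_sim: int = 2000,
        sim_seed: int = 0,
        var_floor: float | None = None,
        eq4_literal: bool = False,
        max_pred_stimuli: int | None = None,
    ) -> None:
        self.variant = int(variant)
        self.free_names = variant_free_names(self.variant)  # validates variant
        self.trials = trials.reset_index(drop=True)
        self.criteria = criteria or ConfidenceCriteria()
        self.normalize_confidence = normalize_confidence
        self.predict_method = predict_method
        self.n_sim = n_sim
        self.sim_seed = sim_seed
        self.eq4_literal = eq4_literal
        if "sigma" in self.trials.columns:
            sigmas = self.trials["sigma"].to_numpy(dtype=float)
            self.var_floor = float(sigmas.min()) if var_floor is None else float(var_floor)
        else:
            self.var_floor = 0.0 if var_floor is None else float(var_floor)
        self.cells = summarize_cells(self.trials)
        if len(self.cells) == 1:
            warnings.warn("fitting to a single design cell; parameters are weakly constrained")
        self.n_points = 2 * len(self.cells)
        if max_pred_stimuli is not None:
            self._pred_stimuli = (
                self.trials.groupby(CELL_KEYS + ["category"], group_keys=False)
                .head(max_pred_stimuli)
                .reset_index(drop=True)
            )
        else:
            self._pred_stimuli = self.trials

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, variant: int = 4, **kwargs) -> "ConfidenceModel":
        return cls(trials, variant, **kwargs)

    @classmethod
    def from_csv(cls, path, variant: int = 4, **kwargs) -> "ConfidenceModel":
        from .io import read_trials

        return cls(read_trials(path), variant, **kwargs)

    def params_from_free(self, theta) -> ModelParams:
        return ModelParams.from_free(self.variant, theta, eq4_literal=self.eq4_literal)

    def predict(self, params: ModelParams) -> pd.DataFrame:
        return predict_cells(
            params,
            self._pred_stimuli,
            n_sim=self.n_sim,
            seed=self.sim_seed,
            method=self.predict_method,
            var_floor=self.var_floor,
            criteria=self.criteria,
        )

    def objective(self, theta) -> float:
        """SSE of the cell means at a free-parameter vector."""
        params = self.params_from_free(theta)
        return sse_cost(
            self.cells, self.predict(params), normalize_confidence=self.normalize_confidence
        )

    def fit(
        self,
        bounds: dict[str, tuple[float, float]] | None = None,
        budget: int = 1000,
        seed: int | None = None,
        *,
        popsize: int = 8,
        tol: float = 1e-8,
        polish: bool = True,
    ) -> "ConfidenceModelResults":
        """Minimise the SSE with differential evolution.

        ``budget`` is the iteration (generation) cap; the reference
        procedure used 1000 iterations, far beyond what the smooth
        oracle objective needs, so smaller budgets with the default
        local polish are routinely used.
        """
        if budget < 1:
            raise ValueError("budget must be at least 1")
        bound_map = {**DEFAULT_BOUNDS, **(bounds or {})}
        de_bounds = [bound_map[name] for name in self.free_names]
        result = differential_evolution(
            self.objective,
            de_bounds,
            maxiter=budget,
            seed=seed,
            popsize=popsize,
            tol=tol,
            polish=polish,
        )
        params = self.params_from_free(result.x)
        return ConfidenceModelResults(
            model=self,
            params=params,
            sse=float(result.fun),
            optimizer_meta={
                "iterations": int(result.nit),
                "nfev": int(result.nfev),
                "seed": seed,
                "budget": budget,
                "bounds": {n: tuple(b) for n, b in zip(self.free_names, de_bounds)},
                "message": str(result.message),
            },
        )


@dataclass
class ConfidenceModelResults:
    """Fit result: parameters, SSE, AIC and optimizer metadata."""

    model: ConfidenceModel
    params: ModelParams
    sse: float
    optimizer_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("SSE must be non-negative")
        self.k_free = self.params.k_free
        self.n_points = self.model.n_points
        self.aic = (
            -np.inf if self.sse == 0 else aic(self.sse, self.k_free, self.n_points)
        )

    @property
    def variant(self) -> int:
        return self.params.variant

    @property
    def predicted(self) -> pd.DataFrame:
        """Observed and fitted cell means side by side."""
        return self.model.cells.merge(self.model.predict(self.params), on=CELL_KEYS)

    def simulate(self, rng: np.random.Generator, stimuli: pd.DataFrame | None = None) -> pd.DataFrame:
        """Simulate a dataset from the fitted parameters."""
        stimuli = self.model.trials if stimuli is None else stimuli
        return simulate_dataset(
            stimuli[HUE_COLUMNS + [c for c in stimuli.columns if c not in HUE_COLUMNS]],
            self.params,
            rng,
            criteria=self.model.criteria,
            var_floor=self.model.var_floor,
        )

    def plot_cells(self, axes=None):
        """Observed vs fitted accuracy and confidence per design cell."""
        import matplotlib.pyplot as plt

        table = self.predicted
        labels = [f"m{int(r.mean_level)}v{int(r.var_level)}" for r in table.itertuples()]
        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(8, 3))
        for ax, obs, pred, name in (
            (axes[0], "oACC", "pACC", "accuracy"),
            (axes[1], "oCJ", "pCJ", "confidence"),
        ):
            x = np.arange(len(table))
            ax.plot(x, table[obs], "o", label="observed")
            ax.plot(x, table[pred], "x", label="fitted")
            ax.set_xticks(x, labels)
            ax.set_title(name)
        axes[0].legend()
        return axes

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": {n: getattr(self.params, n) for n in self.params.free_names},
            "sse": self.sse,
            "k_free": self.k_free,
            "n_points": self.n_points,
            "aic": self.aic,
            "optimizer": self.optimizer_meta,
        }

    def summary(self) -> SimpleTable:
        rows = [[name, f"{getattr(self.params, name):.6g}"] for name in self.params.free_names]
        rows += [
            ["SSE", f"{self.sse:.6g}"],
            ["k (free)", str(self.k_free)],
            ["n (points)", str(self.n_points)],
            ["AIC", f"{self.aic:.4f}"],
        ]
        return SimpleTable(
            rows,
            headers=["", "value"],
            title=f"c-LPR variant {self.variant} ({self.params.transfer}) fit",
        )


def fit_model(
    trials: pd.DataFrame,
    variant: int = 4,
    bounds: dict[str, tuple[float, float]] | None = None,
    budget: int = 1000,
    seed: int | None = None,
    **model_kwargs,
) -> ConfidenceModelResults:
    """Fit one variant to a trial table (functional wrapper)."""
    return ConfidenceModel(trials, variant, **model_kwargs).fit(
        bounds=bounds, budget=budget, seed=seed
    )


@dataclass
class ModelComparison:
    """Per-agent, per-variant AICs with summary statistics."""

    table: pd.DataFrame  # columns: agent_id, variant, aic, sse, params...

    @property
    def summary_table(self) -> pd.DataFrame:
        agg = (
            self.table.groupby("variant")
            .agg(mean_aic=("aic", "mean"), sum_aic=("aic", "sum"), k_free=("k_free", "first"))
            .reset_index()
        )
        return agg.sort_values(["mean_aic", "k_free"]).reset_index(drop=True)

    @property
    def winner(self) -> int:
        """Variant with the lowest mean AIC; ties go to fewer free parameters."""
        return int(self.summary_table.iloc[0]["variant"])

    def summary(self) -> SimpleTable:
        s = self.summary_table
        rows = [
            [int(r.variant), int(r.k_free), f"{r.mean_aic:.2f}", f"{r.sum_aic:.1f}"]
            for r in s.itertuples()
        ]
        return SimpleTable(
            rows,
            headers=["variant", "df", "mean AIC", "sum AIC"],
            title="c-LPR model comparison (lower AIC is better)",
        )


def compare_models(
    trials: pd.DataFrame,
    variants: Sequence[int] = (1, 2, 3, 4, 5, 6, 7),
    budget: int = 1000,
    seed: int | None = None,
    **model_kwargs,
) -> ModelComparison:
    """Fit each variant to each agent's trials and tabulate AICs.

    ``trials`` may carry an ``agent_id`` column; absent one, the table is
    treated as a single agent.
    """
    if "agent_id" not in trials.columns:
        trials = trials.assign(agent_id=0)
    variants = list(variants)
    rows = []
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(trials["agent_id"].nunique() * len(variants)))
    for agent_id, agent_trials in trials.groupby("agent_id"):
        for variant in variants:
            fit_seed = int(next(children).generate_state(1)[0] % (2**31))
            res = fit_model(
                agent_trials, variant, budget=budget, seed=fit_seed, **model_kwargs
            )
            row = {
                "agent_id": agent_id,
                "variant": variant,
                "aic": res.aic,
                "sse": res.sse,
                "k_free": res.k_free,
            }
            row.update({n: getattr(res.params, n) for n in res.params.free_names})
            rows.append(row)
    return ModelComparison(table=pd.DataFrame(rows))
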