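"""Reverse-correlation analysis: choice and confidence weights by hue rank.

Each trial's eight hues are sorted ascending (rank 1 = bluest, rank 8 =
reddest) and used as predictors of the trial's choice (logistic link) or
confidence rating (linear link), separately per stimulus category or per
response.  The pattern of the eight coefficients is then summarised with
three planned contrasts:

* ``slope`` — a centered linear trend across ranks;
* ``congruency`` — mean weight of the stimulus-incongruent elements
  (ranks 1-4 for red, 5-8 for blue) minus the congruent elements;
* ``inlying_outlying`` — mean weight of the inlying ranks 3-6 minus the
  outlying ranks 1-2 and 7-8 (a choice-level robust-averaging signature).

Sign conventions.  Raw regression coefficients are reported exactly as
fitted.  For *confidence* fits the direction of the hue effect depends on
the category (on blue trials a redder element lowers confidence), so the
slope and congruency contrasts are computed on category-oriented
coefficients, ``beta * split_value``; with that orientation a
response-incongruent-evidence (RIE) pattern yields a negative slope for
red, a positive slope for blue and a positive congruency contrast for
both categories.  Choice fits keep raw coefficients (the choice variable
already has a global direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .stimuli import HUE_COLUMNS, N_ELEMENTS

RANK_COLUMNS = [f"rank_{i}" for i in range(1, N_ELEMENTS + 1)]

#: Centered unit-spaced weights for the linear slope contrast.
SLOPE_WEIGHTS = np.arange(1, N_ELEMENTS + 1, dtype=float) - (N_ELEMENTS + 1) / 2.0

INLYING = (3, 4, 5, 6)
OUTLYING = (1, 2, 7, 8)


def rank_hues(trials: pd.DataFrame) -> pd.DataFrame:
    """Sort each trial's hues ascending into rank columns (rank 1 = bluest)."""
    hues = trials[HUE_COLUMNS].to_numpy(dtype=float)
    ranked = np.sort(hues, axis=1)
    out = trials.copy()
    out[RANK_COLUMNS] = ranked
    return out


def incongruent_positions(category: int) -> tuple[int, ...]:
    """Hue ranks carrying stimulus-incongruent evidence for a category."""
    if category == 1:  # red: the bluest four elements oppose the category
        return (1, 2, 3, 4)
    if category == -1:
        return (5, 6, 7, 8)
    raise ValueError("category must be -1 or +1")


@dataclass(frozen=True)
class ContrastResult:
    """A linear contrast on the eight rank coefficients."""

    estimate: float
    se: float
    z_or_t: float
    p_value: float
    contrast_kind: str

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se <= 0:
            raise ValueError("contrast standard error must be positive when estimable")


@dataclass
class RegressionFit:
    """Hue-rank regression coefficients for one split of the data.

    ``betas``/``ses``/``cov`` cover the eight rank predictors (the
    intercept is excluded); ``orientation`` is the sign applied to the
    betas before the slope and congruency contrasts (the category sign
    for confidence fits, +1 for choice fits).
    """

    betas: np.ndarray
    ses: np.ndarray
    cov: np.ndarray
    kind: str  # 'choice-logistic' or 'confidence-linear'
    split_label: int
    goodness: float
    n_obs: int
    df_resid: float
    orientation: int = 1
    separation_flag: bool = False

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (N_ELEMENTS,):
            raise ValueError("a rank regression has exactly 8 coefficients")
        if self.n_obs <= N_ELEMENTS:
            raise ValueError("need more observations than predictors")

    @property
    def oriented_betas(self) -> np.ndarray:
        return self.orientation * self.betas

    def _wald(self, w: np.ndarray, kind: str, *, oriented: bool) -> ContrastResult:
        if not np.all(np.isfinite(self.cov)):
            raise ValueError("singular or undefined coefficient covariance")
        sign = self.orientation if oriented else 1
        est = float(sign * w @ self.betas)
        var = float(w @ self.cov @ w)
        if var <= 0:
            raise ValueError("singular coefficient covariance for contrast")
        se = float(np.sqrt(var))
        stat = est / se
        if self.kind == "confidence-linear":
            p = 2 * stats.t.sf(abs(stat), self.df_resid)
        else:
            p = 2 * stats.norm.sf(abs(stat))
        return ContrastResult(est, se, stat, float(p), kind)

    def slope_contrast(self) -> ContrastResult:
        """Linear trend of the (oriented) coefficients across hue ranks."""
        return self._wald(SLOPE_WEIGHTS, "slope", oriented=self.kind == "confidence-linear")

    def congruency_contrast(self, category: int | None = None) -> ContrastResult:
        """Incongruent-minus-congruent mean weight (RIE is positive).

        ``category`` defaults to the fit's split label.
        """
        category = self.split_label if category is None else category
        incon = incongruent_positions(category)
        w = np.array([1.0 / 4 if i in incon else -1.0 / 4 for i in range(1, 9)])
        return self._wald(w, "congruency", oriented=self.kind == "confidence-linear")

    def inlying_outlying_contrast(self) -> ContrastResult:
        """Inlying (ranks 3-6) minus outlying (1-2, 7-8) mean weight, raw betas."""
        w = np.array([1.0 / 4 if i in INLYING else -1.0 / 4 for i in range(1, 9)])
        return self._wald(w, "inlying_outlying", oriented=False)

    def plot(self, ax=None):
        """Plot coefficients (with +-1 SE bars) against hue rank."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ranks = np.arange(1, N_ELEMENTS + 1)
        ax.errorbar(ranks, self.betas, yerr=self.ses, marker="o")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("hue rank (1 = bluest)")
        ax.set_ylabel(f"{self.kind} weight")
        ax.set_title(f"split = {self.split_label}")
        return ax


def _fit_one(ranked: pd.DataFrame, dv: str, split_value: int) -> RegressionFit:
    X = sm.add_constant(ranked[RANK_COLUMNS].to_numpy(dtype=float))
    separation = False
    if dv == "choice":
        y = (ranked["choice"].to_numpy() == 1).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            except Exception:
                separation = True
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        if not separation and np.abs(res.params).max() > 1e3:
            separation = True
        if separation:
            warnings.warn(
                f"possible perfect separation in choice fit (split={split_value}); "
                "coefficients are unreliable"
            )
        goodness = float(1 - res.llf / res.llnull) if hasattr(res, "llnull") else np.nan
        kind = "choice-logistic"
        df_resid = np.inf
    else:
        y = ranked["confidence"].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        goodness = float(res.rsquared)
        kind = "confidence-linear"
        df_resid = float(res.df_resid)
    return RegressionFit(
        betas=np.asarray(res.params)[1:],
        ses=np.asarray(res.bse)[1:],
        cov=np.asarray(res.cov_params())[1:, 1:],
        kind=kind,
        split_label=int(split_value),
        goodness=goodness,
        n_obs=len(ranked),
        df_resid=df_resid,
        orientation=int(split_value) if dv == "confidence" else 1,
        separation_flag=separation,
    )


def fit_rank_regression(
    trials: pd.DataFrame,
    dv: str = "confidence",
    split_by: str = "category",
) -> dict[int, RegressionFit]:
    """Regress choice or confidence on the eight ranked hues per split.

    Returns a mapping from split value (-1/+1) to its :class:`RegressionFit`.
    Logistic link for ``dv='choice'``, identity for ``dv='confidence'``;
    predictors are the raw (unstandardised) ranked hues plus an intercept.
    """
    if dv not in ("choice", "confidence"):
        raise ValueError("dv must be 'choice' or 'confidence'")
    if split_by not in ("category", "response"):
        raise ValueError("split_by must be 'category' or 'response'")
    split_col = "category" if split_by == "category" else "choice"
    ranked = rank_hues(trials)
    fits: dict[int, RegressionFit] = {}
    for value, part in ranked.groupby(split_col):
        if len(part) < 200:
            warnings.warn(f"only {len(part)} trials in split {split_col}={value}")
        fits[int(value)] = _fit_one(part, dv, int(value))
    return fits


def drop_one_r2(
    trials: pd.DataFrame,
    split_by: str = "category",
) -> pd.DataFrame:
    """Stepwise confidence regressions each omitting one hue rank.

    Returns a tidy table with, per split and dropped rank, the 7-predictor
    R^2 and its drop from the full 8-predictor model.  Large drops for the
    incongruent-side ranks are the RIE signature in explained variance.
    """
    split_col = "category" if split_by == "category" else "choice"
    if split_by not in ("category", "response"):
        raise ValueError("split_by must be 'category' or 'response'")
    ranked = rank_hues(trials)
    rows = []
    for value, part in ranked.groupby(split_col):
        if len(part) < 9 * (N_ELEMENTS + 1):
            warnings.warn(f"few trials ({len(part)}) for drop-one analysis in split {value}")
        y = part["confidence"].to_numpy(dtype=float)
        X_full = sm.add_constant(part[RANK_COLUMNS].to_numpy(dtype=float))
        r2_full = float(sm.OLS(y, X_full).fit().rsquared)
        for dropped in range(1, N_ELEMENTS + 1):
            keep = [c for c in RANK_COLUMNS if c != f"rank_{dropped}"]
            X = sm.add_constant(part[keep].to_numpy(dtype=float))
            r2 = float(sm.OLS(y, X).fit().rsquared)
            rows.append(
                {
                    "split": int(value),
                    "dropped_rank": dropped,
                    "r2": r2,
                    "r2_full": r2_full,
                    "delta_r2": r2_full - r2,
                }
            )
    return pd.DataFrame(rows)


def contrast_table(fits: dict[int, RegressionFit], include_inlying: bool = False) -> pd.DataFrame:
    """Tidy table of planned contrasts across splits."""
    rows = []
    for value, fit in sorted(fits.items()):
        contrasts = [fit.slope_contrast(), fit.congruency_contrast()]
        if include_inlying:
            contrasts.append(fit.inlying_outlying_contrast())
        for c in contrasts:
            rows.append(
                {
                    "split": value,
                    "kind": fit.kind,
                    "contrast": c.contrast_kind,
                    "estimate": c.estimate,
                    "se": c.se,
                    "stat": c.z_or_t,
                    "p_value": c.p_value,
                }
            )
    return pd.DataFrame(rows)
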