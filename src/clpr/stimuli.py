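"""Synthetic stimuli for the multi-element color-averaging task.

Each trial presents eight colored elements whose hues live on a scale
rescaled to [-0.5, 0.5], symmetric around the category boundary at 0
(negative = blue, positive = red).  Difficulty is manipulated factorially
by the distance of the mean hue from the boundary (``mean_levels``) and by
the spread of the elements around that mean (``variance_levels``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HUE_MIN = -0.5
HUE_MAX = 0.5
N_ELEMENTS = 8

HUE_COLUMNS = [f"hue_{i}" for i in range(1, N_ELEMENTS + 1)]

#: Default factorial design: accuracy in the 70-90% band typical of the task.
DEFAULT_MEAN_LEVELS = (0.03, 0.06)
DEFAULT_VARIANCE_LEVELS = (0.05, 0.15)


@dataclass(frozen=True)
class StimulusDesign:
    """Factorial stimulus design (category x mean level x variance level).

    Parameters
    ----------
    mean_levels
        Unsigned distances of the category mean from the boundary, in hue
        units.  All must be positive.
    variance_levels
        Standard deviations of the element distribution, in hue units,
        strictly ascending so that ``variance_levels[0]`` is the lowest
        variance condition (the metanoise reference level).
    boundary
        Hue value of the category boundary (0 in rescaled hue space).
    n_per_cell
        Trials per (category, mean level, variance level) cell.
    """

    mean_levels: tuple[float, ...] = DEFAULT_MEAN_LEVELS
    variance_levels: tuple[float, ...] = DEFAULT_VARIANCE_LEVELS
    boundary: float = 0.0
    n_per_cell: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_levels", tuple(float(m) for m in self.mean_levels))
        object.__setattr__(self, "variance_levels", tuple(float(v) for v in self.variance_levels))
        if len(self.mean_levels) == 0 or len(self.variance_levels) == 0:
            raise ValueError("mean_levels and variance_levels must be non-empty")
        if any(m <= 0 for m in self.mean_levels):
            raise ValueError("all mean levels must be positive hue distances")
        if any(v < 0 for v in self.variance_levels):
            raise ValueError("variance levels must be non-negative")
        diffs = np.diff(self.variance_levels)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("variance_levels must be strictly ascending")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be at least 1")

    @property
    def n_cells(self) -> int:
        return 2 * len(self.mean_levels) * len(self.variance_levels)

    @property
    def n_trials(self) -> int:
        return self.n_cells * self.n_per_cell

    @property
    def var_floor(self) -> float:
        """Lowest variance level (reference for variance-scaled metanoise)."""
        return self.variance_levels[0]


@dataclass(frozen=True)
class Stimulus:
    """A single eight-element stimulus with boundary-relative hues."""

    hues: np.ndarray
    category: int
    mean_level: int = 1
    var_level: int = 1
    mu: float = field(default=np.nan)
    sigma: float = field(default=np.nan)

    def __post_init__(self) -> None:
        hues = np.asarray(self.hues, dtype=float)
        if hues.shape != (N_ELEMENTS,):
            raise ValueError(f"a stimulus has exactly {N_ELEMENTS} hues, got shape {hues.shape}")
        if self.category not in (-1, 1):
            raise ValueError("category must be -1 (blue) or +1 (red)")
        object.__setattr__(self, "hues", hues)


def generate_stimulus(
    category: int,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
    *,
    exact_mean: bool = True,
) -> Stimulus:
    """Draw one stimulus: 8 hues ~ Normal(category*mu, sigma).

    With ``exact_mean`` (default) the draws are re-centered so the sample
    mean equals ``category*mu`` exactly, emulating the tightly controlled
    stimulus sets of the task; hues are then clipped to [-0.5, 0.5].
    Clipping after re-centering can slightly bias extreme cells; this is
    accepted for simplicity.
    """
    if category not in (-1, 1):
        raise ValueError("category must be -1 or +1")
    if mu <= 0:
        raise ValueError("mu must be a positive distance from the boundary")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    target = category * mu
    hues = rng.normal(target, sigma, size=N_ELEMENTS)
    if exact_mean:
        hues = hues - hues.mean() + target
    hues = np.clip(hues, HUE_MIN, HUE_MAX)
    return Stimulus(hues=hues, category=category, mu=mu, sigma=sigma)


def generate_design_set(
    design: StimulusDesign,
    rng: np.random.Generator,
    *,
    exact_mean: bool = True,
) -> pd.DataFrame:
    """Generate a balanced stimulus table for a factorial design.

    Returns a trial table with one row per stimulus and columns
    ``hue_1..hue_8, category, mean_level, var_level, mu, sigma``
    (levels are 1-based indices into the design).  Cell order and hue
    draws are deterministic under a fixed generator state.
    """
    rows = []
    for category in (-1, 1):
        for k, mu in enumerate(design.mean_levels, start=1):
            for j, sigma in enumerate(design.variance_levels, start=1):
                target = category * mu
                hues = rng.normal(target, sigma, size=(design.n_per_cell, N_ELEMENTS))
                if exact_mean:
                    hues = hues - hues.mean(axis=1, keepdims=True) + target
                hues = np.clip(hues, HUE_MIN, HUE_MAX)
                cell = pd.DataFrame(hues, columns=HUE_COLUMNS)
                cell["category"] = category
                cell["mean_level"] = k
                cell["var_level"] = j
                cell["mu"] = mu
                cell["sigma"] = sigma
                rows.append(cell)
    table = pd.concat(rows, ignore_index=True)
    table.insert(0, "trial", np.arange(1, len(table) + 1))
    return table


def shift_boundary(stimuli: pd.DataFrame, new_boundary: float) -> pd.DataFrame:
    """Re-express hues relative to a shifted category boundary.

    Hues become ``C_i - new_boundary`` and categories are re-derived from
    the sign of the new boundary-relative sample mean (mean > 0 -> red,
    otherwise blue, matching the choice-rule tie convention).  The input
    table is left unchanged; the shift is exactly invertible.
    """
    hues = stimuli[HUE_COLUMNS].to_numpy(dtype=float) - new_boundary
    if np.any((hues < HUE_MIN) | (hues > HUE_MAX)):
        raise ValueError(
            "boundary shift pushes hues outside the representable range "
            f"[{HUE_MIN}, {HUE_MAX}]"
        )
    out = stimuli.copy()
    out[HUE_COLUMNS] = hues
    rel_mean = hues.mean(axis=1)
    out["category"] = np.where(rel_mean > 0, 1, -1)
    return out
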