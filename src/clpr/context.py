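"""Boundary-shift (color context) experiment simulation.

The model predicts that the weighting of evidence in confidence follows
the *currently active* category boundary: physically identical "purple"
stimuli should show opposite confidence-weight slopes when judged in a
Blue Context (purple vs blue, boundary shifted toward blue) versus a Red
Context (purple vs red, boundary shifted toward red).

:func:`simulate_context_study` builds one shared purple stimulus set and
two flanker sets at -offset and +offset, places the boundary at the
midpoint of each context's pair, simulates responses with hues expressed
relative to the active boundary, and returns the two trial tables with
their physical (context-independent) hues.  :func:`context_flip_test`
fits the confidence rank regression to the purple trials of each context
and reports whether the slope contrast flips sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ConfidenceCriteria, ModelParams, simulate_dataset
from .regression import ContrastResult, fit_rank_regression
from .stimuli import HUE_COLUMNS, HUE_MAX, HUE_MIN, N_ELEMENTS, shift_boundary


def _stimulus_block(
    center: float, sigma: float, n: int, rng: np.random.Generator, label: str,
    margin: float = 0.0,
) -> pd.DataFrame:
    # physical hues are kept a boundary-shift away from the scale limits so
    # they stay representable relative to either context's boundary
    hues = rng.normal(center, sigma, size=(n, N_ELEMENTS))
    hues = hues - hues.mean(axis=1, keepdims=True) + center
    hues = np.clip(hues, HUE_MIN + margin, HUE_MAX - margin)
    block = pd.DataFrame(hues, columns=HUE_COLUMNS)
    block["stimulus_type"] = label
    block["sigma"] = sigma
    return block


def simulate_context_study(
    params: ModelParams,
    offset: float = 0.1,
    n_per_cell: int = 150,
    seed: int | None = None,
    *,
    sigma: float = 0.1,
    criteria: ConfidenceCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the two-context boundary-shift study.

    Purple stimuli are centered at physical hue 0; blue flankers at
    ``-offset`` and red flankers at ``+offset``.  The Blue Context pairs
    purple with the blue set under a boundary at ``-offset/2``; the Red
    Context pairs purple with the red set under ``+offset/2``.  The purple
    hue vectors are bit-identical across the two returned tables.

    ``n_per_cell`` trials are simulated per stimulus type per context
    (the reference study used 150 + 150 = 300 trials per context).
    Returns ``(blue_context, red_context)`` trial tables carrying the
    physical hues, ``context``, ``boundary``, ``stimulus_type``,
    ``category`` (boundary-relative), ``choice``, ``confidence`` and
    ``accuracy`` columns.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if offset / 2 + 4 * sigma > HUE_MAX - HUE_MIN:
        raise ValueError("offset too large for the representable hue range")
    rng = np.random.default_rng(seed)
    margin = offset / 2
    purple = _stimulus_block(0.0, sigma, n_per_cell, rng, "purple", margin)
    blue = _stimulus_block(-offset, sigma, n_per_cell, rng, "flanker", margin)
    red = _stimulus_block(+offset, sigma, n_per_cell, rng, "flanker", margin)

    sim_rng = rng.spawn(2)
    tables = []
    for name, flanker, boundary, child in (
        ("blue", blue, -offset / 2, sim_rng[0]),
        ("red", red, +offset / 2, sim_rng[1]),
    ):
        physical = pd.concat([purple, flanker], ignore_index=True)
        physical["category"] = 0  # placeholder, re-derived after the shift
        relative = shift_boundary(physical, boundary)
        responses = simulate_dataset(relative, params, child, criteria=criteria)
        out = physical.copy()
        out["category"] = relative["category"]
        out["context"] = name
        out["boundary"] = boundary
        out["choice"] = responses["choice"]
        out["confidence"] = responses["confidence"]
        out["accuracy"] = responses["accuracy"]
        tables.append(out)
    return tables[0], tables[1]


@dataclass
class ContextFlipResult:
    """Per-context purple-trial confidence slopes and the flip verdict."""

    blue_slope: ContrastResult
    red_slope: ContrastResult
    flip: bool
    reliable: bool

    def to_dict(self) -> dict:
        return {
            "blue_slope": vars(self.blue_slope),
            "red_slope": vars(self.red_slope),
            "flip": self.flip,
            "reliable": self.reliable,
        }


def context_flip_test(
    blue_table: pd.DataFrame,
    red_table: pd.DataFrame,
    *,
    z_threshold: float = 2.0,
) -> ContextFlipResult:
    """Test whether the purple-trial confidence slope flips across contexts.

    Fits the confidence hue-rank regression to the purple trials of each
    context (split by the boundary-relative category, which orients the
    slope) and flags a flip when the two slope estimates have opposite
    signs.  The result is marked unreliable when either slope fails to
    reach ``z_threshold`` in absolute value, e.g. under shuffled
    confidence ratings.
    """
    slopes = {}
    for name, table in (("blue", blue_table), ("red", red_table)):
        purple = table[table["stimulus_type"] == "purple"]
        if len(purple) == 0:
            raise ValueError(f"no purple trials in the {name}-context table")
        cat = int(np.sign(purple["category"].sum())) or 1
        fits = fit_rank_regression(purple, dv="confidence", split_by="category")
        slopes[name] = fits[cat].slope_contrast()
    flip = np.sign(slopes["blue"].estimate) != np.sign(slopes["red"].estimate)
    reliable = all(abs(s.z_or_t) >= z_threshold for s in slopes.values())
    return ContextFlipResult(
        blue_slope=slopes["blue"], red_slope=slopes["red"], flip=bool(flip),
        reliable=bool(reliable),
    )
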