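"""Generative machinery of the seven c-LPR model variants.

The confidence-extended log-posterior-ratio (c-LPR) family assumes that the
eight element hues C_i of a stimulus are passed through a transfer function
(sigmoidal compression or a linear map), noisily averaged into a decision
variable DV1, compared against zero to produce the choice x, further
corrupted into DV2 by metacognitive noise, and finally binned into a
six-point confidence rating by a fixed set of criteria.

Variants
--------
=======  ========  ==========================================  ====
variant  transfer  free parameters                              df
=======  ========  ==========================================  ====
1        sigmoid   d, decnoise, metanoise, scalemetanoise       4
2        sigmoid   d, decnoise, metanoise                       3
3        linear    d, decnoise, metanoise                       3
4        sigmoid   d, decnoise            (metanoise=decnoise)  2
5        linear    d, decnoise, scalemetanoise (meta=decnoise)  3
6        linear    d, decnoise            (metanoise=decnoise)  2
7        sigmoid   d, decnoise   (RCE confidence, meta=dec)     2
=======  ========  ==========================================  ====

Variant 7 hard-codes the positive-evidence bias (response-congruent
evidence, RCE): element-level noise, choice from the compressed mean, but
confidence from the summed *raw* choice-congruent elements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stimuli import HUE_COLUMNS, N_ELEMENTS, Stimulus

#: Fixed confidence criteria for x = +1, highest first; mirrored for x = -1.
DEFAULT_CRITERIA = (0.60, 0.35, 0.10, -0.15, -0.40)

_VARIANT_FREE = {
    1: ("d", "decnoise", "metanoise", "scalemetanoise"),
    2: ("d", "decnoise", "metanoise"),
    3: ("d", "decnoise", "metanoise"),
    4: ("d", "decnoise"),
    5: ("d", "decnoise", "scalemetanoise"),
    6: ("d", "decnoise"),
    7: ("d", "decnoise"),
}

_LINEAR_VARIANTS = frozenset({3, 5, 6})
_RCE_VARIANT = 7


@dataclass(frozen=True)
class ConfidenceCriteria:
    """Fixed confidence criteria (not fitted, shared across participants).

    ``thresholds`` are the five finite criteria for x = +1 in strictly
    descending order; confidence c requires DV2 to exceed the (7-c)-th
    ascending edge.  For x = -1 the criteria are multiplied by -1, which
    is implemented by binning -DV2 against the same thresholds.
    """

    thresholds: tuple[float, ...] = DEFAULT_CRITERIA

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.thresholds)
        if len(t) != 5 or not all(a > b for a, b in zip(t, t[1:])):
            raise ValueError("criteria must be 5 strictly descending thresholds")
        object.__setattr__(self, "thresholds", t)

    @property
    def ascending_edges(self) -> np.ndarray:
        """The five finite bin edges in ascending order."""
        return np.array(self.thresholds[::-1], dtype=float)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one c-LPR variant.

    Parameters
    ----------
    variant
        Model variant, 1-7 (see module docstring).
    d
        Compression: slope scale of the transfer function, in hue units.
        Small d compresses extreme hues strongly and heightens sensitivity
        at the category boundary.
    decnoise
        SD of the Gaussian noise on the averaged decision variable
        (element-level noise for variant 7), in DV units.
    metanoise
        SD of the additional metacognitive noise on DV2.  Free only for
        variants 1-3; for variants 4-7 it is fixed to ``decnoise`` and
        must be left at None.
    scalemetanoise
        Unitless coefficient scaling metanoise with the excess of the
        condition's element spread over the lowest spread.  Free only for
        variants 1 and 5; zero otherwise.
    eq4_literal
        If True, use the literal printed metanoise rule in which the whole
        noise term is multiplied by ``(var_j - var_1) * scalemetanoise``
        (no metacognitive noise at the lowest variance level).  Default
        False: baseline metanoise is always present and the variance-scaled
        term is the *additional* noise,
        ``SD = metanoise * (1 + (var_j - var_1) * scalemetanoise)``.
    """

    variant: int
    d: float
    decnoise: float
    metanoise: float | None = None
    scalemetanoise: float = 0.0
    eq4_literal: bool = False

    def __post_init__(self) -> None:
        if self.variant not in _VARIANT_FREE:
            raise ValueError(f"variant must be 1-7, got {self.variant}")
        if self.d <= 0:
            raise ValueError("compression d must be positive")
        if self.decnoise < 0:
            raise ValueError("decnoise must be non-negative")
        free = _VARIANT_FREE[self.variant]
        if "metanoise" in free:
            if self.metanoise is None:
                raise ValueError(f"variant {self.variant} requires metanoise")
            if self.metanoise < 0:
                raise ValueError("metanoise must be non-negative")
        elif self.metanoise is not None:
            raise ValueError(
                f"variant {self.variant} fixes metanoise = decnoise; leave it None"
            )
        if "scalemetanoise" in free:
            if self.scalemetanoise < 0:
                raise ValueError("scalemetanoise must be non-negative")
        elif self.scalemetanoise != 0.0:
            raise ValueError(f"variant {self.variant} has no scalemetanoise")

    @property
    def transfer(self) -> str:
        return "linear" if self.variant in _LINEAR_VARIANTS else "sigmoidal"

    @property
    def free_names(self) -> tuple[str, ...]:
        return _VARIANT_FREE[self.variant]

    @property
    def k_free(self) -> int:
        return len(self.free_names)

    @property
    def metanoise_effective(self) -> float:
        """Baseline metanoise SD (equals decnoise where metanoise is fixed)."""
        return self.decnoise if self.metanoise is None else self.metanoise

    def metanoise_sd(self, var_j: float, var_1: float) -> float:
        """Effective metacognitive-noise SD in variance condition ``var_j``.

        ``var_1`` is the lowest element-spread in the design; no
        variance-scaled noise is added in that condition.
        """
        if var_j < var_1:
            raise ValueError("var_j must not be below the lowest variance level var_1")
        base = self.metanoise_effective
        scale = (var_j - var_1) * self.scalemetanoise
        return base * scale if self.eq4_literal else base * (1.0 + scale)

    @property
    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in self.free_names], dtype=float)

    @classmethod
    def from_free(cls, variant: int, theta, **kwargs) -> "ModelParams":
        """Build params from a free-parameter vector in canonical order."""
        names = _VARIANT_FREE.get(variant)
        if names is None:
            raise ValueError(f"variant must be 1-7, got {variant}")
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(names),):
            raise ValueError(f"variant {variant} expects {len(names)} free parameters")
        return cls(variant=variant, **dict(zip(names, theta)), **kwargs)

    def with_(self, **changes) -> "ModelParams":
        return replace(self, **changes)


def variant_free_names(variant: int) -> tuple[str, ...]:
    if variant not in _VARIANT_FREE:
        raise ValueError(f"variant must be 1-7, got {variant}")
    return _VARIANT_FREE[variant]


def sigmoid_transfer(C, d: float):
    """Sigmoidal compression E = -1 + 2 / (1 + exp(-C/d)) = tanh(C / (2d))."""
    if d <= 0:
        raise ValueError("compression d must be positive")
    return np.tanh(np.asarray(C, dtype=float) / (2.0 * d))


def linear_transfer(C, d: float):
    """Linear map E = clip(C/d, -1, 1); d = 0.5 maps the full hue range onto [-1, 1]."""
    if d <= 0:
        raise ValueError("compression d must be positive")
    return np.clip(np.asarray(C, dtype=float) / d, -1.0, 1.0)


def transfer(C, params: ModelParams):
    fn = linear_transfer if params.transfer == "linear" else sigmoid_transfer
    return fn(C, params.d)


def compute_dv1(E, decnoise: float, rng: np.random.Generator) -> float:
    """Noisy average of the transferred elements: mean(E) + N(0, decnoise)."""
    E = np.asarray(E, dtype=float)
    if E.shape != (N_ELEMENTS,):
        raise ValueError(f"E must have length {N_ELEMENTS}")
    return float(E.mean() + rng.normal(0.0, decnoise))


def choose(dv1) -> int:
    """Choice rule: x = 1 if DV1 > 0 else -1 (ties at zero go to -1)."""
    return np.where(np.asarray(dv1) > 0, 1, -1)[()] if np.ndim(dv1) else (1 if dv1 > 0 else -1)


def compute_dv2(
    dv1: float,
    params: ModelParams,
    var_j: float,
    var_1: float,
    rng: np.random.Generator,
) -> float:
    """Metacognitively degraded decision variable DV2 = DV1 + scaled noise."""
    s = params.metanoise_sd(var_j, var_1)
    return float(dv1 + rng.normal(0.0, s))


def map_confidence(dv2, x, criteria: ConfidenceCriteria | None = None):
    """Bin DV2 into a 1-6 confidence rating against the fixed criteria.

    Bins are lower-exclusive / upper-inclusive: DV2 must strictly exceed an
    edge to move up a bin.  For x = -1 the sign-mirrored criteria are used.
    """
    criteria = criteria or ConfidenceCriteria()
    edges = criteria.ascending_edges
    dv2 = np.asarray(dv2, dtype=float)
    x = np.asarray(x)
    if not np.all(np.isin(x, (-1, 1))):
        raise ValueError("x must be -1 or +1")
    oriented = np.where(x == 1, dv2, -dv2)
    conf = 1 + (oriented[..., None] > edges).sum(axis=-1)
    return conf if conf.ndim else int(conf)


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated response with its internal diagnostic variables."""

    x: int
    confidence: int
    E: np.ndarray
    dv1: float
    dv2: float
    congruent_sum: float = np.nan

    def __post_init__(self) -> None:
        if self.x not in (-1, 1):
            raise ValueError("x must be -1 or +1")
        if not 1 <= self.confidence <= 6:
            raise ValueError("confidence must be in 1..6")


def simulate_trial(
    stimulus: Stimulus,
    params: ModelParams,
    rng: np.random.Generator,
    *,
    var_j: float | None = None,
    var_1: float | None = None,
    criteria: ConfidenceCriteria | None = None,
) -> TrialOutcome:
    """Simulate one trial under any variant.

    ``var_j``/``var_1`` (element-spread of the trial's condition and of the
    lowest-variance condition) default to the stimulus's own sigma, i.e. no
    variance-scaled metanoise; they only matter for variants 1 and 5.
    """
    criteria = criteria or ConfidenceCriteria()
    if var_j is None:
        var_j = stimulus.sigma if np.isfinite(stimulus.sigma) else 0.0
    if var_1 is None:
        var_1 = var_j
    C = stimulus.hues
    if params.variant == _RCE_VARIANT:
        E = C + rng.normal(0.0, params.decnoise, size=N_ELEMENTS)
        dv1 = float(sigmoid_transfer(E, params.d).mean())
        x = choose(dv1)
        congruent = E[(E > 0) == (x == 1)]
        congruent_sum = float(congruent.sum())
        dv2 = float(congruent_sum + rng.normal(0.0, params.metanoise_effective))
        conf = map_confidence(dv2, x, criteria)
        return TrialOutcome(x=x, confidence=conf, E=E, dv1=dv1, dv2=dv2,
                            congruent_sum=congruent_sum)
    E = transfer(C, params)
    dv1 = compute_dv1(E, params.decnoise, rng)
    x = choose(dv1)
    dv2 = compute_dv2(dv1, params, var_j, var_1, rng)
    conf = map_confidence(dv2, x, criteria)
    return TrialOutcome(x=x, confidence=conf, E=E, dv1=dv1, dv2=dv2)


def simulate_dataset(
    stimuli: pd.DataFrame,
    params: ModelParams,
    rng: np.random.Generator,
    *,
    criteria: ConfidenceCriteria | None = None,
    var_floor: float | None = None,
    diagnostics: bool = False,
) -> pd.DataFrame:
    """Vectorised simulation of responses to a stimulus table.

    The table must carry ``hue_1..hue_8``, ``category`` and (for the
    variance-scaled metanoise models) a ``sigma`` column with the element
    spread of each trial's condition.  ``var_floor`` is the lowest spread
    in the design (defaults to the table's minimum sigma).

    Returns a copy with ``choice``, ``confidence`` and ``accuracy`` columns
    (plus ``dv1``/``dv2`` when ``diagnostics``).
    """
    criteria = criteria or ConfidenceCriteria()
    C = stimuli[HUE_COLUMNS].to_numpy(dtype=float)
    n = len(stimuli)
    if "sigma" in stimuli.columns:
        sigma = stimuli["sigma"].to_numpy(dtype=float)
    else:
        sigma = np.zeros(n)
    if var_floor is None:
        var_floor = float(sigma.min()) if n else 0.0

    if params.variant == _RCE_VARIANT:
        E = C + rng.normal(0.0, params.decnoise, size=C.shape)
        dv1 = sigmoid_transfer(E, params.d).mean(axis=1)
        x = np.where(dv1 > 0, 1, -1)
        congruent = np.where((E > 0) == (x[:, None] == 1), E, 0.0)
        dv2 = congruent.sum(axis=1) + rng.normal(0.0, params.metanoise_effective, size=n)
    else:
        E = transfer(C, params)
        dv1 = E.mean(axis=1) + rng.normal(0.0, params.decnoise, size=n)
        x = np.where(dv1 > 0, 1, -1)
        s = np.array([params.metanoise_sd(v, var_floor) for v in sigma]) \
            if params.scalemetanoise != 0.0 or params.eq4_literal \
            else np.full(n, params.metanoise_effective)
        dv2 = dv1 + rng.normal(0.0, 1.0, size=n) * s

    conf = map_confidence(dv2, x, criteria)
    out = stimuli.copy()
    out["choice"] = x
    out["confidence"] = conf
    out["accuracy"] = (out["choice"] == out["category"]).astype(int)
    if diagnostics:
        out["dv1"] = dv1
        out["dv2"] = dv2
    return out
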