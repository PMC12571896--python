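"""Closed-form choice and confidence probabilities for variants 1-6.

For those variants the pair (DV1, DV2) given a stimulus is bivariate
normal: both are centered on m = mean(E), with variances e1^2 and
e1^2 + s^2 and covariance e1^2, where e1 is decnoise and s the effective
metanoise SD of the trial's variance condition.  Choice and confidence
probabilities are therefore exact bivariate normal orthant/strip
probabilities, which gives a deterministic, noise-free objective for model
fitting and an independent check on the trial simulator.

Variant 7 adds noise per element before the nonlinearity, so its cell
means have no single-integral closed form and must be simulated.

The bivariate normal CDF is evaluated with a vectorised Owen's-T
construction (scipy.special.owens_t); scipy's ``multivariate_normal.cdf``
computes the same quantity by per-point quadrature and is used as the
reference in tests, but is orders of magnitude too slow inside an
optimisation loop.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t
from scipy.optimize import brentq

from .model import ConfidenceCriteria, ModelParams, transfer
from .stimuli import HUE_COLUMNS, Stimulus

_TINY = 1e-12
_CONF_LEVELS = np.arange(1, 7, dtype=float)


def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Vectorised over ``h`` and ``k`` (broadcast); ``rho`` must be scalar.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(np.clip(rho, -1.0, 1.0))
    if rho >= 1.0 - _TINY:
        return ndtr(np.minimum(h, k))
    if rho <= -1.0 + _TINY:
        return np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0)
    # nudge exact zeros so the Owen's-T formula's sign rules stay valid
    h = np.where(h == 0.0, _TINY, h)
    k = np.where(k == 0.0, _TINY, k)
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    delta = np.where(h * k > 0, 0.0, 0.5)
    return ndtr(h) * 0.5 + ndtr(k) * 0.5 - owens_t(h, a_h) - owens_t(k, a_k) - delta


def _deterministic_pmf(m, s, edges):
    """Joint pmf when decnoise = 0 (DV1 = m exactly)."""
    m = np.atleast_1d(m)
    n = len(m)
    pmf = np.zeros((n, 2, 6))
    x_is_red = m > 0  # tie at 0 -> blue, as in the choice rule
    oriented = np.where(x_is_red, m, -m)
    if s < _TINY:
        conf = 1 + (oriented[:, None] > edges).sum(axis=1)
        pmf[np.arange(n), np.where(x_is_red, 0, 1), conf - 1] = 1.0
    else:
        # DV2 ~ N(m, s); bin the chosen side's mirrored value
        upper = np.concatenate([edges, [np.inf]])
        lower = np.concatenate([[-np.inf], edges])
        strip = ndtr((upper[None, :] - oriented[:, None]) / s) - ndtr(
            (lower[None, :] - oriented[:, None]) / s
        )
        pmf[x_is_red, 0, :] = strip[x_is_red]
        pmf[~x_is_red, 1, :] = strip[~x_is_red]
    return pmf


def joint_pmf(m, decnoise: float, s: float, criteria: ConfidenceCriteria | None = None):
    """Exact joint pmf over (choice, confidence) given DV means ``m``.

    Parameters
    ----------
    m
        Mean transferred evidence per trial (scalar or array).
    decnoise
        SD of the decision noise on DV1.
    s
        Effective metacognitive-noise SD added between DV1 and DV2.

    Returns an array of shape (n, 2, 6): axis 1 indexes choice (0 -> x=+1,
    1 -> x=-1), axis 2 confidence 1..6.
    """
    criteria = criteria or ConfidenceCriteria()
    edges = criteria.ascending_edges
    scalar = np.ndim(m) == 0
    m = np.atleast_1d(np.asarray(m, dtype=float))
    if decnoise < _TINY:
        pmf = _deterministic_pmf(m, s, edges)
        return pmf[0] if scalar else pmf

    sigma2 = np.hypot(decnoise, s)
    h = m / decnoise
    n = len(m)
    # Q[e] = P(DV1 > 0, DV2 > e);  R[e] = P(DV1 <= 0, DV2 < -e)
    if s < _TINY:
        Q = ndtr((m[:, None] - np.maximum(0.0, edges)[None, :]) / decnoise)
        R = ndtr((np.minimum(0.0, -edges)[None, :] - m[:, None]) / decnoise)
    else:
        rho = decnoise / sigma2
        Q = bvn_cdf(h[:, None], (m[:, None] - edges[None, :]) / sigma2, rho)
        R = bvn_cdf(-h[:, None], (-edges[None, :] - m[:, None]) / sigma2, rho)
    p_red = ndtr(h)
    Q = np.concatenate([p_red[:, None], Q, np.zeros((n, 1))], axis=1)
    R = np.concatenate([(1.0 - p_red)[:, None], R, np.zeros((n, 1))], axis=1)
    pmf = np.empty((n, 2, 6))
    pmf[:, 0, :] = np.maximum(Q[:, :-1] - Q[:, 1:], 0.0)
    pmf[:, 1, :] = np.maximum(R[:, :-1] - R[:, 1:], 0.0)
    return pmf[0] if scalar else pmf


def _effective_s(params: ModelParams, var_j, var_1):
    return params.metanoise_sd(float(var_j), float(var_1))


def _require_closed_form(params: ModelParams) -> None:
    if params.variant == 7:
        raise ValueError(
            "variant 7 adds per-element noise before the nonlinearity; "
            "no closed-form oracle exists, use simulation"
        )


def choice_prob_oracle(stimulus: Stimulus, params: ModelParams) -> float:
    """Exact P(x = +1) for a stimulus under variants 1-6.

    Equals Phi(mean(E) / decnoise); for decnoise = 0 it is the step
    function of sign(mean(E)) with the tie at zero going to x = -1.
    """
    _require_closed_form(params)
    m = float(np.mean(transfer(stimulus.hues, params)))
    if params.decnoise < _TINY:
        return 1.0 if m > 0 else 0.0
    return float(ndtr(m / params.decnoise))


def confidence_pmf_oracle(
    stimulus: Stimulus,
    params: ModelParams,
    var_j: float | None = None,
    var_1: float | None = None,
    criteria: ConfidenceCriteria | None = None,
) -> np.ndarray:
    """Exact joint pmf over (choice, confidence) for one stimulus (variants 1-6)."""
    _require_closed_form(params)
    if var_j is None:
        var_j = stimulus.sigma if np.isfinite(stimulus.sigma) else 0.0
    if var_1 is None:
        var_1 = var_j
    m = float(np.mean(transfer(stimulus.hues, params)))
    return joint_pmf(m, params.decnoise, _effective_s(params, var_j, var_1), criteria)


def trial_expectations(
    hues: np.ndarray,
    categories: np.ndarray,
    params: ModelParams,
    sigma: np.ndarray,
    var_floor: float,
    criteria: ConfidenceCriteria | None = None,
):
    """Per-trial expected accuracy and confidence under variants 1-6.

    ``hues`` is (n, 8); ``sigma`` the per-trial condition spread.  Trials
    are processed in groups of equal effective metanoise SD.  Returns
    (p_correct, e_conf) arrays of length n.
    """
    _require_closed_form(params)
    hues = np.asarray(hues, dtype=float)
    categories = np.asarray(categories)
    sigma = np.asarray(sigma, dtype=float)
    m = transfer(hues, params).mean(axis=1)
    p_correct = np.empty(len(m))
    e_conf = np.empty(len(m))
    for sig in np.unique(sigma):
        mask = sigma == sig
        s = _effective_s(params, sig, var_floor)
        pmf = joint_pmf(m[mask], params.decnoise, s, criteria)
        p_red = pmf[:, 0, :].sum(axis=1)
        p_correct[mask] = np.where(categories[mask] == 1, p_red, 1.0 - p_red)
        e_conf[mask] = (pmf * _CONF_LEVELS[None, None, :]).sum(axis=(1, 2))
    return p_correct, e_conf


def expected_cell_means(
    trials,
    params: ModelParams,
    var_floor: float | None = None,
    criteria: ConfidenceCriteria | None = None,
):
    """Oracle-expected accuracy and mean confidence per (mean, variance) cell.

    ``trials`` is a stimulus/trial table with hue columns, ``category``,
    ``mean_level``, ``var_level`` and ``sigma``.  Returns a DataFrame with
    one row per cell and columns ``pACC``/``pCJ``.
    """
    import pandas as pd

    hues = trials[HUE_COLUMNS].to_numpy(dtype=float)
    sigma = trials["sigma"].to_numpy(dtype=float) if "sigma" in trials else np.zeros(len(trials))
    if var_floor is None:
        var_floor = float(sigma.min()) if len(sigma) else 0.0
    p_correct, e_conf = trial_expectations(
        hues, trials["category"].to_numpy(), params, sigma, var_floor, criteria
    )
    frame = pd.DataFrame(
        {
            "mean_level": trials["mean_level"].to_numpy(),
            "var_level": trials["var_level"].to_numpy(),
            "pACC": p_correct,
            "pCJ": e_conf,
        }
    )
    return frame.groupby(["mean_level", "var_level"], as_index=False).mean()


def matched_mean_for_accuracy(
    target_accuracy: float,
    params: ModelParams,
    sigma: float,
    var_floor: float,
    rng: np.random.Generator,
    *,
    n_stimuli: int = 4000,
    mu_bracket: tuple[float, float] = (0.005, 0.25),
) -> float:
    """Find the mean-distance mu whose expected accuracy matches a target.

    Used to construct performance-matched conditions (e.g. the medium
    conditions: low mean/low variance vs high mean/high variance).  The
    expectation is over a fixed seeded stimulus ensemble, so the root
    find is deterministic given the generator state.
    """
    z = rng.normal(size=(n_stimuli, 8))
    z = z - z.mean(axis=1, keepdims=True)

    def acc_at(mu: float) -> float:
        hues = np.clip(mu + sigma * z, -0.5, 0.5)
        cats = np.ones(n_stimuli, dtype=int)
        p, _ = trial_expectations(hues, cats, params, np.full(n_stimuli, sigma), var_floor)
        return float(p.mean())

    lo, hi = mu_bracket
    return brentq(lambda mu: acc_at(mu) - target_accuracy, lo, hi, xtol=1e-6)
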