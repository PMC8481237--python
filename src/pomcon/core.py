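"""Conjugate-Gaussian belief inference over signed motion coherence.

The hidden state of a trial is the signed coherence ``c`` (positive =
rightward). Momentary observations are ``z_t ~ N(c, w_z)``; the agent,
which knows neither ``c`` nor ``w_z``, assumes a Gaussian likelihood with
learned width ``sigma_z`` and a Gaussian prior ``N(0, sigma_0)``, so the
posterior after ``t`` observations is Gaussian with

    sigma_t^2 = 1 / (t / sigma_z^2 + 1 / sigma_0^2)
    mu_t      = (sum_j z_j / sigma_z^2) * sigma_t^2

Confidence in a direction choice is ``Phi(|mu_t| / sigma_t)``, the
posterior mass on the chosen side of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .params import ModelParams

__all__ = [
    "Belief",
    "ActionOutcome",
    "initial_belief",
    "update_belief",
    "belief_from_sum",
    "posterior_sigma",
    "posterior_mu",
    "confidence",
    "believed_p_right",
    "accuracy_zero_cost",
    "select_terminal_action",
]


@dataclass(frozen=True)
class Belief:
    """Gaussian posterior over signed coherence after ``t`` observations.

    ``sum_z`` carries the running observation sum; it doubles as the
    drift-diffusion decision variable ``V_t``.
    """

    mu: float
    sigma: float
    t: int
    sum_z: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"belief sigma must be positive, got {self.sigma}")
        if self.t < 0:
            raise ValueError(f"belief t must be non-negative, got {self.t}")


@dataclass(frozen=True)
class ActionOutcome:
    """A terminal action and, for direction choices, its confidence."""

    action: str  # one of {"left", "right", "sure"}
    confidence: float | None


def posterior_sigma(t, params: ModelParams):
    """Posterior standard deviation after ``t`` observations (closed form)."""
    t = np.asarray(t, dtype=float)
    return 1.0 / np.sqrt(t / params.sigma_z**2 + 1.0 / params.sigma_0**2)


def posterior_mu(sum_z, t, params: ModelParams):
    """Posterior mean from the observation sum (closed form, ``mu_0 = 0``)."""
    t = np.asarray(t, dtype=float)
    sum_z = np.asarray(sum_z, dtype=float)
    return (sum_z / params.sigma_z**2) / (t / params.sigma_z**2 + 1.0 / params.sigma_0**2)


def initial_belief(params: ModelParams) -> Belief:
    """The prior belief ``N(0, sigma_0)`` before any observation."""
    return Belief(mu=params.mu_0, sigma=params.sigma_0, t=0, sum_z=0.0)


def update_belief(belief: Belief, z: float, params: ModelParams) -> Belief:
    """Absorb one observation ``z`` into the belief (recursive form).

    The recursive precision-weighted update and the closed form over the
    observation sum agree to floating-point accuracy; properties of both
    are exercised in the test suite.
    """
    z = float(z)
    if not math.isfinite(z):
        raise ValueError(f"observation must be finite, got {z}")
    s2 = belief.sigma**2
    sz2 = params.sigma_z**2
    mu_new = (s2 * z + sz2 * belief.mu) / (s2 + sz2)
    sigma_new = math.sqrt(s2 * sz2 / (s2 + sz2))
    return Belief(mu=mu_new, sigma=sigma_new, t=belief.t + 1, sum_z=belief.sum_z + z)


def belief_from_sum(sum_z: float, t: int, params: ModelParams) -> Belief:
    """Construct the posterior directly from the observation sum."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    return Belief(
        mu=float(posterior_mu(sum_z, t, params)),
        sigma=float(posterior_sigma(t, params)),
        t=int(t),
        sum_z=float(sum_z),
    )


def confidence(belief: Belief) -> float:
    """Posterior probability that the maximum-belief direction is correct.

    Equals ``Phi(|mu| / sigma)``; lies in ``[0.5, 1)`` and is exactly 0.5
    for a symmetric (``mu = 0``) belief.
    """
    return float(norm.cdf(abs(belief.mu) / belief.sigma))


def believed_p_right(sum_z, t, params: ModelParams):
    """Agent's posterior probability that the direction is rightward.

    ``Phi(sum_z / sigma_z^2 / sqrt(t / sigma_z^2 + 1 / sigma_0^2))``.
    Accepts scalars or arrays; ``t = 0`` returns the prior belief 0.5.
    """
    t = np.asarray(t, dtype=float)
    sum_z = np.asarray(sum_z, dtype=float)
    denom = np.sqrt(t / params.sigma_z**2 + 1.0 / params.sigma_0**2)
    out = norm.cdf((sum_z / params.sigma_z**2) / denom)
    if out.ndim == 0:
        return float(out)
    return out


def accuracy_zero_cost(c, t, w_z):
    """Probability of a correct direction choice with free observations.

    When all ``t`` observations are used, the choice is the sign of the
    observation sum ``~ N(t c, sqrt(t) w_z)``, so accuracy is
    ``Phi(sqrt(t) |c| / w_z)``; at ``c = 0`` correctness is a fair coin
    and accuracy is 0.5.
    """
    c = np.asarray(c, dtype=float)
    t = np.asarray(t, dtype=float)
    out = norm.cdf(np.sqrt(t) * np.abs(c) / w_z)
    out = np.where(c == 0.0, 0.5, out)
    if out.ndim == 0:
        return float(out)
    return out


def select_terminal_action(
    belief: Belief,
    params: ModelParams,
    sure_available: bool,
    rng: np.random.Generator | None = None,
) -> ActionOutcome:
    """Pick the utility-maximizing terminal action for the current belief.

    With the sure bet on offer, it is chosen whenever its guaranteed
    utility is at least the expected utility of the better direction,
    i.e. whenever ``confidence <= utility_ratio`` (ties go to the sure
    bet). Otherwise the sign of the posterior mean decides the direction;
    an exactly symmetric belief is broken by a seeded uniform draw.
    """
    conf = confidence(belief)
    if sure_available and conf <= params.utility_ratio:
        return ActionOutcome(action="sure", confidence=None)
    if belief.mu > 0:
        action = "right"
    elif belief.mu < 0:
        action = "left"
    else:
        if rng is None:
            rng = np.random.default_rng()
        action = "right" if rng.random() < 0.5 else "left"
    return ActionOutcome(action=action, confidence=conf)
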