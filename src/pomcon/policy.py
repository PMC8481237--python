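"""Cost-based termination policy and the exact POMDP-to-DDM mapping.

The agent stops sampling by a one-step look-ahead rule: take another
observation only while the expected confidence gain of that single
observation exceeds ``cost / r_direction``. Because the gain falls with
elapsed time and with |mu_t|, the rule is an iso-gain contour in the
``(mu_t, t)`` plane — a time-varying (collapsing) bound on ``|mu_t|``.
The rule is myopic: it ignores the option value of being able to stop
later, so it terminates slightly before the exact dynamic-programming
optimum (the expected-utility shortfall is below one observation cost;
the test suite quantifies this against a DP oracle).

Because ``mu_t / sigma_t^2 = sum_z / sigma_z^2``, the same policy can be
run on the raw evidence sum ``V_t = sum_z`` (a drift-diffusion model)
with the transformed bound ``Theta(t) = (t + sigma_z^2/sigma_0^2) *
Theta'(t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import norm

from .core import Belief, posterior_sigma
from .params import ModelParams

__all__ = [
    "PolicyMap",
    "DDMSpec",
    "expected_confidence_gain",
    "compute_termination_bound",
    "sure_threshold_mu",
    "surebet_thresholds_on_sum",
    "ddm_from_belief",
    "ddm_bound_from_policy",
]

#: absolute quadrature tolerance on the expected confidence gain
_QUAD_TOL = 1e-10
#: bisection tolerance on the bound location (in mu units)
_BISECT_TOL = 1e-6

#: fixed Gauss-Legendre rules; the fine/coarse pair provides an error check
_GL_COARSE = np.polynomial.legendre.leggauss(48)
_GL_FINE = np.polynomial.legendre.leggauss(96)


def _gl_piece(a, b, m, s, sigma_next, rule):
    nodes, weights = rule
    x = 0.5 * (b - a) * nodes + 0.5 * (b + a)
    f = norm.pdf(x, loc=m, scale=s) * norm.cdf(np.abs(x) / sigma_next)
    return 0.5 * (b - a) * float(weights @ f)


@dataclass(frozen=True)
class PolicyMap:
    """Termination bounds and sure-bet thresholds per observation step.

    ``bound_mu[i]`` is the symmetric termination bound on ``|mu_t|`` at
    ``times[i]`` observations (``inf`` when observations are free), and
    ``sure_threshold_mu[i]`` is the ``|mu_t|`` level at which confidence
    equals the sure-bet utility ratio.
    """

    times: np.ndarray
    bound_mu: np.ndarray
    sure_threshold_mu: np.ndarray
    params: ModelParams

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: step, bound_mu, sure_threshold_mu, bound_V."""
        spec = ddm_bound_from_policy(self, self.params)
        return pd.DataFrame(
            {
                "step": self.times,
                "bound_mu": self.bound_mu,
                "sure_threshold_mu": self.sure_threshold_mu,
                "bound_V": spec.bound_V,
            }
        )


@dataclass(frozen=True)
class DDMSpec:
    """Drift-diffusion bound on the accumulated evidence ``V_t = sum_z``."""

    times: np.ndarray
    bound_V: np.ndarray


def expected_confidence_gain(
    mu: float, t: int, params: ModelParams, predictive: str = "posterior"
) -> float:
    """Expected increase in confidence from taking one more observation.

    By default the agent predicts the next observation from its full
    posterior predictive, ``N(mu_t, sqrt(sigma_t^2 + sigma_z^2))`` — the
    Bayes-exact forecast under the learned generative model, and the
    variant whose bounded simulations reproduce the published cost
    effects on accuracy and confidence. ``predictive="likelihood"``
    instead centres the learned likelihood on the current mean,
    ``N(mu_t, sigma_z)``, ignoring the residual uncertainty in the
    inferred coherence. The expectation of the post-update confidence is
    evaluated by paired coarse/fine Gauss-Legendre panels split at the
    |mu| kink, falling back to adaptive quadrature if they disagree.
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    sigma_t = float(posterior_sigma(t, params))
    sigma_next = float(posterior_sigma(t + 1, params))
    if predictive not in ("posterior", "likelihood"):
        raise ValueError(f"unknown predictive {predictive!r}")
    sz2 = params.sigma_z**2
    shrink = sigma_t**2 / (sigma_t**2 + sz2)  # weight of z in the updated mean
    pred_sd = math.sqrt(sigma_t**2 + sz2) if predictive == "posterior" else params.sigma_z
    # mu_{t+1} = shrink * z + (1 - shrink) * mu_t is Gaussian:
    m, s = float(mu), shrink * pred_sd

    lo, hi = m - 12.0 * s, m + 12.0 * s
    if lo < 0.0 < hi:
        pieces = [(lo, 0.0), (0.0, hi)]  # kink of |x| at zero
    else:
        pieces = [(lo, hi)]
    expected = 0.0
    for a, b in pieces:
        coarse = _gl_piece(a, b, m, s, sigma_next, _GL_COARSE)
        fine = _gl_piece(a, b, m, s, sigma_next, _GL_FINE)
        if not math.isfinite(fine) or abs(fine - coarse) > 1e-8:
            # smooth-integrand quadrature disagreed: fall back to adaptive
            fine, err = quad(
                lambda x: norm.pdf(x, loc=m, scale=s) * norm.cdf(abs(x) / sigma_next),
                a,
                b,
                epsabs=_QUAD_TOL,
                limit=200,
            )
            if not math.isfinite(fine) or err > 1e-6:
                raise RuntimeError(
                    f"confidence-gain quadrature failed on [{a}, {b}] "
                    f"(mu={mu}, t={t}, err={err})"
                )
        expected += fine
    return expected - float(norm.cdf(abs(m) / sigma_t))


def compute_termination_bound(
    params: ModelParams, horizon: int | None = None, predictive: str = "posterior"
) -> PolicyMap:
    """Iso-gain termination bound ``Theta'(t)`` on ``|mu_t|`` per step.

    At each step the bound is the smallest ``|mu|`` at which the expected
    confidence gain of one more observation no longer exceeds
    ``cost / r_direction``. Zero cost yields infinite bounds (the agent
    never stops early); once the gain at ``mu = 0`` falls below the cost
    the bound collapses to 0 and the agent stops regardless of evidence.
    """
    horizon = params.horizon if horizon is None else int(horizon)
    times = np.arange(1, horizon + 1)
    target = params.cost / params.r_direction
    if target == 0.0:
        bound = np.full(horizon, np.inf)
        return PolicyMap(times, bound, _sure_thresholds(times, params), params)

    bound = np.empty(horizon)
    prev = None
    for i, t in enumerate(times):
        bound[i] = _bound_at(int(t), target, params, predictive, bracket_hi=prev)
        # the bound collapses over time; the previous value brackets the next
        prev = bound[i] if bound[i] > 0 else None
    return PolicyMap(times, bound, _sure_thresholds(times, params), params)


def _bound_at(
    t: int,
    target: float,
    params: ModelParams,
    predictive: str,
    bracket_hi: float | None = None,
) -> float:
    gain0 = expected_confidence_gain(0.0, t, params, predictive)
    if gain0 <= target:
        return 0.0
    # expand until the gain has dropped below the target on the outer flank
    hi = params.sigma_0 if bracket_hi is None or not math.isfinite(bracket_hi) else bracket_hi
    for _ in range(60):
        if expected_confidence_gain(hi, t, params, predictive) <= target:
            break
        hi *= 2.0
    else:
        return math.inf  # gain never drops below the cost within reach
    lo = 0.0
    while hi - lo > _BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if expected_confidence_gain(mid, t, params, predictive) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sure_threshold_mu(t, params: ModelParams):
    """The ``|mu_t|`` level where confidence equals the utility ratio."""
    return posterior_sigma(t, params) * norm.ppf(params.utility_ratio)


def _sure_thresholds(times: np.ndarray, params: ModelParams) -> np.ndarray:
    return np.asarray(sure_threshold_mu(times, params), dtype=float)


def surebet_thresholds_on_sum(
    params: ModelParams, utility_ratio: float, t: int
) -> tuple[float, float]:
    """Symmetric thresholds on the observation sum for sure-bet rejection.

    The sure bet is rejected when confidence exceeds the utility ratio,
    which maps to ``|sum_z|`` exceeding a fixed threshold at a given
    duration: the belief about rightward crosses the ratio exactly at
    ``sum_z = Phi^{-1}(ratio) * sigma_z^2 * sqrt(t/sigma_z^2 + 1/sigma_0^2)``.
    """
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    denom = math.sqrt(t / params.sigma_z**2 + 1.0 / params.sigma_0**2)
    s = norm.ppf(utility_ratio) * params.sigma_z**2 * denom
    return (-s, s)


def ddm_from_belief(belief: Belief, params: ModelParams) -> float:
    """Recover the DDM decision variable ``V_t`` from a belief state.

    ``V_t = mu_t * sigma_z^2 / sigma_t^2`` equals the raw observation sum
    exactly; at fixed ``t`` the map between ``mu_t`` and ``V_t`` is linear
    with positive slope, hence bijective.
    """
    return belief.mu * params.sigma_z**2 / belief.sigma**2


def ddm_bound_from_policy(policy: PolicyMap, params: ModelParams) -> DDMSpec:
    """Transform the belief-space bound to the evidence-sum bound.

    ``Theta(t) = (t + sigma_z^2 / sigma_0^2) * Theta'(t)``: a DDM run on
    the same observation stream stops at the same step with the same
    choice as the POMDP policy.
    """
    factor = policy.times + params.sigma_z**2 / params.sigma_0**2
    return DDMSpec(times=policy.times, bound_V=factor * policy.bound_mu)
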