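"""Synthetic wagering task and vectorized agent simulators.

Emulates the random-dot direction-discrimination task with post-decision
wagering: signed coherences from the seven experimental magnitudes,
stimulus durations of 100-900 ms in 10-ms steps, and a sure-bet option
offered on a random half of trials. Momentary observations are i.i.d.
``N(c, w_z)`` per 10-ms step.

Durations default to a truncated-exponential distribution (scale 120 ms
over 100-900 ms). This mimics the short-duration-heavy designs typical
of the task family and makes the task statistics consistent with the
reference parameter sets: the estimation pipeline ties the prior width
to the task mixture through ``sigma_0^2 = Var(c) + sigma_z^2 * E[1/t]``,
and the reference (sigma_0, sigma_z) pairs imply a harmonic-mean
duration near 160-180 ms, which a uniform duration mix cannot produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .params import COHERENCE_MAGNITUDES, ModelParams
from .policy import PolicyMap, compute_termination_bound

__all__ = [
    "TaskConfig",
    "generate_trials",
    "sample_observations",
    "simulate_fixed_duration",
    "simulate_reaction_time",
]

_CHUNK = 200_000  # trials per vectorized block; bounds peak memory


@dataclass(frozen=True)
class TaskConfig:
    """Stimulus-generation settings for the wagering task."""

    coherence_magnitudes: tuple = COHERENCE_MAGNITUDES
    duration_range_ms: tuple = (100, 900)
    duration_distribution: str = "truncexp"  # or "uniform"
    duration_scale_ms: float = 120.0
    p_sure_shown: float = 0.5
    n_trials: int = 10_000
    seed: int = 0
    dt_ms: float = 10.0

    def __post_init__(self) -> None:
        if len(self.coherence_magnitudes) == 0:
            raise ValueError("coherence_magnitudes must be non-empty")
        if any(m < 0 for m in self.coherence_magnitudes):
            raise ValueError("coherence magnitudes are unsigned; got a negative value")
        if not 0.0 <= self.p_sure_shown <= 1.0:
            raise ValueError(f"p_sure_shown must lie in [0, 1], got {self.p_sure_shown}")
        lo, hi = self.duration_range_ms
        if lo > hi or lo <= 0:
            raise ValueError(f"bad duration range {self.duration_range_ms}")
        if lo % self.dt_ms or hi % self.dt_ms:
            raise ValueError("duration range must be a multiple of the time step")
        if self.duration_distribution not in ("truncexp", "uniform"):
            raise ValueError(f"unknown duration distribution {self.duration_distribution!r}")

    @property
    def step_range(self) -> tuple[int, int]:
        return (
            int(self.duration_range_ms[0] / self.dt_ms),
            int(self.duration_range_ms[1] / self.dt_ms),
        )


def _sample_duration_steps(config: TaskConfig, n: int, rng: np.random.Generator):
    lo, hi = config.step_range
    steps = np.arange(lo, hi + 1)
    if config.duration_distribution == "uniform":
        p = np.full(steps.size, 1.0 / steps.size)
    else:
        w = np.exp(-steps / (config.duration_scale_ms / config.dt_ms))
        p = w / w.sum()
    return rng.choice(steps, size=n, p=p)


def generate_trials(config: TaskConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a reproducible stimulus set (no agent behaviour yet).

    Each trial samples a coherence magnitude uniformly from the
    configured levels and an independent uniform sign, so each signed
    nonzero level appears with probability ``1/(2 m)`` for ``m``
    magnitudes (zero coherence collects both signs). Sure-bet
    availability is i.i.d. Bernoulli(``p_sure_shown``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    mags = np.asarray(config.coherence_magnitudes, dtype=float)
    mag = rng.choice(mags, size=n)
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    return pd.DataFrame(
        {
            "coherence": mag * sign,
            "duration_steps": _sample_duration_steps(config, n, rng),
            "sure_shown": rng.random(n) < config.p_sure_shown,
        }
    )


def sample_observations(c: float, t: int, w_z: float, rng=None, seed=None) -> np.ndarray:
    """``t`` i.i.d. momentary observations ``N(c, w_z)``."""
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.normal(c, w_z, size=int(t))


def _resolve_policy(params: ModelParams, policy: PolicyMap | None, horizon: int) -> np.ndarray:
    if policy is None:
        policy = compute_termination_bound(params, horizon=horizon)
    if policy.bound_mu.size < horizon:
        raise ValueError(
            f"policy covers {policy.bound_mu.size} steps but trials need {horizon}"
        )
    return policy.bound_mu[:horizon]


def simulate_fixed_duration(
    trials: pd.DataFrame,
    params: ModelParams,
    policy: PolicyMap | None = None,
    rng: np.random.Generator | None = None,
    keep_observation_sum: bool = False,
) -> pd.DataFrame:
    """Run the belief-updating agent on experimenter-controlled durations.

    The belief is updated each 10-ms step. If ``|mu_t|`` reaches the
    termination bound the belief freezes — later observations are
    ignored — but the trial still lasts its full duration. The direction
    choice and confidence come from the frozen (or final) belief; when
    the sure bet is on offer it is taken whenever confidence does not
    exceed the utility ratio. Correctness at zero coherence is a fair
    coin, mirroring the random reward rule of the experiment.
    """
    if rng is None:
        rng = np.random.default_rng()
    dur = trials["duration_steps"].to_numpy(dtype=int)
    if (dur < 1).any():
        raise ValueError("all durations must be at least one step")
    horizon = int(dur.max())
    bound = _resolve_policy(params, policy, horizon)

    coh = trials["coherence"].to_numpy(dtype=float)
    sure_shown = trials["sure_shown"].to_numpy(dtype=bool)
    n = len(trials)

    tgrid = np.arange(1, horizon + 1)
    precision = tgrid / params.sigma_z**2 + 1.0 / params.sigma_0**2
    sigma_t = 1.0 / np.sqrt(precision)
    finite = np.isfinite(bound)

    out = {
        "decision_step": np.empty(n, dtype=int),
        "mu_dec": np.empty(n),
        "sigma_dec": np.empty(n),
        "sum_dec": np.empty(n),
    }
    for start in range(0, n, _CHUNK):
        sl = slice(start, min(start + _CHUNK, n))
        m = sl.stop - sl.start
        z = rng.normal(coh[sl, None], params.w_z, size=(m, horizon))
        S = np.cumsum(z, axis=1)
        mu = (S / params.sigma_z**2) / precision
        valid = tgrid[None, :] <= dur[sl, None]
        if finite.any():
            hit = (np.abs(mu) >= bound[None, :]) & valid
            any_hit = hit.any(axis=1)
            first = np.where(any_hit, hit.argmax(axis=1) + 1, dur[sl])
        else:
            first = dur[sl]
        idx = first - 1
        rows = np.arange(m)
        out["decision_step"][sl] = first
        out["mu_dec"][sl] = mu[rows, idx]
        out["sigma_dec"][sl] = sigma_t[idx]
        out["sum_dec"][sl] = S[rows, idx]

    mu_dec = out["mu_dec"]
    tie = mu_dec == 0.0
    go_right = np.where(tie, rng.random(n) < 0.5, mu_dec > 0)
    conf = norm.cdf(np.abs(mu_dec) / out["sigma_dec"])
    chose_sure = sure_shown & (conf <= params.utility_ratio)
    correct = np.where(
        coh == 0.0, rng.random(n) < 0.5, (go_right & (coh > 0)) | (~go_right & (coh < 0))
    )

    result = pd.DataFrame(
        {
            "coherence": coh,
            "duration_steps": dur,
            "sure_shown": sure_shown,
            "choice": np.where(chose_sure, "sure", np.where(go_right, "right", "left")),
            "correct": correct.astype(bool),
            "confidence": conf,
            "decision_step": out["decision_step"],
        }
    )
    if keep_observation_sum:
        result["sum_z"] = out["sum_dec"]
    return result


def simulate_reaction_time(
    coherences: np.ndarray,
    params: ModelParams,
    policy: PolicyMap | None = None,
    non_decision_steps: int = 25,
    report_mode: str = "simultaneous",
    rng: np.random.Generator | None = None,
    horizon: int | None = None,
) -> pd.DataFrame:
    """Reaction-time version: the agent controls viewing duration.

    The trial ends when ``|mu_t|`` crosses the termination bound (which
    requires a positive observation cost). In ``simultaneous`` mode
    confidence is read out at the bound, together with the choice. In
    ``sequential`` mode the stimulus continues through the sensorimotor
    non-decision time, the belief keeps updating on those extra
    observations, and the confidence report — but not the choice — uses
    the refined belief, signed by the committed choice, so it can fall
    below 0.5 after strong disconfirming evidence.
    """
    if report_mode not in ("simultaneous", "sequential"):
        raise ValueError(f"unknown report mode {report_mode!r}")
    if non_decision_steps < 0:
        raise ValueError("non_decision_steps must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    horizon = params.horizon if horizon is None else int(horizon)
    bound = _resolve_policy(params, policy, horizon)
    if not np.isfinite(bound).all():
        raise ValueError(
            "reaction-time simulation needs finite termination bounds at every "
            "step: use a positive observation cost"
        )

    coh = np.asarray(coherences, dtype=float)
    n = coh.size
    total = horizon + non_decision_steps
    tgrid = np.arange(1, total + 1)
    precision = tgrid / params.sigma_z**2 + 1.0 / params.sigma_0**2
    sigma_t = 1.0 / np.sqrt(precision)

    res = {
        "decision_step": np.empty(n, dtype=int),
        "mu_dec": np.empty(n),
        "conf": np.empty(n),
    }
    for start in range(0, n, _CHUNK // 4):
        sl = slice(start, min(start + _CHUNK // 4, n))
        m = sl.stop - sl.start
        z = rng.normal(coh[sl, None], params.w_z, size=(m, total))
        S = np.cumsum(z, axis=1)
        mu = (S / params.sigma_z**2) / precision
        hit = np.abs(mu[:, :horizon]) >= bound[None, :]
        any_hit = hit.any(axis=1)
        first = np.where(any_hit, hit.argmax(axis=1) + 1, horizon)
        rows = np.arange(m)
        mu_dec = mu[rows, first - 1]
        res["decision_step"][sl] = first
        res["mu_dec"][sl] = mu_dec
        if report_mode == "simultaneous" or non_decision_steps == 0:
            res["conf"][sl] = norm.cdf(np.abs(mu_dec) / sigma_t[first - 1])
        else:
            post = first - 1 + non_decision_steps
            mu_post = mu[rows, post]
            signed = np.where(mu_dec >= 0, mu_post, -mu_post)
            res["conf"][sl] = norm.cdf(signed / sigma_t[post])

    tie = res["mu_dec"] == 0.0
    go_right = np.where(tie, rng.random(n) < 0.5, res["mu_dec"] > 0)
    correct = np.where(
        coh == 0.0, rng.random(n) < 0.5, (go_right & (coh > 0)) | (~go_right & (coh < 0))
    )
    return pd.DataFrame(
        {
            "coherence": coh,
            "choice": np.where(go_right, "right", "left"),
            "correct": correct.astype(bool),
            "confidence": res["conf"],
            "decision_step": res["decision_step"],
            "sure_shown": False,
        }
    )
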