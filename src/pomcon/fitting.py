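"""Parameter estimation for the wagering-task model.

The estimation pipeline mirrors how the model is constrained by choice
data alone:

1. ``fit_wz`` — maximum-likelihood observation noise from the
   psychometric surface: rightward choices are Bernoulli with mean
   ``Phi(sqrt(t) c / w_z)`` (zero-cost model, c = 0 trials excluded).
2. ``estimate_prior`` — the prior over signed coherence is matched to
   the across-trial distribution of inferred coherences: one draw of
   ``N(c, noise/sqrt(t))`` per trial, Gaussian MLE over the pooled
   draws.
3. ``fit_sigma_z`` — the learned likelihood width is chosen so the
   agent's stated belief matches its accuracy: rightward choices are
   Bernoulli with mean ``Phi(sum_z / sigma_z^2 / sqrt(t/sigma_z^2 +
   1/sigma_0^2))``, with the per-trial observation sums re-simulated
   from the true stimulus (the experimenter never sees the subject's
   actual observations).
4. ``iterate_prior_noise`` — steps 2 and 3 alternate (the prior re-drawn
   with the learned width) until the prior width settles.
5. ``fit_utility_ratio`` — the sure-bet threshold on confidence is a
   1-D MLE against the opt-out frequencies.

For a model with a positive observation cost the choice probability has
no closed form; ``particle_filter_loglik`` estimates it by forward
simulation and ``grid_search_cost_model`` maximizes it over a
(cost, w_z) grid with the step 2-4 inner loop at every grid point.

Note on identifiability: with free observations the direction choices
pin down only ``w_z``; (sigma_z, sigma_0) converge to a pseudo-true
fixed point set by ``w_z`` and the task mixture (the stated belief can
never calibrate exactly against a re-simulated observation sum), and
their estimates should be read as the self-consistent values for the
data at hand rather than as recovered agent internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .params import ModelParams
from .policy import compute_termination_bound

__all__ = [
    "FitResult",
    "fit_wz",
    "estimate_prior",
    "fit_sigma_z",
    "iterate_prior_noise",
    "fit_utility_ratio",
    "particle_filter_loglik",
    "grid_search_cost_model",
    "vuong_test",
]

WZ_BOUNDS = (0.05, 10.0)
SIGMA_Z_BOUNDS = (0.05, 20.0)
RATIO_BOUNDS = (0.501, 0.999)
_P_FLOOR = 1e-12


@dataclass
class FitResult:
    """Estimates with likelihood and convergence diagnostics."""

    w_z_hat: float | None = None
    sigma_0_hat: float | None = None
    sigma_z_hat: float | None = None
    mu_0_hat: float | None = None
    utility_ratio_hat: float | None = None
    cost_hat: float | None = None
    loglik: float = np.nan
    se: float | None = None
    n_iterations: int = 0
    converged: bool = True
    flags: list = field(default_factory=list)
    surface: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "w_z_hat",
                "sigma_0_hat",
                "sigma_z_hat",
                "mu_0_hat",
                "utility_ratio_hat",
                "cost_hat",
                "loglik",
                "n_iterations",
                "converged",
            )
            if getattr(self, k) is not None
        }
        d["flags"] = list(self.flags)
        return d


def _direction_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """No-sure-target trials with a direction choice and nonzero coherence."""
    keep = (~trials["sure_shown"]) & (trials["coherence"] != 0.0)
    sub = trials.loc[keep]
    if sub.empty:
        raise ValueError("no usable direction trials (need sure_shown=False, c != 0)")
    return sub


def _scalar_mle(nll, bounds, xatol=1e-6):
    res = minimize_scalar(nll, bounds=bounds, method="bounded", options={"xatol": xatol})
    return float(res.x), float(-res.fun)


def _boundary_flag(x, bounds, name, flags, rel=0.01):
    lo, hi = bounds
    if x - lo < rel * (hi - lo) or hi - x < rel * (hi - lo):
        flags.append(f"{name} estimate at search boundary ({x:.4g} in [{lo}, {hi}])")


def fit_wz(trials: pd.DataFrame) -> FitResult:
    """MLE of the true observation noise from direction choices alone.

    Rightward choice ~ Bernoulli(Phi(sqrt(t) c / w_z)). The standard
    error comes from the observed information (numerical second
    derivative at the optimum).
    """
    sub = _direction_trials(trials)
    c = sub["coherence"].to_numpy(float)
    t = sub["duration_steps"].to_numpy(float)
    y = (sub["choice"] == "right").to_numpy()

    def nll(w):
        p = np.clip(norm.cdf(np.sqrt(t) * c / w), _P_FLOOR, 1 - _P_FLOOR)
        return -(np.log(p[y]).sum() + np.log1p(-p[~y]).sum())

    w_hat, loglik = _scalar_mle(nll, WZ_BOUNDS)
    h = 1e-4 * w_hat
    info = (nll(w_hat + h) - 2 * nll(w_hat) + nll(w_hat - h)) / h**2
    se = float(1.0 / np.sqrt(info)) if info > 0 else None
    result = FitResult(w_z_hat=w_hat, loglik=loglik, se=se)
    _boundary_flag(w_hat, WZ_BOUNDS, "w_z", result.flags)
    return result


def estimate_prior(
    trials: pd.DataFrame,
    noise_sd: float,
    rng: np.random.Generator | None = None,
    standard_draws: np.ndarray | None = None,
    method: str = "sample",
) -> tuple[float, float]:
    """Gaussian MLE of the prior from per-trial inferred coherences.

    With ``method="sample"`` (default) each trial contributes one draw
    ``N(c, noise_sd / sqrt(t))`` and the pooled draws are fitted by
    moment-matching (the Gaussian MLE); ``standard_draws`` lets callers
    reuse one set of standard-normal deviates across repeated calls
    (common random numbers stabilize the prior/noise iteration).
    ``method="moment"`` computes the same mixture's mean and width
    deterministically (variance-reduced: no sampling noise).
    """
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be positive, got {noise_sd}")
    c = trials["coherence"].to_numpy(float)
    t = trials["duration_steps"].to_numpy(float)
    if method == "moment":
        var = c.var() + (noise_sd**2 / t).mean()
        return float(c.mean()), float(np.sqrt(var))
    if method != "sample":
        raise ValueError(f"unknown method {method!r}")
    if standard_draws is None:
        if rng is None:
            rng = np.random.default_rng()
        standard_draws = rng.standard_normal(c.size)
    draws = c + noise_sd / np.sqrt(t) * standard_draws
    return float(draws.mean()), float(draws.std())


def fit_sigma_z(
    trials: pd.DataFrame,
    w_z: float,
    sigma_0: float,
    rng: np.random.Generator,
    standard_draws: np.ndarray | None = None,
) -> FitResult:
    """MLE of the learned noise by matching stated belief to choices.

    The per-trial observation sum is re-simulated as
    ``N(t c, sqrt(t) w_z)`` (seeded); the recorded rightward choice is
    Bernoulli with mean ``believed_p_right(sum, t)`` under candidate
    ``sigma_z``.
    """
    sub = _direction_trials(trials)
    c = sub["coherence"].to_numpy(float)
    t = sub["duration_steps"].to_numpy(float)
    y = (sub["choice"] == "right").to_numpy()
    if standard_draws is None:
        standard_draws = rng.standard_normal(c.size)
    elif standard_draws.size != len(trials):
        raise ValueError("standard_draws must have one deviate per trial")
    else:
        standard_draws = standard_draws[
            ((~trials["sure_shown"]) & (trials["coherence"] != 0.0)).to_numpy()
        ]
    s = t * c + np.sqrt(t) * w_z * standard_draws

    def nll(sigma_z):
        denom = np.sqrt(t / sigma_z**2 + 1.0 / sigma_0**2)
        p = np.clip(norm.cdf((s / sigma_z**2) / denom), _P_FLOOR, 1 - _P_FLOOR)
        return -(np.log(p[y]).sum() + np.log1p(-p[~y]).sum())

    sz_hat, loglik = _scalar_mle(nll, SIGMA_Z_BOUNDS)
    result = FitResult(sigma_z_hat=sz_hat, sigma_0_hat=sigma_0, w_z_hat=w_z, loglik=loglik)
    _boundary_flag(sz_hat, SIGMA_Z_BOUNDS, "sigma_z", result.flags)
    return result


def iterate_prior_noise(
    trials: pd.DataFrame,
    w_z: float,
    tol: float = 1e-3,
    max_iter: int = 20,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Alternate prior and learned-noise estimation to a fixed point.

    The first prior estimate uses the true noise ``w_z``; every
    subsequent pass re-draws the inferred coherences with the current
    ``sigma_z``. Iteration stops when the prior width moves by less than
    ``tol``. Common random numbers are reused across iterations so the
    fixed point is deterministic given the generator state.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if rng is None:
        rng = np.random.default_rng()
    prior_draws = rng.standard_normal(len(trials))
    sum_draws = rng.standard_normal(len(trials))

    mu0, sigma_0 = estimate_prior(trials, w_z, rng, standard_draws=prior_draws)
    last = FitResult()
    n_done = 0
    converged = False
    for it in range(1, max_iter + 1):
        last = fit_sigma_z(trials, w_z, sigma_0, rng, standard_draws=sum_draws)
        mu0, sigma_0_new = estimate_prior(
            trials, last.sigma_z_hat, rng, standard_draws=prior_draws
        )
        n_done = it
        delta, sigma_0 = abs(sigma_0_new - sigma_0), sigma_0_new
        if delta < tol:
            converged = True
            break
    result = FitResult(
        w_z_hat=w_z,
        sigma_0_hat=sigma_0,
        sigma_z_hat=last.sigma_z_hat,
        mu_0_hat=mu0,
        loglik=last.loglik,
        n_iterations=n_done,
        converged=converged,
        flags=list(last.flags),
    )
    if abs(mu0) > 5 * sigma_0 / np.sqrt(max(len(trials), 1)):
        result.flags.append(
            f"prior mean estimate {mu0:.4g} differs from 0; the model clamps mu_0 to 0"
        )
    if not converged:
        result.flags.append(f"prior/noise iteration did not converge in {max_iter} passes")
    return result


def surebet_prob_zero_cost(
    coherence, duration_steps, ratio: float, params: ModelParams
):
    """P(choose sure | c, t) for the free-observation model.

    Confidence exceeds the ratio exactly when the observation sum passes
    ``s*(t) = Phi^{-1}(ratio) sigma_z^2 sqrt(t/sigma_z^2 + 1/sigma_0^2)``,
    and the sum is ``N(t c, sqrt(t) w_z)`` under the true stimulus.
    """
    c = np.asarray(coherence, float)
    t = np.asarray(duration_steps, float)
    s_star = (
        norm.ppf(ratio)
        * params.sigma_z**2
        * np.sqrt(t / params.sigma_z**2 + 1.0 / params.sigma_0**2)
    )
    scale = np.sqrt(t) * params.w_z
    return norm.cdf((s_star - t * c) / scale) - norm.cdf((-s_star - t * c) / scale)


def fit_utility_ratio(trials: pd.DataFrame, params: ModelParams) -> FitResult:
    """MLE of the sure-bet confidence threshold from opt-out frequencies."""
    sub = trials.loc[trials["sure_shown"]]
    if sub.empty:
        raise ValueError("no sure-shown trials to fit the utility ratio")
    c = sub["coherence"].to_numpy(float)
    t = sub["duration_steps"].to_numpy(float)
    y = (sub["choice"] == "sure").to_numpy()

    def nll(ratio):
        p = np.clip(surebet_prob_zero_cost(c, t, ratio, params), _P_FLOOR, 1 - _P_FLOOR)
        return -(np.log(p[y]).sum() + np.log1p(-p[~y]).sum())

    r_hat, loglik = _scalar_mle(nll, RATIO_BOUNDS, xatol=1e-7)
    result = FitResult(utility_ratio_hat=r_hat, loglik=loglik)
    _boundary_flag(r_hat, RATIO_BOUNDS, "utility_ratio", result.flags)
    return result


def particle_filter_loglik(
    trials: pd.DataFrame,
    params: ModelParams,
    n_particles: int = 20_000,
    rng: np.random.Generator | None = None,
    p_floor: float = 1e-4,
) -> float:
    """Log-likelihood of direction choices under the bounded policy.

    The choice probability per (coherence, duration) condition is
    estimated by forward-simulating ``n_particles`` observation streams
    through the frozen-belief policy; trials sharing a condition share
    the estimate. Conditions whose estimated probability is 0 or 1 are
    floored at ``p_floor`` to keep the log-likelihood finite.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be at least 1")
    if rng is None:
        rng = np.random.default_rng()
    sub = _direction_trials(trials)
    horizon = int(sub["duration_steps"].max())
    policy = compute_termination_bound(params, horizon=horizon)
    bound = policy.bound_mu
    tgrid = np.arange(1, horizon + 1)
    precision = tgrid / params.sigma_z**2 + 1.0 / params.sigma_0**2

    loglik = 0.0
    grouped = sub.groupby(["coherence", "duration_steps"], sort=True)
    for (c, t), g in grouped:
        t = int(t)
        z = rng.normal(c, params.w_z, size=(n_particles, t))
        mu = (np.cumsum(z, axis=1) / params.sigma_z**2) / precision[:t]
        if np.isfinite(bound[:t]).any():
            hit = np.abs(mu) >= bound[None, :t]
            first = np.where(hit.any(axis=1), hit.argmax(axis=1), t - 1)
        else:
            first = np.full(n_particles, t - 1)
        mu_dec = mu[np.arange(n_particles), first]
        ties = mu_dec == 0.0
        go_right = np.where(ties, rng.random(n_particles) < 0.5, mu_dec > 0)
        p_right = float(np.clip(go_right.mean(), p_floor, 1 - p_floor))
        n_right = int((g["choice"] == "right").sum())
        loglik += n_right * np.log(p_right) + (len(g) - n_right) * np.log1p(-p_right)
    return float(loglik)


def grid_search_cost_model(
    trials: pd.DataFrame,
    cost_grid: np.ndarray,
    wz_grid: np.ndarray,
    n_particles: int = 20_000,
    rng: np.random.Generator | None = None,
    iterate_tol: float = 1e-3,
) -> FitResult:
    """Joint (cost, w_z) fit of the bounded model by grid search.

    Every grid point re-runs the prior/noise inner loop (so sigma_0 and
    sigma_z stay self-consistent with the candidate w_z) before scoring
    the choices with the particle-filter likelihood. Returns the argmax
    and the full likelihood surface.
    """
    if rng is None:
        rng = np.random.default_rng()
    cost_grid = np.asarray(cost_grid, float)
    wz_grid = np.asarray(wz_grid, float)
    if cost_grid.size == 0 or wz_grid.size == 0:
        raise ValueError("grids must be non-empty")
    # one child generator per grid point keeps the surface reproducible
    # and independent of evaluation order
    seeds = rng.spawn(cost_grid.size * wz_grid.size)
    rows = []
    k = 0
    for w_z in wz_grid:
        inner = iterate_prior_noise(trials, w_z, tol=iterate_tol, rng=seeds[k])
        for cost in cost_grid:
            params = ModelParams(
                w_z=float(w_z),
                sigma_z=inner.sigma_z_hat,
                sigma_0=inner.sigma_0_hat,
                cost=float(cost),
            )
            ll = particle_filter_loglik(trials, params, n_particles, rng=seeds[k])
            rows.append(
                {
                    "cost": float(cost),
                    "w_z": float(w_z),
                    "sigma_z": inner.sigma_z_hat,
                    "sigma_0": inner.sigma_0_hat,
                    "loglik": ll,
                }
            )
            k += 1
    surface = pd.DataFrame(rows)
    best = surface.loc[surface["loglik"].idxmax()]
    return FitResult(
        w_z_hat=best["w_z"],
        sigma_z_hat=best["sigma_z"],
        sigma_0_hat=best["sigma_0"],
        cost_hat=best["cost"],
        loglik=best["loglik"],
        converged=True,
        surface=surface,
    )


def vuong_test(
    pointwise_llr: np.ndarray,
    k1: int = 0,
    k2: int = 0,
    penalized: bool = True,
    centered: bool = False,
) -> tuple[float, float]:
    """Closeness test for two non-nested models.

    ``Z = LR / (sqrt(N) w)`` with ``LR = L1 - L2 - 0.5 (K1 - K2) log N``
    (the parameter-count penalty is dropped with ``penalized=False``)
    and ``w`` the root mean square of the pointwise log-likelihood
    ratios (``centered=True`` uses their standard deviation instead).
    Returns the Z statistic and the two-sided normal p-value.
    """
    llr = np.asarray(pointwise_llr, float)
    n = llr.size
    if n <= 1:
        raise ValueError("need more than one pointwise log-likelihood ratio")
    w2 = np.mean(llr**2) - (centered * np.mean(llr) ** 2)
    if w2 <= 0:
        raise ValueError("degenerate test: pointwise log-likelihood ratios are identical")
    lr = llr.sum()
    if penalized:
        lr -= 0.5 * (k1 - k2) * np.log(n)
    z = lr / (np.sqrt(n) * np.sqrt(w2))
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)
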