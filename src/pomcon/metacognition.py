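"""Type-1 and type-2 sensitivity for binary confidence ratings.

Equal-variance signal detection: the two stimulus classes (leftward /
rightward) generate unit-variance evidence distributions separated by
``d'``; the choice criterion is ``c1``. Meta-d' asks what separation an
SDT-ideal confidence rater would need to produce the observed
high-confidence rates conditional on each response, holding the type-1
criterion fixed in scaled form (``meta_c1 = c1 * meta_d' / d'``). For
an observer whose ratings are carved from the same evidence as the
choice, meta-d' equals d'; information lost between choice and rating —
such as a belief frozen by an early termination bound — pushes the
ratio below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = ["ConfusionCounts", "MetaResult", "type1_dprime", "meta_dprime", "counts_from_trials"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of (choice, rating) cells per stimulus class.

    ``high[s, r]`` / ``low[s, r]`` index stimulus ``s`` (0 = leftward,
    1 = rightward) and response ``r`` (0 = left, 1 = right).
    """

    high: np.ndarray
    low: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.high, self.low):
            if np.asarray(a).shape != (2, 2):
                raise ValueError("count arrays must be 2x2 (stimulus x response)")
            if (np.asarray(a) < 0).any():
                raise ValueError("counts must be non-negative")
        if self.class_totals().min() <= 0:
            raise ValueError("both stimulus classes need at least one trial")

    def class_totals(self) -> np.ndarray:
        return (np.asarray(self.high) + np.asarray(self.low)).sum(axis=1)

    def swap_labels(self) -> "ConfusionCounts":
        """Relabel left<->right for both stimulus and response."""
        return ConfusionCounts(self.high[::-1, ::-1].copy(), self.low[::-1, ::-1].copy())


@dataclass(frozen=True)
class MetaResult:
    d_prime: float
    c1: float
    meta_d_prime: float
    ratio: float
    fit_loglik: float
    corrected_cells: int = 0


def counts_from_trials(stim_right, resp_right, high) -> ConfusionCounts:
    """Tabulate boolean trial vectors into a ConfusionCounts table."""
    stim_right = np.asarray(stim_right, bool)
    resp_right = np.asarray(resp_right, bool)
    high = np.asarray(high, bool)
    h = np.zeros((2, 2))
    l = np.zeros((2, 2))
    for s in (0, 1):
        for r in (0, 1):
            m = (stim_right == bool(s)) & (resp_right == bool(r))
            h[s, r] = (high & m).sum()
            l[s, r] = (~high & m).sum()
    return ConfusionCounts(h, l)


def _corrected_rate(k, n):
    """Log-linear cell correction for rates of exactly 0 or 1."""
    if n == 0:
        raise ValueError("empty stimulus class")
    if k == 0 or k == n:
        return (k + 0.5) / (n + 1.0), True
    return k / n, False


def type1_dprime(counts: ConfusionCounts) -> tuple[float, float]:
    """Choice sensitivity and criterion: ``d' = z(HR) - z(FAR)``.

    Hit rate is P(respond right | rightward stimulus), false-alarm rate
    is P(respond right | leftward stimulus); extreme rates receive the
    log-linear half-count correction.
    """
    tot = np.asarray(counts.high) + np.asarray(counts.low)
    n_right_class, n_left_class = tot[1].sum(), tot[0].sum()
    hr, _ = _corrected_rate(tot[1, 1], n_right_class)
    far, _ = _corrected_rate(tot[0, 1], n_left_class)
    d = float(norm.ppf(hr) - norm.ppf(far))
    c1 = float(-0.5 * (norm.ppf(hr) + norm.ppf(far)))
    return d, c1


def meta_dprime(counts: ConfusionCounts) -> MetaResult:
    """MLE of meta-d' for binary high/low confidence ratings.

    Maximizes the likelihood of the rating counts conditional on each
    (stimulus, response) cell under the equal-variance SDT model with
    free type-2 criteria on both sides of the scaled type-1 criterion.
    """
    d, c1 = type1_dprime(counts)
    if d == 0.0:
        raise ValueError("type-1 d' is zero: meta-d' ratio undefined")
    high = np.asarray(counts.high, float)
    low = np.asarray(counts.low, float)
    corrected = 0
    rate = np.empty((2, 2))
    for s in (0, 1):
        for r in (0, 1):
            n_cell = high[s, r] + low[s, r]
            if n_cell == 0:
                rate[s, r] = np.nan
                continue
            rate[s, r], fixed = _corrected_rate(high[s, r], n_cell)
            corrected += fixed
    c_over_d = c1 / d

    def nll(theta):
        meta_d, log_off_r, log_off_l = theta
        meta_c1 = c_over_d * meta_d
        c2_r = meta_c1 + np.exp(log_off_r)
        c2_l = meta_c1 - np.exp(log_off_l)
        total = 0.0
        for s in (0, 1):
            mu_s = meta_d / 2.0 if s == 1 else -meta_d / 2.0
            p_resp_r = norm.sf(meta_c1 - mu_s)
            p_high_r = norm.sf(c2_r - mu_s) / max(p_resp_r, 1e-300)
            p_high_l = norm.cdf(c2_l - mu_s) / max(1.0 - p_resp_r, 1e-300)
            for r, ph in ((1, p_high_r), (0, p_high_l)):
                n_cell = high[s, r] + low[s, r]
                if n_cell == 0:
                    continue
                ph = min(max(ph, 1e-12), 1 - 1e-12)
                total -= high[s, r] * np.log(ph) + low[s, r] * np.log1p(-ph)
        return total

    res = minimize(
        nll,
        x0=np.array([d, np.log(0.5), np.log(0.5)]),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-8, "maxiter": 5000},
    )
    meta_d = float(res.x[0])
    return MetaResult(
        d_prime=d,
        c1=c1,
        meta_d_prime=meta_d,
        ratio=meta_d / d,
        fit_loglik=float(-res.fun),
        corrected_cells=corrected,
    )
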