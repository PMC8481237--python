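"""Model parameter container and published reference parameter sets.

All coherences are signed fractions (``+0.128`` means 12.8% rightward);
time is measured in integer 10-ms observation steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelParams:
    """Scalar constants of the POMDP decision model.

    Parameters
    ----------
    w_z
        True (generative) standard deviation of a momentary observation,
        in signed-coherence units. Shapes the samples the agent receives.
    sigma_z
        Observation noise standard deviation *learned* by the agent; this
        is the likelihood width used for belief updating and may differ
        from ``w_z``.
    sigma_0
        Standard deviation of the agent's Gaussian prior over signed
        coherence.
    mu_0
        Prior mean. Fixed at 0 for the symmetric direction task; nonzero
        values are rejected (estimation routines may *report* a nonzero
        mean, but the model itself always starts unbiased).
    cost
        Observation cost per 10-ms step, in utility units. ``0`` means
        observations are free and the agent never stops early.
    r_direction
        Utility of a correct direction choice (left/right are symmetric).
    utility_ratio
        ``r_sure / r_direction``: the guaranteed sure-bet utility relative
        to a correct direction choice. Acts as the confidence threshold
        for opting out.
    dt_ms
        Duration of one observation step in milliseconds.
    horizon
        Maximum number of observation steps in a trial.
    """

    w_z: float
    sigma_z: float
    sigma_0: float
    mu_0: float = 0.0
    cost: float = 0.0
    r_direction: float = 1.0
    utility_ratio: float = 0.63
    dt_ms: float = 10.0
    horizon: int = 90

    def __post_init__(self) -> None:
        if not self.w_z > 0:
            raise ValueError(f"w_z must be positive, got {self.w_z}")
        if not self.sigma_z > 0:
            raise ValueError(f"sigma_z must be positive, got {self.sigma_z}")
        if not self.sigma_0 > 0:
            raise ValueError(f"sigma_0 must be positive, got {self.sigma_0}")
        if self.mu_0 != 0.0:
            raise ValueError(
                "mu_0 must be 0: the agent's prior over signed coherence is "
                "unbiased in the symmetric direction task"
            )
        if self.cost < 0:
            raise ValueError(f"cost must be non-negative, got {self.cost}")
        if not 0.0 < self.utility_ratio < 1.0:
            raise ValueError(
                f"utility_ratio must lie in (0, 1), got {self.utility_ratio}"
            )
        if not self.r_direction > 0:
            raise ValueError(f"r_direction must be positive, got {self.r_direction}")
        if not self.dt_ms > 0:
            raise ValueError(f"dt_ms must be positive, got {self.dt_ms}")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")

    @property
    def r_sure(self) -> float:
        """Utility of the guaranteed sure-bet choice."""
        return self.utility_ratio * self.r_direction

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


#: Parameters fitted to monkey M1's choice behaviour (zero observation cost).
M1_PARAMS = ModelParams(w_z=0.90, sigma_z=1.60, sigma_0=0.46, utility_ratio=0.63)

#: Parameters fitted to monkey M2's choice behaviour (zero observation cost).
M2_PARAMS = ModelParams(w_z=1.69, sigma_z=3.59, sigma_0=0.87, utility_ratio=0.59)

#: Parameter set used for the reaction-time simulations (finite cost gives
#: collapsing termination bounds; the agent controls viewing duration).
RT_PARAMS = ModelParams(
    w_z=0.4, sigma_z=0.75, sigma_0=5.0, cost=2e-3, utility_ratio=0.63, horizon=300
)

#: The seven coherence magnitudes used in the wagering experiment.
COHERENCE_MAGNITUDES = (0.0, 0.016, 0.032, 0.064, 0.128, 0.256, 0.512)
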