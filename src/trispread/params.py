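"""Model parameters and external resource-allocation strategies.

Eight rates/factors govern the coupled dynamics:

* ``lambda_info`` (λ): probability that an unaware node adopts the panic
  information from one spreading neighbour per step (U→A).
* ``delta`` (δ): probability that a spreader quits spreading (A→U).
* ``eta`` (η): fraction of the population externally supplied with a
  therapeutic resource each step (per-individual acquisition probability
  within the eligible group).
* ``omega`` (ω): willingness of an unaware resource holder to transfer its
  resource to one requesting infected neighbour.
* ``theta`` (θ): panic-mitigation factor in [0, 1]; spreaders transfer with
  dampened willingness θ·ω (θ=0: spreaders refuse to share; θ=1: panic has
  no effect on sharing).
* ``beta`` (β): per-contact infection probability (S→I).
* ``mu`` (μ): baseline recovery probability without a resource, μ_N = μ.
* ``gamma`` (γ ≥ 1): recovery enhancement factor; a resource raises the
  recovery probability to μ_R = min(γμ, 1).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Any

__all__ = ["ModelParams", "AllocationStrategy"]


class AllocationStrategy(str, enum.Enum):
    """Who is eligible for the external (centralized) resource supply.

    ``RANDOM_ALL``: every node not already holding a resource.
    ``SUSCEPTIBLE_ONLY``: only resource-less susceptibles (UNS, ANS).
    ``INFECTED_ONLY``: only resource-less infecteds (UNI).
    """

    RANDOM_ALL = "random_all"
    SUSCEPTIBLE_ONLY = "susceptible_only"
    INFECTED_ONLY = "infected_only"

    @classmethod
    def coerce(cls, value: "AllocationStrategy | str") -> "AllocationStrategy":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())

    def eta_split(self, eta: float) -> tuple[float, float]:
        """Effective η in the susceptible and the infected (UNI) branches."""
        if self is AllocationStrategy.RANDOM_ALL:
            return eta, eta
        if self is AllocationStrategy.SUSCEPTIBLE_ONLY:
            return eta, 0.0
        return 0.0, eta


_PROB_FIELDS = ("lambda_info", "delta", "eta", "omega", "theta", "beta", "mu")


@dataclass(frozen=True)
class ModelParams:
    lambda_info: float = 0.5
    delta: float = 0.3
    eta: float = 0.2
    omega: float = 0.3
    theta: float = 0.0
    beta: float = 0.16
    mu: float = 0.3
    gamma: float = 3.0

    def __post_init__(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.gamma < 1.0:
            raise ValueError(f"gamma must be >= 1, got {self.gamma}")

    @property
    def mu_N(self) -> float:
        """Recovery probability without a resource."""
        return self.mu

    @property
    def mu_R(self) -> float:
        """Recovery probability with a resource, min(γμ, 1)."""
        return min(self.gamma * self.mu, 1.0)

    def with_(self, **kwargs: Any) -> "ModelParams":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)
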