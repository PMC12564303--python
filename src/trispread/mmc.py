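"""Microscopic Markov chain (MMC) engine for the coupled three-process model.

Each node carries a probability vector over the seven admissible compound
states (information, resource, epidemic):

    UNS, ANS, ARS, URS, URI, ARI, UNI

The eighth combination ANI (aware ∧ infected ∧ no resource) is excluded: an
infected individual without a resource must request aid from neighbours and
ceases spreading panic information, so any ANI mass is routed to UNI.

One synchronous step computes, from the time-t distribution, per-node local
probabilities

    α_i = 1 − (1−ω)^(Σ_j b_ji p_j^UNI)            transfer willingness
    π_ij = [p_j^URS + θ p_j^ARS] p_i^UNI α_i / Σ_k b_jk p_k^UNI
                                                   per-edge acquisition
    r_i = Π_j (1 − a_ji p_j^A λ)                   no information exposure
    s_i = Π_j (1 − b_ji π_ij)                      no peer resource received
    q_i = Π_j (1 − c_ji p_j^I β)                   no infection

and then pushes each node through the seven probability transition trees.
External allocation η enters the susceptible branches and/or the UNI branch
depending on the allocation strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .networks import MultiplexNetwork
from .params import AllocationStrategy, ModelParams

__all__ = [
    "STATES",
    "StateDistribution",
    "LocalProbabilities",
    "SteadySolution",
    "uniform_initial_distribution",
    "bernoulli_initial_distribution",
    "transfer_willingness",
    "acquisition_probability",
    "local_probabilities",
    "mmc_step",
    "effective_allocation",
    "iterate_to_steady_state",
]

STATES = ("UNS", "ANS", "ARS", "URS", "URI", "ARI", "UNI")
UNS, ANS, ARS, URS, URI, ARI, UNI = range(7)

#: state membership masks used for the aggregate densities
_A_STATES = (ANS, ARS, ARI)          # information spreaders
_R_STATES = (ARS, URS, URI, ARI)     # resource holders
_I_STATES = (URI, ARI, UNI)          # infected


@dataclass(frozen=True)
class StateDistribution:
    """Per-node probabilities over the seven compound states, shape (n, 7)."""

    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != 7:
            raise ValueError("probs must have shape (n_nodes, 7)")
        if p.min() < -1e-12 or p.max() > 1.0 + 1e-12:
            raise ValueError("state probabilities must lie in [0, 1]")
        if np.abs(p.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("each node's seven probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def n_nodes(self) -> int:
        return self.probs.shape[0]

    # aggregate per-node probabilities -----------------------------------
    def p_spreader(self) -> np.ndarray:
        """p_i^A = p^ANS + p^ARS + p^ARI."""
        return self.probs[:, list(_A_STATES)].sum(axis=1)

    def p_resource(self) -> np.ndarray:
        return self.probs[:, list(_R_STATES)].sum(axis=1)

    def p_infected(self) -> np.ndarray:
        """p_i^I = p^URI + p^ARI + p^UNI."""
        return self.probs[:, list(_I_STATES)].sum(axis=1)

    def densities(self) -> tuple[float, float, float]:
        """(ρ_A, ρ_R, ρ_I) population means."""
        return (
            float(self.p_spreader().mean()),
            float(self.p_resource().mean()),
            float(self.p_infected().mean()),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (node, state, probability)."""
        n = self.n_nodes
        return pd.DataFrame(
            {
                "node": np.repeat(np.arange(n), 7),
                "state": list(STATES) * n,
                "probability": self.probs.ravel(),
            }
        )


@dataclass(frozen=True)
class LocalProbabilities:
    """Per-node intermediate quantities entering one MMC step."""

    alpha: np.ndarray
    r: np.ndarray
    s: np.ndarray
    q: np.ndarray
    p_spreader: np.ndarray
    p_infected: np.ndarray


@dataclass(frozen=True)
class SteadySolution:
    """Fixed point (or last iterate) of the synchronous MMC update."""

    distribution: StateDistribution
    rho_A: float
    rho_R: float
    rho_I: float
    iterations: int
    converged: bool
    residual: float

    def summary(self) -> dict:
        return {
            "rho_A": self.rho_A,
            "rho_R": self.rho_R,
            "rho_I": self.rho_I,
            "iterations": self.iterations,
            "converged": self.converged,
            "residual": self.residual,
        }

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.summary(), indent=2))


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def uniform_initial_distribution(net: MultiplexNetwork, rho_A0: float, rho_I0: float) -> StateDistribution:
    """Node-homogeneous mean-field start with no resources (ρ_R = 0).

    Information and infection are assigned independently; the aware∧infected
    mass is routed to UNI because ANI is excluded:

        p^UNI = ρ_I0,  p^ANS = ρ_A0 (1−ρ_I0),  p^UNS = (1−ρ_A0)(1−ρ_I0).
    """
    if not 0.0 <= rho_A0 <= 1.0 or not 0.0 <= rho_I0 <= 1.0:
        raise ValueError("initial fractions must lie in [0, 1]")
    row = np.zeros(7)
    row[UNI] = rho_I0
    row[ANS] = rho_A0 * (1.0 - rho_I0)
    row[UNS] = (1.0 - rho_A0) * (1.0 - rho_I0)
    return StateDistribution(np.tile(row, (net.n_nodes, 1)))


def bernoulli_initial_distribution(
    net: MultiplexNetwork, rho_A0: float, rho_I0: float, seed: int
) -> StateDistribution:
    """Node-resolved 0/1 start mirroring the agent-based initializer."""
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    aware = rng.random(n) < rho_A0
    infected = rng.random(n) < rho_I0
    p = np.zeros((n, 7))
    p[infected, UNI] = 1.0                      # infected start without resources
    p[aware & ~infected, ANS] = 1.0
    p[~aware & ~infected, UNS] = 1.0
    return StateDistribution(p)


# ---------------------------------------------------------------------------
# local probabilities
# ---------------------------------------------------------------------------

def transfer_willingness(dist: StateDistribution, net: MultiplexNetwork, omega: float) -> np.ndarray:
    """α_i = 1 − (1−ω)^(Σ_j b_ji p_j^UNI), a real-valued exponent.

    The exponent is the expected number of requesting (UNI) neighbours on the
    resource layer; np.power handles the ω=1 limit (0^0 = 1 → α=0 when the
    sum is zero, 0^x = 0 for x>0 → α=1).
    """
    b = net.resource_layer.adjacency
    expo = b @ dist.probs[:, UNI]
    return 1.0 - np.power(1.0 - omega, expo)


def acquisition_probability(
    dist: StateDistribution,
    net: MultiplexNetwork,
    alpha: np.ndarray,
    theta: float,
    *,
    conditional: bool = False,
) -> sp.csr_array:
    """Per-edge probabilities π_ij that UNI node i receives from neighbour j.

    π_ij = [p_j^URS + θ p_j^ARS] · p_i^UNI · α_i / Σ_k b_jk p_k^UNI, defined
    as exactly 0 when the denominator vanishes.  With ``conditional=True``
    the p_i^UNI factor is dropped (probability conditioned on i being UNI).
    Returned as a sparse matrix on the resource-layer edge pattern.
    """
    b = net.resource_layer.adjacency
    p_uni = dist.probs[:, UNI]
    denom = b @ p_uni                             # Σ_k b_jk p_k^UNI per node j
    give = dist.probs[:, URS] + theta * dist.probs[:, ARS]
    # denominators below ~1e-200 carry requesting mass (and hence π) that is
    # numerically zero; guard them to avoid overflow in the ratio
    safe = denom > 1e-200
    g = np.where(safe, give / np.where(safe, denom, 1.0), 0.0)
    h = alpha if conditional else p_uni * alpha
    bc = b.tocsr()
    rows = np.repeat(np.arange(bc.shape[0]), np.diff(bc.indptr))
    vals = np.clip(g[bc.indices] * h[rows], 0.0, 1.0)
    return sp.csr_array((vals, bc.indices.copy(), bc.indptr.copy()), shape=b.shape)


def _edge_product(pattern: sp.csr_array, edge_vals: np.ndarray, n: int) -> np.ndarray:
    """Π over row edges of (1 − v_e) given CSR edge values, per node."""
    rows = np.repeat(np.arange(n), np.diff(pattern.indptr))
    with np.errstate(divide="ignore"):
        logs = np.log1p(-np.clip(edge_vals, 0.0, 1.0))
    return np.exp(np.bincount(rows, weights=logs, minlength=n))


def local_probabilities(
    dist: StateDistribution,
    net: MultiplexNetwork,
    params: ModelParams,
    *,
    conditional_transfer: bool = False,
) -> LocalProbabilities:
    """Compute α, r, s, q and the aggregate p^A, p^I for one step."""
    n = dist.n_nodes
    p_a = dist.p_spreader()
    p_i = dist.p_infected()

    alpha = transfer_willingness(dist, net, params.omega)
    pi = acquisition_probability(dist, net, alpha, params.theta, conditional=conditional_transfer)

    a = net.info_layer.adjacency
    c = net.epidemic_layer.adjacency
    with np.errstate(divide="ignore"):
        r = np.exp(a @ np.log1p(-np.clip(params.lambda_info * p_a, 0.0, 1.0)))
        q = np.exp(c @ np.log1p(-np.clip(params.beta * p_i, 0.0, 1.0)))
    s = _edge_product(pi, pi.data, n)
    return LocalProbabilities(alpha=alpha, r=r, s=s, q=q, p_spreader=p_a, p_infected=p_i)


# ---------------------------------------------------------------------------
# synchronous update
# ---------------------------------------------------------------------------

def effective_allocation(
    strategy: AllocationStrategy,
    eta: float,
    susceptible_fraction: float,
    infected_fraction: float,
    *,
    per_individual: bool = False,
) -> tuple[float, float]:
    """Per-step allocation probabilities (η in the S branches, η in the UNI branch).

    The external supply is a fixed budget of ηN resources per step, spread
    uniformly over the strategy's designated compartment; resource-less
    members therefore acquire one with probability min(1, η / compartment
    fraction) (shares landing on current holders are wasted).  For random
    allocation the compartment is the whole population, so the probability
    is exactly η — the unmodified update equations.  With ``per_individual``
    the rescaling is skipped and every eligible node simply draws η.
    """
    eta_s, eta_i = strategy.eta_split(eta)
    if per_individual or eta == 0.0:
        return eta_s, eta_i
    if strategy is AllocationStrategy.SUSCEPTIBLE_ONLY:
        eta_s = min(1.0, eta / susceptible_fraction) if susceptible_fraction > 0.0 else 0.0
    elif strategy is AllocationStrategy.INFECTED_ONLY:
        eta_i = min(1.0, eta / infected_fraction) if infected_fraction > 0.0 else 0.0
    return eta_s, eta_i


def mmc_step(
    dist: StateDistribution,
    net: MultiplexNetwork,
    params: ModelParams,
    strategy: AllocationStrategy | str = AllocationStrategy.RANDOM_ALL,
    *,
    conditional_transfer: bool = False,
    per_individual_eta: bool = False,
) -> StateDistribution:
    """One synchronous seven-state update (the probability-tree equations).

    The external-allocation probability enters the probability trees in the
    susceptible (UNS/ANS) branches and/or the UNI branch (no-resource factor
    (1−η)s_i) according to the strategy, with the budget rescaling described
    in :func:`effective_allocation`.
    """
    strategy = AllocationStrategy.coerce(strategy)
    loc = local_probabilities(dist, net, params, conditional_transfer=conditional_transfer)

    p = dist.probs
    uns, ans, ars, urs, uri, ari, uni = (p[:, k] for k in range(7))
    al, r, s, q = loc.alpha, loc.r, loc.s, loc.q
    d, th = params.delta, params.theta
    mu_n, mu_r = params.mu_N, params.mu_R

    eta_s, eta_i = effective_allocation(
        strategy,
        params.eta,
        1.0 - float(loc.p_infected.mean()),
        float(loc.p_infected.mean()),
        per_individual=per_individual_eta,
    )

    # no-resource probability of a UNI node after allocation + peer transfer
    no_aid = (1.0 - eta_i) * s

    new = np.empty_like(p)
    new[:, UNS] = (
        uns * r * (1 - eta_s) * q
        + ans * d * (1 - eta_s) * q
        + ars * d * al * q
        + urs * r * al * q
        + uri * r * mu_r
        + ari * d * mu_r
        + uni * no_aid * mu_n
        + uni * (1 - no_aid) * mu_r
    )
    new[:, ANS] = (
        uns * (1 - r) * (1 - eta_s) * q
        + ans * (1 - d) * (1 - eta_s) * q
        + ars * (1 - d) * th * al * q
        + urs * (1 - r) * th * al * q
        + uri * (1 - r) * mu_r
        + ari * (1 - d) * mu_r
    )
    new[:, ARS] = (
        uns * (1 - r) * eta_s * q
        + ans * (1 - d) * eta_s * q
        + ars * (1 - d) * (1 - th * al) * q
        + urs * (1 - r) * (1 - th * al) * q
    )
    new[:, URS] = (
        uns * r * eta_s * q
        + ans * d * eta_s * q
        + ars * d * (1 - al) * q
        + urs * r * (1 - al) * q
    )
    new[:, URI] = (
        uns * r * eta_s * (1 - q)
        + ans * d * eta_s * (1 - q)
        + ars * d * (1 - al) * (1 - q)
        + urs * r * (1 - al) * (1 - q)
    )
    new[:, ARI] = (
        uns * (1 - r) * eta_s * (1 - q)
        + ans * (1 - d) * eta_s * (1 - q)
        + ars * (1 - d) * (1 - th * al) * (1 - q)
        + urs * (1 - r) * (1 - th * al) * (1 - q)
    )
    new[:, UNI] = (
        uns * (1 - eta_s) * (1 - q)
        + ans * (1 - eta_s) * (1 - q)
        + ars * (d * al + (1 - d) * th * al) * (1 - q)
        + urs * (r * al + (1 - r) * th * al) * (1 - q)
        + uri * (1 - mu_r)
        + ari * (1 - mu_r)
        + uni * no_aid * (1 - mu_n)
        + uni * (1 - no_aid) * (1 - mu_r)
    )
    return StateDistribution(new)


def iterate_to_steady_state(
    dist0: StateDistribution,
    net: MultiplexNetwork,
    params: ModelParams,
    strategy: AllocationStrategy | str = AllocationStrategy.RANDOM_ALL,
    tol: float = 1e-9,
    max_iter: int = 20000,
    *,
    conditional_transfer: bool = False,
    per_individual_eta: bool = False,
) -> SteadySolution:
    """Iterate the synchronous update until the max-abs one-step change < tol.

    Non-convergence within ``max_iter`` is reported via the ``converged``
    flag, never raised; densities are read from the final iterate.
    """
    dist = dist0
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        new = mmc_step(
            dist,
            net,
            params,
            strategy,
            conditional_transfer=conditional_transfer,
            per_individual_eta=per_individual_eta,
        )
        residual = float(np.max(np.abs(new.probs - dist.probs)))
        dist = new
        if residual < tol:
            break
    rho_a, rho_r, rho_i = dist.densities()
    return SteadySolution(
        distribution=dist,
        rho_A=rho_a,
        rho_R=rho_r,
        rho_I=rho_i,
        iterations=it,
        converged=residual < tol,
        residual=residual,
    )
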