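"""Agent-based Monte-Carlo engine applying the same rules as the MMC.

Every node holds one discrete compound state (UNS, ANS, ARS, URS, URI, ARI,
UNI; ANI is forbidden).  One synchronous step, sampled entirely from the
time-t configuration:

1. information layer — each unaware node (except UNI, which has ceased
   participating in the information process while requesting aid) becomes a
   spreader with probability 1−(1−λ)^k_A over its spreading neighbours;
   each spreader quits with probability δ;
2. external allocation — a budget of ηN resources is spread uniformly over
   the strategy's designated compartment (everyone / susceptibles /
   infecteds), so each resource-less member receives one with probability
   min(1, ηN / compartment size); for random allocation this is exactly η;
3. peer transfer — each susceptible resource holder with n ≥ 1 requesting
   (UNI) resource-layer neighbours transfers with probability 1−(1−w)^n,
   where w = ω for an (updated-state) unaware donor and w = θω for a
   spreader; the recipient is chosen uniformly among its UNI neighbours;
   the donor always loses the resource, colliding surplus deliveries are
   wasted (a recipient's resource state is binary);
4. epidemic layer — each susceptible contracts infection with probability
   1−(1−β)^k_I over infected neighbours; each node infected at time t
   recovers with μ_R if it holds or has just obtained a resource (consumed
   either way) and μ_N otherwise;
5. coercion — any aware ∧ infected ∧ resource-less outcome is set to UNI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mmc import STATES, UNS, ANS, ARS, URS, URI, ARI, UNI, effective_allocation
from .networks import MultiplexNetwork
from .params import AllocationStrategy, ModelParams

__all__ = ["AgentConfiguration", "EnsembleResult", "initialize_agents", "mc_step", "run_trajectory", "run_ensemble"]

# compound-state lookup: index = 4*aware + 2*resource + infected
# the two ANI slots (aware, no resource, infected) are coerced to UNI
_COMPOSE = np.array([UNS, UNI, URS, URI, ANS, UNI, ARS, ARI], dtype=np.int8)

_AWARE = np.zeros(7, dtype=bool)
_AWARE[[ANS, ARS, ARI]] = True
_RESOURCE = np.zeros(7, dtype=bool)
_RESOURCE[[ARS, URS, URI, ARI]] = True
_INFECTED = np.zeros(7, dtype=bool)
_INFECTED[[URI, ARI, UNI]] = True


@dataclass(frozen=True)
class AgentConfiguration:
    """Discrete per-node compound states (int8 codes into ``STATES``)."""

    state: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.state, dtype=np.int8)
        if s.ndim != 1 or s.min() < 0 or s.max() > 6:
            raise ValueError("state must be a 1-D array of codes 0..6")
        object.__setattr__(self, "state", s)

    @property
    def n_nodes(self) -> int:
        return self.state.shape[0]

    def aware(self) -> np.ndarray:
        return _AWARE[self.state]

    def has_resource(self) -> np.ndarray:
        return _RESOURCE[self.state]

    def infected(self) -> np.ndarray:
        return _INFECTED[self.state]

    def densities(self) -> tuple[float, float, float]:
        """(ρ_A, ρ_R, ρ_I) fractions of spreaders, holders, infecteds."""
        n = self.n_nodes
        return (
            float(self.aware().sum() / n),
            float(self.has_resource().sum() / n),
            float(self.infected().sum() / n),
        )

    def counts(self) -> dict[str, int]:
        c = np.bincount(self.state, minlength=7)
        return {name: int(k) for name, k in zip(STATES, c)}


def initialize_agents(net: MultiplexNetwork, rho_A0: float, rho_I0: float, seed: int) -> AgentConfiguration:
    """⌊ρ_I0 N⌋ infected and ⌊ρ_A0 N⌋ aware nodes, drawn independently,
    nobody holding resources; aware ∧ infected nodes are coerced to UNI."""
    if not 0.0 <= rho_A0 <= 1.0 or not 0.0 <= rho_I0 <= 1.0:
        raise ValueError("initial fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    infected = np.zeros(n, dtype=bool)
    infected[rng.choice(n, size=int(rho_I0 * n), replace=False)] = True
    aware = np.zeros(n, dtype=bool)
    aware[rng.choice(n, size=int(rho_A0 * n), replace=False)] = True
    state = np.full(n, UNS, dtype=np.int8)
    state[aware] = ANS
    state[infected] = UNI  # infected start resource-less; aware∧infected → UNI
    return AgentConfiguration(state)


def _pick_uni_neighbors(
    bc, donors: np.ndarray, is_uni: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """For each donor row, pick one uniformly-random UNI neighbour (vectorized).

    ``donors`` must all have >= 1 UNI neighbour on the resource layer ``bc``
    (CSR).  Returns the chosen recipient node index per donor.
    """
    starts = bc.indptr[donors]
    lengths = (bc.indptr[donors + 1] - starts).astype(np.int64)
    total = int(lengths.sum())
    ends = np.cumsum(lengths)
    # flat array of every neighbour of every donor, donor-major order
    row_of = np.repeat(np.arange(donors.size), lengths)
    offs = np.arange(total) - np.repeat(ends - lengths, lengths)
    flat = bc.indices[np.repeat(starts, lengths) + offs]
    mask = is_uni[flat]
    # 0-based rank of each UNI neighbour within its donor row
    cum = np.cumsum(mask)
    n_uni = np.bincount(row_of, weights=mask, minlength=donors.size).astype(np.int64)
    cum_before_row = cum[ends - 1] - n_uni
    rank = cum - 1 - np.repeat(cum_before_row, lengths)
    target = rng.integers(0, n_uni)  # uniform 0..n_uni-1 per donor
    return flat[mask & (rank == target[row_of])]


def mc_step(
    config: AgentConfiguration,
    net: MultiplexNetwork,
    params: ModelParams,
    strategy: AllocationStrategy | str,
    rng: np.random.Generator,
    *,
    per_individual_eta: bool = False,
    first_donor_only: bool = False,
) -> AgentConfiguration:
    """One synchronous stochastic update of every agent (see module rules)."""
    strategy = AllocationStrategy.coerce(strategy)
    n = config.n_nodes
    st = config.state
    aware_t = config.aware()
    res_t = config.has_resource()
    inf_t = config.infected()
    is_uni = st == UNI

    a = net.info_layer.adjacency
    b = net.resource_layer.adjacency
    c = net.epidemic_layer.adjacency

    # 1. information (UNI keeps U: it has withdrawn from the info process)
    k_a = a @ aware_t.astype(np.float64)
    p_adopt = 1.0 - np.power(1.0 - params.lambda_info, k_a)
    u = rng.random(n)
    new_aware = np.where(
        aware_t,
        u >= params.delta,                       # spreaders quit w.p. δ
        (u < p_adopt) & ~is_uni,                 # unaware adopt; UNI stays U
    )

    # 2. external allocation to resource-less members of the compartment
    n_inf = int(inf_t.sum())
    eta_s, eta_i = effective_allocation(
        strategy,
        params.eta,
        (n - n_inf) / n,
        n_inf / n,
        per_individual=per_individual_eta,
    )
    allocated = (~res_t) & (rng.random(n) < np.where(inf_t, eta_i, eta_s))

    # 3. peer transfer from susceptible holders to requesting UNI neighbours
    n_uni_nb = (b @ is_uni.astype(np.float64)).astype(np.int64)
    donors_mask = res_t & ~inf_t & (n_uni_nb > 0)
    received = np.zeros(n, dtype=bool)
    transferred = np.zeros(n, dtype=bool)
    if donors_mask.any():
        w = np.where(new_aware, params.theta * params.omega, params.omega)
        p_transfer = 1.0 - np.power(1.0 - w, n_uni_nb)
        does = donors_mask & (rng.random(n) < p_transfer)
        donors = np.flatnonzero(does)
        if donors.size:
            recipients = _pick_uni_neighbors(b, donors, is_uni, rng)
            if first_donor_only:
                # only the first donor targeting a recipient spends its resource
                keep = np.zeros(donors.size, dtype=bool)
                seen: set[int] = set()
                for idx, rcp in enumerate(recipients):
                    if int(rcp) not in seen:
                        seen.add(int(rcp))
                        keep[idx] = True
                donors = donors[keep]
                recipients = recipients[keep]
            transferred[donors] = True
            received[recipients] = True

    # 4. epidemic layer
    k_i = c @ inf_t.astype(np.float64)
    p_inf = 1.0 - np.power(1.0 - params.beta, k_i)
    newly_infected = ~inf_t & (rng.random(n) < p_inf)

    has_aid = res_t | allocated | received       # resource available to an infected
    rec_prob = np.where(has_aid, params.mu_R, params.mu_N)
    recovers = inf_t & (rng.random(n) < rec_prob)

    # compose next state
    res_next = np.where(
        inf_t,
        False,                                   # infecteds consume any resource
        (res_t & ~transferred) | allocated | received,
    )
    inf_next = np.where(inf_t, ~recovers, newly_infected)
    idx = 4 * new_aware.astype(np.int8) + 2 * res_next.astype(np.int8) + inf_next.astype(np.int8)
    return AgentConfiguration(_COMPOSE[idx])


@dataclass(frozen=True)
class EnsembleResult:
    """Steady densities averaged over a window, then over independent runs."""

    rho_A: float
    rho_R: float
    rho_I: float
    n_runs: int
    burn_in: int
    window: int
    per_run: pd.DataFrame = field(repr=False)     # run_id, rho_A, rho_R, rho_I
    trajectories: list[pd.DataFrame] | None = field(default=None, repr=False)

    def summary(self) -> dict:
        return {
            "rho_A": self.rho_A,
            "rho_R": self.rho_R,
            "rho_I": self.rho_I,
            "n_runs": self.n_runs,
            "burn_in": self.burn_in,
            "window": self.window,
        }

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.summary(), indent=2))


def run_trajectory(
    net: MultiplexNetwork,
    params: ModelParams,
    strategy: AllocationStrategy | str,
    t_max: int,
    seed: int,
    *,
    rho_A0: float = 0.1,
    rho_I0: float = 0.1,
    stop_on_extinction: bool = True,
    settle: int = 100,
    config0: AgentConfiguration | None = None,
) -> pd.DataFrame:
    """One realization; returns a (t, rho_A, rho_R, rho_I) table of length t_max+1.

    With ``stop_on_extinction`` the loop runs ``settle`` more steps after the
    infection dies out (letting ρ_A and ρ_R relax in the infection-free
    dynamics) and then holds the final densities constant — once ρ_I = 0 the
    epidemic can never restart.
    """
    rng = np.random.default_rng(seed)
    config = config0 if config0 is not None else initialize_agents(net, rho_A0, rho_I0, seed)
    rows = np.empty((t_max + 1, 3))
    rows[0] = config.densities()
    extinct_since: int | None = None
    for t in range(1, t_max + 1):
        config = mc_step(config, net, params, strategy, rng)
        rows[t] = config.densities()
        if stop_on_extinction and rows[t, 2] == 0.0:
            if extinct_since is None:
                extinct_since = t
            elif t - extinct_since >= settle:
                rows[t + 1 :] = rows[t]
                break
        else:
            extinct_since = None
    out = pd.DataFrame(rows, columns=["rho_A", "rho_R", "rho_I"])
    out.insert(0, "t", np.arange(t_max + 1))
    return out


def run_ensemble(
    net: MultiplexNetwork,
    params: ModelParams,
    strategy: AllocationStrategy | str = AllocationStrategy.RANDOM_ALL,
    n_runs: int = 20,
    t_max: int = 1000,
    burn_in: int = 800,
    window: int = 200,
    seed: int = 0,
    *,
    rho_A0: float = 0.1,
    rho_I0: float = 0.1,
    keep_trajectories: bool = False,
) -> EnsembleResult:
    """Independent realizations; densities averaged over each run's final
    ``window`` steps, then across runs.  Run ``k`` uses RNG seed ``seed+k``."""
    if window > t_max - burn_in + 1:
        raise ValueError("window must fit after burn_in within t_max")
    per_run = []
    trajs: list[pd.DataFrame] = []
    for k in range(n_runs):
        traj = run_trajectory(
            net, params, strategy, t_max, seed + k, rho_A0=rho_A0, rho_I0=rho_I0
        )
        tail = traj.iloc[-window:]
        per_run.append(
            {
                "run_id": k,
                "rho_A": float(tail["rho_A"].mean()),
                "rho_R": float(tail["rho_R"].mean()),
                "rho_I": float(tail["rho_I"].mean()),
            }
        )
        if keep_trajectories:
            traj = traj.copy()
            traj["run_id"] = k
            trajs.append(traj)
    table = pd.DataFrame(per_run)
    return EnsembleResult(
        rho_A=float(table["rho_A"].mean()),
        rho_R=float(table["rho_R"].mean()),
        rho_I=float(table["rho_I"].mean()),
        n_runs=n_runs,
        burn_in=burn_in,
        window=window,
        per_run=table,
        trajectories=trajs if keep_trajectories else None,
    )
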