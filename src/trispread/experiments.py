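"""Config-driven experiment drivers: engine comparison, strategy grids,
threshold surfaces.

Each driver takes an :class:`ExperimentSpec` (constructible from a YAML/JSON
mapping) and returns tidy pandas tables that round-trip through CSV.  All
randomness flows from the spec's ``seed``; rerunning a spec reproduces the
outputs exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mc import run_ensemble
from .mmc import iterate_to_steady_state, uniform_initial_distribution
from .networks import MultiplexNetwork, generate_multiplex, leading_eigenvalue, read_edge_list
from .params import AllocationStrategy, ModelParams
from .threshold import analytic_threshold, threshold_scan

__all__ = ["ExperimentSpec", "ComparisonTable", "run_comparison", "run_strategy_grid", "run_threshold_surface"]

log = logging.getLogger("trispread")

_DEFAULT_BETAS = tuple(np.round(np.arange(0.0, 0.6001, 0.02), 4))


@dataclass(frozen=True)
class ExperimentSpec:
    """Settings for one experiment.

    Defaults mirror the reference setting: N=10000, ⟨k⟩=6, BA information
    layer over independent ER physical layers, initial ρ_A = ρ_I = 0.1 with
    no resources, MC ensembles of 20 runs.  ``scale`` divides N and n_runs
    proportionally for desk-scale runs (minimum N=500, 5 runs).
    """

    n: int = 10000
    mean_degree: float = 6.0
    topologies: tuple[str, str, str] = ("ba", "er", "er")
    layer_files: tuple[str, str, str] | None = None
    params: ModelParams = field(default_factory=ModelParams)
    betas: Sequence[float] = _DEFAULT_BETAS
    strategy: AllocationStrategy = AllocationStrategy.RANDOM_ALL
    engine: str = "both"  # mmc | mc | both
    n_runs: int = 20
    t_max: int = 1000
    burn_in: int = 800
    window: int = 200
    rho_A0: float = 0.1
    rho_I0: float = 0.1
    seed: int = 0
    tol: float = 1e-9
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if self.engine not in ("mmc", "mc", "both"):
            raise ValueError("engine must be one of mmc | mc | both")
        if len(self.betas) == 0:
            raise ValueError("beta grid must be non-empty")
        object.__setattr__(self, "strategy", AllocationStrategy.coerce(self.strategy))

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "ExperimentSpec":
        cfg = dict(cfg)
        if "params" in cfg and not isinstance(cfg["params"], ModelParams):
            cfg["params"] = ModelParams(**cfg["params"])
        if "topologies" in cfg:
            cfg["topologies"] = tuple(cfg["topologies"])
        return cls(**cfg)

    def scaled(self, factor: float) -> "ExperimentSpec":
        """Proportionally reduced copy for desk-scale runs."""
        if factor <= 0 or factor > 1:
            raise ValueError("scale factor must lie in (0, 1]")
        return replace(
            self,
            n=max(500, int(self.n * factor)),
            n_runs=max(5, int(round(self.n_runs * factor))),
        )

    def build_network(self) -> MultiplexNetwork:
        if self.layer_files is not None:
            layers = [read_edge_list(f) for f in self.layer_files]
            return MultiplexNetwork(*layers)
        net = generate_multiplex(self.n, self.mean_degree, self.topologies, seed=self.seed)
        log.info(
            "generated multiplex n=%d seed=%d realized <k>=(%.3f, %.3f, %.3f)",
            net.n_nodes,
            self.seed,
            *(layer.mean_degree for layer in net.layers),
        )
        return net


@dataclass(frozen=True)
class ComparisonTable:
    """Per-β engine comparison and mean relative errors.

    Relative error is |mmc − mc| / mc, computed only where the MC value is
    positive; the mean is taken over those grid points.
    """

    table: pd.DataFrame
    mean_relative_error: dict[str, float]


def _mmc_steady(net, params, strategy, spec: ExperimentSpec):
    dist0 = uniform_initial_distribution(net, spec.rho_A0, spec.rho_I0)
    return iterate_to_steady_state(dist0, net, params, strategy, tol=spec.tol, max_iter=spec.max_iter)


def run_comparison(spec: ExperimentSpec) -> ComparisonTable:
    """MMC and/or MC steady densities across the β grid on one multiplex."""
    net = spec.build_network()
    rows = []
    for beta in spec.betas:
        p = spec.params.with_(beta=float(beta))
        row: dict = {"beta": float(beta)}
        if spec.engine in ("mmc", "both"):
            sol = _mmc_steady(net, p, spec.strategy, spec)
            row |= {"rho_A_mmc": sol.rho_A, "rho_R_mmc": sol.rho_R, "rho_I_mmc": sol.rho_I}
            log.info("beta=%.3f mmc converged=%s iters=%d", beta, sol.converged, sol.iterations)
        if spec.engine in ("mc", "both"):
            ens = run_ensemble(
                net,
                p,
                spec.strategy,
                n_runs=spec.n_runs,
                t_max=spec.t_max,
                burn_in=spec.burn_in,
                window=spec.window,
                seed=spec.seed,
                rho_A0=spec.rho_A0,
                rho_I0=spec.rho_I0,
            )
            row |= {"rho_A_mc": ens.rho_A, "rho_R_mc": ens.rho_R, "rho_I_mc": ens.rho_I}
        rows.append(row)
    table = pd.DataFrame(rows)

    mre: dict[str, float] = {}
    if spec.engine == "both":
        for qty in ("rho_A", "rho_R", "rho_I"):
            mc = table[f"{qty}_mc"]
            mmc = table[f"{qty}_mmc"]
            ok = mc > 0
            table[f"rel_err_{qty}"] = np.where(ok, np.abs(mmc - mc) / mc.where(ok), np.nan)
            mre[qty] = float(table.loc[ok, f"rel_err_{qty}"].mean())
    return ComparisonTable(table=table, mean_relative_error=mre)


def run_strategy_grid(
    spec: ExperimentSpec,
    grid_param: str,
    grid_values: Sequence[float],
    *,
    with_threshold: bool = False,
) -> pd.DataFrame:
    """Steady MMC ρ_A and ρ_I over a (grid_param × β) grid for one strategy.

    ``grid_param`` is any :class:`ModelParams` field (typically lambda_info,
    eta or gamma).  With ``with_threshold`` the random-allocation analytic
    β_c for each row's parameters is appended.
    """
    if len(grid_values) == 0:
        raise ValueError("grid must be non-empty")
    net = spec.build_network()
    rows = []
    for gv in grid_values:
        base = spec.params.with_(**{grid_param: float(gv)})
        bc = analytic_threshold(base, net.epidemic_layer).beta_c if with_threshold else None
        for beta in spec.betas:
            p = base.with_(beta=float(beta))
            sol = _mmc_steady(net, p, spec.strategy, spec)
            row = {
                grid_param: float(gv),
                "beta": float(beta),
                "strategy": spec.strategy.value,
                "rho_A": sol.rho_A,
                "rho_I": sol.rho_I,
                "converged": sol.converged,
            }
            if with_threshold:
                row["beta_c_analytic"] = bc
            rows.append(row)
    return pd.DataFrame(rows)


def run_threshold_surface(
    spec: ExperimentSpec,
    eta_values: Sequence[float],
    gamma_values: Sequence[float],
    n_seeds: int = 5,
) -> pd.DataFrame:
    """Analytic β_c over an (η, γ) grid, repeated over network seeds.

    Returns tidy columns (eta, gamma, seed, beta_c, delta_max, topology)
    plus per-cell mean and sd via groupby-friendly layout.
    """
    rows = []
    for k in range(n_seeds):
        seed = spec.seed + k
        net = generate_multiplex(spec.n, spec.mean_degree, spec.topologies, seed=seed)
        dmax = leading_eigenvalue(net.epidemic_layer)
        log.info("seed=%d delta_max=%.4f", seed, dmax)
        scan = threshold_scan(spec.params, net.epidemic_layer, eta_values, gamma_values)
        scan["seed"] = seed
        scan["delta_max"] = dmax
        scan["topology"] = spec.topologies[2]
        rows.append(scan)
    return pd.concat(rows, ignore_index=True)
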