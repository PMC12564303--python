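# trispread

Coupled spreading of **panic information**, **therapeutic resources**, and an
**epidemic** on a three-layer multiplex network.

During an outbreak, three processes feed back on each other: panic-laden
misinformation spreads on online platforms, therapeutic resources are
centrally distributed and passed between acquaintances, and the disease
itself spreads over physical contacts.  `trispread` models this as three
coupled discrete-time processes — UAU information dynamics on layer A, an
NRN (no-resource / resource / no-resource) supply-and-transfer process on
layer B, and SIS epidemics on layer C — over one shared set of N
individuals.  Infected individuals recover at the bare rate μ_N = μ without
a resource and at μ_R = min(γμ, 1) with one; panic dampens the willingness
to share resources by a factor θ; an infected individual without a resource
stops spreading panic and requests aid, so the compound state
"spreading ∧ infected ∧ resource-less" never occurs.

The package is aimed at researchers in network epidemiology who want to
study how allocation strategy (random, susceptible-only, infected-only),
supply η, sharing willingness ω and treatment efficacy γ shape prevalence
and the outbreak threshold.  It provides:

* `trispread.mmc` — a vectorized microscopic Markov chain (per-node
  probability) engine with a seven-state synchronous update and fixed-point
  steady-state solver;
* `trispread.mc` — an agent-based Monte-Carlo engine obeying the identical
  rules, for validating the probability equations;
* `trispread.threshold` — the closed-form epidemic threshold
  β_c = [η μ_R + (1−η) μ_N] / Δmax(C) (Δmax(C) is the leading adjacency
  eigenvalue of the epidemic layer), a linear-stability growth factor, and
  numeric onset detection from prevalence curves;
* `trispread.networks` — ER / BA layer generators, edge-list I/O and small
  deterministic fixtures;
* `trispread.experiments` + a `trispread` CLI — config-driven drivers for
  engine comparisons, strategy grids and threshold surfaces.

## Worked example

```python
from trispread import (
    ModelParams, generate_multiplex, uniform_initial_distribution,
    iterate_to_steady_state, run_ensemble, analytic_threshold,
)

# scale-free information layer over two independent random physical layers
net = generate_multiplex(10_000, mean_degree=6.0,
                         topologies=("ba", "er", "er"), seed=1)
params = ModelParams(lambda_info=0.5, delta=0.3, eta=0.2, omega=0.3,
                     theta=0.0, beta=0.16, mu=0.3, gamma=3.0)

dist0 = uniform_initial_distribution(net, rho_A0=0.1, rho_I0=0.1)
sol = iterate_to_steady_state(dist0, net, params, "random_all")
print(f"MMC: rho_A={sol.rho_A:.4f} rho_R={sol.rho_R:.4f} "
      f"rho_I={sol.rho_I:.4f} ({sol.iterations} iterations)")

ens = run_ensemble(net, params, "random_all", n_runs=20, seed=1)
print(f"MC : rho_A={ens.rho_A:.4f} rho_R={ens.rho_R:.4f} rho_I={ens.rho_I:.4f}")

bc = analytic_threshold(params, net.epidemic_layer)
print(f"beta_c = {bc.beta_c:.4f}  (Dmax = {bc.delta_max:.3f})")
```

Output:

```
MMC: rho_A=0.3848 rho_R=0.2371 rho_I=0.3708 (83 iterations)
MC : rho_A=0.4186 rho_R=0.2737 rho_I=0.3344
beta_c = 0.0588  (Dmax = 7.145)
```

At β=0.16 roughly 37% of the population is infected at steady state, about
38–41% spread the panic message (the two engines bracket it), and under a
quarter hold a resource at any moment — recovery keeps consuming them.
The closed-form threshold says an epidemic with β below ≈0.06 cannot
invade; because the disease-free state is resource-saturated, the observed
onset for γ>1 is delayed beyond this bound and the transition is
discontinuous (see `docs/methods.md`).

Strategy choice matters enormously.  At β=0.12, λ=0.32 (η=0.4, μ=0.2,
γ=4), the steady prevalence is ≈0.18 under random allocation, ≈0.37 when
the budget goes to susceptibles (who hoard), and ≈0.03 when it goes
straight to the infected:

```bash
trispread simulate mmc --beta 0.12 --lambda-info 0.32 --eta 0.4 \
    --mu 0.2 --gamma 4 --strategy infected_only --seed 1
```

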