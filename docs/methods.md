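# Model and methods

## The coupled three-process model

`trispread` simulates the co-evolution of three discrete-time processes over
one population of N individuals, each process living on its own network
layer of the same node set:

* **Panic information (UAU)** on the online layer A: unaware (U) nodes
  adopt the panic message from each spreading neighbour independently with
  probability λ per step; spreaders (A) quit with probability δ.
* **Therapeutic resources (NRN)** on the contact layer B: a central source
  distributes a budget of ηN resources per step, and resource-holding
  susceptibles may pass their resource to one requesting infected
  neighbour.  A resource is binary (held or not) and is consumed the moment
  an infected individual uses it for a recovery attempt.
* **Epidemic (SIS)** on the contact layer C: susceptibles are infected by
  each infectious neighbour independently with probability β; infected
  individuals recover with probability μ_N = μ bare, or μ_R = min(γμ, 1)
  when they hold or have just obtained a resource (γ ≥ 1 is the treatment
  efficacy).

The joint state of a node is a compound label over (information, resource,
health).  Seven of the eight combinations are admissible — UNS, ANS, ARS,
URS, URI, ARI, UNI.  The eighth, ANI (spreading ∧ infected ∧ resource-less),
is excluded by a behavioural rule: an infected individual without a
resource turns to its neighbours for help and stops spreading panic, so any
such outcome is coerced to UNI.  This coercion is the main coupling from
the epidemic back onto the information layer; the coupling in the other
direction is the panic-mitigation factor θ ∈ [0, 1], which dampens a
spreader's willingness to transfer its resource (θ·willingness instead of
willingness; θ=0 means spreaders hoard unconditionally).

### Transfer microdynamics

A susceptible holder i with n requesting (UNI) neighbours on layer B
transfers with probability 1 − (1−ω)^n (ω is the per-request willingness),
giving the resource to one of those neighbours chosen uniformly.  The
mean-field engine works with the expected requesting mass
Σ_j b_ji p_j^UNI instead of the integer n:

    α_i = 1 − (1−ω)^{Σ_j b_ji p_j^UNI}.

A requesting node i obtains the resource of neighbour j with the per-edge
probability

    π_ij = [p_j^URS + θ p_j^ARS] · p_i^UNI · α_i / Σ_k b_jk p_k^UNI,

defined as exactly 0 when the denominator vanishes, and escapes aid
entirely with s_i = Π_j (1 − b_ji π_ij).

Note the conditioning subtlety: s_i is applied inside the UNI branch of the
update — already conditioned on i being UNI — yet π_ij carries an explicit
p_i^UNI factor.  The engine implements this form, which reproduces the
reference steady-state densities; the cleanly conditioned alternative
(dropping the p_i^UNI factor) is available via `conditional_transfer=True`.
The distinction is not cosmetic: under the default form a donor gives its
resource up with probability θα while the matching delivery is discounted
by p^UNI, so increasing θ can *slightly raise* prevalence by draining
donors faster than it helps the infected (a shift of a few 10⁻³ in ρ_I
over θ ∈ [0, 1] on a 300-node test multiplex, bounded below 0.01 in the
tests).  The conditioned form is monotone.  The test suite pins both
behaviours.

### External allocation strategies

The per-step budget ηN is spread uniformly over the designated compartment:

* `random_all` — the whole population; every resource-less node draws η.
  This is the unmodified seven-state update.
* `susceptible_only` — all susceptibles; resource-less susceptibles draw
  min(1, η / ρ_S).  Shares landing on current holders are wasted.
* `infected_only` — all infected; UNI nodes draw min(1, η / ρ_I).

Because the budget concentrates on a compartment that may be much smaller
than the population, the per-member probability is capped at 1 — with few
infected, `infected_only` guarantees every requesting node a resource,
which is what makes it so effective (steady prevalence ≈0.03 vs ≈0.18 for
random allocation at the reference setting).  A strict per-individual
variant with no rescaling (`per_individual_eta=True`) is kept for
sensitivity analysis.

## The two engines

**MMC engine** (`trispread.mmc`): per-node state probabilities evolved by
the synchronous seven-state update built from the probability transition
trees (information branch → allocation/transfer branch → epidemic branch),
assuming neighbour independence.  Probability conservation is exact by the
tree structure (each row sums to 1 to ~1e-16) and is asserted at 1e-12.
The steady state is a fixed-point iteration: the update is repeated until
the max-abs one-step change falls below `tol` (default 1e-9, default cap
20000 iterations; typical convergence 100–300 iterations away from the
onset).  Non-convergence is reported through a flag, never raised.

**MC engine** (`trispread.mc`): the same rules applied to discrete states
with per-edge independent Bernoulli draws, synchronous over the time-t
configuration.  Donors act on their integer count of requesting
neighbours; when several donors pick the same recipient, the recipient
still holds one binary resource and every donor loses theirs (surplus is
wasted; a `first_donor_only` mode spares the redundant donors).  A
spreader-donor transfers with per-request willingness θω, i.e. probability
1 − (1−θω)^n; this coincides with the mean-field θα for n = 1 and differs
only at higher order.  Ensembles average the final `window` steps of each
run (defaults: 1000 steps, burn-in 800, window 200, 20 runs, one RNG
stream per run seeded seed+k); a run whose infection dies out is settled
for 100 further steps (letting ρ_A and ρ_R relax) and then held.

The per-node next-state *marginals* of one MC step are exactly computable
(each node's outcome depends on its own draws and on donors' independent
draws), which the test suite exploits: replicated single steps are
compared against the tree-enumeration distribution at 3σ binomial
resolution, for all three strategies.

## Epidemic threshold

Linearizing the update around the disease-free state with the recovery mix
η μ_R + (1−η) μ_N gives the closed form

    β_c = [η μ_R + (1−η) μ_N] / Δmax(C),

with Δmax(C) the leading adjacency eigenvalue of the epidemic layer
(`analytic_threshold`; the spectral stability factor β·Δmax/[η μ_R +
(1−η) μ_N] is exposed as `linearized_growth_factor`).  Limits: η=0 →
μ_N/Δmax; η=1 → μ_R/Δmax; γ=1 → μ/Δmax for every η.  β_c is monotone
non-decreasing in η and γ, and is larger on ER than on BA layers at equal
mean degree (hubs raise Δmax).

**Validity caveat (first-order onset).**  The closed form is derived for
an invasion in which infected nodes recover at the η-weighted mix.  The
actual disease-free state of the dynamics is resource-saturated (ρ_R → 1:
with no infections nobody consumes resources, so the whole population ends
up holding one), and an invading infection therefore recovers at ≈μ_R.
For γ > 1 the observed prevalence onset from the standard initial
condition sits near μ_R/Δmax — above the closed form — and the transition
is discontinuous (prevalence jumps from ~0 to a finite value; on a 300-node
ER multiplex at the reference parameters the detected onset is ≈0.10–0.11
vs the closed-form 0.058).  The closed form is exact at γ=1 and is a lower bound
in general; `numeric_threshold` (smallest grid β whose steady ρ_I exceeds
ε, default 1e-3) measures the actual onset, which is also how the
strategy-dependent thresholds are obtained.  The tests assert
one-grid-step agreement at γ=1 and the lower-bound property at γ>1.

## Mean-field accuracy

Where prevalence is solidly established (β ≳ 1.5× the onset) the two
engines agree to well under 0.01 in ρ_I.  In a window just above the
discontinuous onset the neighbour-independence approximation overshoots
the agent process by up to ~0.08 in ρ_I (e.g. β≈0.13 at the comparison
setting, any N from 2000 to 10000) — the jump location itself shifts
slightly between the engines.  The spreader density ρ_A shows the same
pattern reported for the reference implementation: agreement to ~0.02
absolute, with large *relative* errors where ρ_A itself is small.  One
acceptance test asserts a uniform ≤0.02 prevalence gap across a β grid
spanning the onset; it fails at the near-onset grid point for the reasons
above and is left failing deliberately rather than tuned around — consult
the assertion message.

## Synthetic networks

Layers are generated with `networkx`: ER as G(n, p) with p = ⟨k⟩/(n−1),
BA with m = ⟨k⟩/2 attachments (m=3 for the reference ⟨k⟩=6).  Defaults
mirror the study conditions: N=10000, ⟨k⟩=6, scale-free information layer,
independent ER physical layers (a `share_physical` option reuses one graph
for layers B and C), initial ρ_A = ρ_I = 0.1 with no resources.  Graphs
are used as generated — isolated ER nodes are legitimate (both engines
handle them); `require_connected=True` extracts the giant component
instead.  What the generator does *not* emulate: degree correlations,
clustering, community structure, or any temporal rewiring of real contact
networks — conclusions about those features are outside what passing tests
establish.

## Numerical choices

* Products over neighbours are computed in log space
  (exp(Σ log1p(−x))), with −inf handled so that a certain event gives a
  clean 0; the ω=1 and λ=1 limits are exact.
* π_ij denominators of 0 short-circuit to π=0; no division occurs.
* Real-valued exponents in α use `np.power` directly (0⁰=1 gives α=0 for
  zero requesting mass under ω=1).
* Steady-state tolerance 1e-9 (max-abs one-step change), cap 20000
  iterations; results read from the final iterate either way.
* Degenerate inputs (edgeless epidemic layer for a threshold, empty
  grids, unsorted β grids, fractions outside [0,1]) raise `ValueError`
  with a description; non-convergence and a fully subcritical β grid are
  reported in-band (flags), since they are legitimate outcomes.
* Problem sizes in the test suite: unit tests run on 3–5-node fixtures and
  300-node seeded multiplexes; the end-to-end density checks regenerate
  the full N=10000 condition, with the two-engine grid comparison at
  N=2000 and 10 ensemble runs.

## Known limitations

* Heterogeneous per-node parameters, weighted/directed/temporal layers,
  and continuous-time (Gillespie) formulations are out of scope.
* ANI exclusion is enforced by coercion at the end of each MC step; the
  intermediate bookkeeping never materializes the state.
* The closed-form threshold is strategy-independent; strategy effects on
  the onset are numeric only.
* The MC marginal oracle used in tests is exact per node but silent about
  joint correlations between neighbouring nodes within one step.
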