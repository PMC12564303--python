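"""Independent reference implementations used only as test oracles.

Everything here is written for transparency, not speed: scalar loops over
dense adjacency matrices, and explicit enumeration of every root-to-leaf
path of the seven probability transition trees (information branch →
resource branch → epidemic branch, with the aware∧infected∧no-resource
outcome coerced to UNI).  The production engines must reproduce these
numbers; these functions never call them.
"""

from __future__ import annotations

import numpy as np

UNS, ANS, ARS, URS, URI, ARI, UNI = range(7)


def compose_state(aware: bool, resource: bool, infected: bool) -> int:
    """Compound state from the three layer outcomes; ANI is coerced to UNI."""
    if infected and not resource:
        return UNI  # aware or not: an infected node without resources is UNI
    if infected:
        return ARI if aware else URI
    if resource:
        return ARS if aware else URS
    return ANS if aware else UNS


def tree_transition_row(
    state: int,
    *,
    r: float,
    s: float,
    q: float,
    delta: float,
    eta_s: float,
    eta_i: float,
    mu_n: float,
    mu_r: float,
    w_u: float,
    w_a: float,
) -> np.ndarray:
    """Next-state distribution for one node by enumerating its probability tree.

    ``r``/``s``/``q`` are the node's no-exposure / no-peer-resource /
    no-infection probabilities; ``w_u`` and ``w_a`` are its transfer
    probabilities when (after the information branch) it is unaware resp.
    a spreader (the mean-field engine uses w_u = α, w_a = θα).
    """
    row = np.zeros(7)

    def info_branches(src: int):
        if src in (ANS, ARS, ARI):  # spreader root: quits with δ
            return ((False, delta), (True, 1.0 - delta))
        if src == UNI:  # has withdrawn from the information process
            return ((False, 1.0),)
        return ((False, r), (True, 1.0 - r))  # unaware root

    if state in (UNS, ANS):
        for aware, p_a in info_branches(state):
            for res, p_r in ((True, eta_s), (False, 1.0 - eta_s)):
                for inf, p_q in ((True, 1.0 - q), (False, q)):
                    row[compose_state(aware, res, inf)] += p_a * p_r * p_q
    elif state in (ARS, URS):
        for aware, p_a in info_branches(state):
            w = w_a if aware else w_u
            for res, p_r in ((False, w), (True, 1.0 - w)):  # transfer loses it
                for inf, p_q in ((True, 1.0 - q), (False, q)):
                    row[compose_state(aware, res, inf)] += p_a * p_r * p_q
    elif state in (URI, ARI):
        # the held resource is consumed; recovery succeeds with μ_R
        for aware, p_a in info_branches(state):
            row[compose_state(aware, False, False)] += p_a * mu_r
        row[UNI] += 1.0 - mu_r
    else:  # UNI: external or peer aid, then recovery attempt; stays unaware
        aid = 1.0 - (1.0 - eta_i) * s
        row[UNS] += aid * mu_r + (1.0 - aid) * mu_n
        row[UNI] += aid * (1.0 - mu_r) + (1.0 - aid) * (1.0 - mu_n)
    return row


# ---------------------------------------------------------------------------
# naive mean-field local probabilities (dense scalar loops)
# ---------------------------------------------------------------------------

def naive_local_probabilities(probs, A, B, C, params, *, conditional=False):
    """α, π, r, s, q by direct per-edge loops over dense adjacency matrices."""
    n = probs.shape[0]
    lam, omega, theta, beta = params.lambda_info, params.omega, params.theta, params.beta
    p_a = probs[:, ANS] + probs[:, ARS] + probs[:, ARI]
    p_i = probs[:, URI] + probs[:, ARI] + probs[:, UNI]
    p_uni = probs[:, UNI]

    alpha = np.zeros(n)
    for i in range(n):
        expo = sum(B[j, i] * p_uni[j] for j in range(n))
        alpha[i] = 1.0 - (1.0 - omega) ** expo

    pi = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if B[i, j] == 0:
                continue
            denom = sum(B[j, k] * p_uni[k] for k in range(n))
            if denom == 0.0:
                continue
            give = probs[j, URS] + theta * probs[j, ARS]
            pi[i, j] = give * alpha[i] / denom
            if not conditional:
                pi[i, j] *= p_uni[i]

    r = np.ones(n)
    s = np.ones(n)
    q = np.ones(n)
    for i in range(n):
        for j in range(n):
            if A[j, i]:
                r[i] *= 1.0 - p_a[j] * lam
            if B[j, i]:
                s[i] *= 1.0 - pi[i, j]
            if C[j, i]:
                q[i] *= 1.0 - p_i[j] * beta
    return alpha, pi, r, s, q


def naive_mmc_step(probs, A, B, C, params, strategy="random_all", *, per_individual=False):
    """Full independent MMC step: naive locals + tree enumeration per node."""
    n = probs.shape[0]
    alpha, _, r, s, q = naive_local_probabilities(probs, A, B, C, params)
    p_i_mean = float((probs[:, URI] + probs[:, ARI] + probs[:, UNI]).mean())
    eta_s, eta_i = _effective_eta(strategy, params.eta, 1.0 - p_i_mean, p_i_mean, per_individual)
    out = np.zeros_like(probs)
    for i in range(n):
        for st in range(7):
            if probs[i, st] == 0.0:
                continue
            row = tree_transition_row(
                st,
                r=r[i],
                s=s[i],
                q=q[i],
                delta=params.delta,
                eta_s=eta_s,
                eta_i=eta_i,
                mu_n=params.mu_N,
                mu_r=params.mu_R,
                w_u=alpha[i],
                w_a=params.theta * alpha[i],
            )
            out[i] += probs[i, st] * row
    return out


def _effective_eta(strategy, eta, frac_s, frac_i, per_individual):
    name = getattr(strategy, "value", strategy)
    if name == "random_all":
        return eta, eta
    if name == "susceptible_only":
        if per_individual:
            return eta, 0.0
        return (min(1.0, eta / frac_s) if frac_s > 0 else 0.0), 0.0
    if name == "infected_only":
        if per_individual:
            return 0.0, eta
        return 0.0, (min(1.0, eta / frac_i) if frac_i > 0 else 0.0)
    raise ValueError(name)


# ---------------------------------------------------------------------------
# exact per-node marginal for the agent-based step
# ---------------------------------------------------------------------------

def mc_marginal_distribution(state, A, B, C, params, strategy="random_all"):
    """Exact marginal next-state distribution of every node for one MC step.

    Valid for any configuration: each node's next state depends on its own
    independent draws and on donors' independent (transfer, pick) draws, so
    the per-node marginal factorizes even though joint outcomes do not.
    """
    n = state.shape[0]
    lam, omega, theta, delta = params.lambda_info, params.omega, params.theta, params.delta
    aware = np.isin(state, (ANS, ARS, ARI))
    resource = np.isin(state, (ARS, URS, URI, ARI))
    infected = np.isin(state, (URI, ARI, UNI))
    n_inf = int(infected.sum())
    eta_s, eta_i = _effective_eta(strategy, params.eta, (n - n_inf) / n, n_inf / n, False)

    out = np.zeros((n, 7))
    for i in range(n):
        k_a = sum(A[j, i] * aware[j] for j in range(n))
        r_i = (1.0 - lam) ** k_a
        k_i = sum(C[j, i] * infected[j] for j in range(n))
        q_i = (1.0 - params.beta) ** k_i
        # probability no donor delivers to i (only matters when i is UNI)
        s_i = 1.0
        for j in range(n):
            if not (B[j, i] and state[j] in (URS, ARS)):
                continue
            n_uni_j = sum(B[j, k] * (state[k] == UNI) for k in range(n))
            if n_uni_j == 0:
                continue
            if state[j] == ARS:
                p_tr = delta * (1 - (1 - omega) ** n_uni_j) + (1 - delta) * (
                    1 - (1 - theta * omega) ** n_uni_j
                )
            else:
                p_tr = r_i_donor(j, A, aware, lam) * (1 - (1 - omega) ** n_uni_j) + (
                    1 - r_i_donor(j, A, aware, lam)
                ) * (1 - (1 - theta * omega) ** n_uni_j)
            s_i *= 1.0 - p_tr / n_uni_j
        n_uni_i = sum(B[j, i] * (state[j] == UNI) for j in range(n))
        out[i] = tree_transition_row(
            int(state[i]),
            r=r_i,
            s=s_i,
            q=q_i,
            delta=delta,
            eta_s=eta_s,
            eta_i=eta_i,
            mu_n=params.mu_N,
            mu_r=params.mu_R,
            w_u=1 - (1 - omega) ** n_uni_i,
            w_a=1 - (1 - theta * omega) ** n_uni_i,
        )
    return out


def r_i_donor(j, A, aware, lam):
    """Probability donor j stays unaware this step (it was unaware at t)."""
    k_a = sum(A[k, j] * aware[k] for k in range(A.shape[0]))
    return (1.0 - lam) ** k_a


# ---------------------------------------------------------------------------
# plain two-state SIS references (decoupling checks, γ=1)
# ---------------------------------------------------------------------------

def sis_qmf_steady(C, beta, mu, rho0=0.1, tol=1e-12, max_iter=200000):
    """Per-node probability iteration of discrete SIS on one layer."""
    n = C.shape[0]
    p = np.full(n, rho0)
    for _ in range(max_iter):
        q = np.ones(n)
        for i in range(n):
            for j in range(n):
                if C[j, i]:
                    q[i] *= 1.0 - beta * p[j]
        new = (1.0 - p) * (1.0 - q) + p * (1.0 - mu)
        if np.abs(new - p).max() < tol:
            return new
        p = new
    return p


def sis_qmf_steady_sparse(C_sparse, beta, mu, rho0=0.1, tol=1e-12, max_iter=200000):
    """Vectorized variant of :func:`sis_qmf_steady` for larger layers."""
    n = C_sparse.shape[0]
    p = np.full(n, rho0)
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            q = np.exp(C_sparse @ np.log1p(-beta * p))
        new = (1.0 - p) * (1.0 - q) + p * (1.0 - mu)
        if np.abs(new - p).max() < tol:
            return new
        p = new
    return p


def sis_mc_steady(C_sparse, beta, mu, n_runs, t_max, burn_in, seed, rho0=0.1):
    """Direct agent-based SIS on one layer; per-run steady prevalences."""
    n = C_sparse.shape[0]
    vals = []
    for k in range(n_runs):
        rng = np.random.default_rng(seed + k)
        inf = np.zeros(n, bool)
        inf[rng.choice(n, size=int(rho0 * n), replace=False)] = True
        tail = []
        for t in range(t_max):
            k_i = C_sparse @ inf.astype(float)
            new_inf = ~inf & (rng.random(n) < 1.0 - np.power(1.0 - beta, k_i))
            rec = inf & (rng.random(n) < mu)
            inf = (inf & ~rec) | new_inf
            if t >= burn_in:
                tail.append(inf.mean())
        vals.append(float(np.mean(tail)))
    return np.array(vals)
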