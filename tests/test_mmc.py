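import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trispread import (
    AllocationStrategy,
    ModelParams,
    analytic_threshold,
    iterate_to_steady_state,
    mmc_step,
    uniform_initial_distribution,
)
from trispread.mmc import (
    ANS,
    ARS,
    UNI,
    UNS,
    URS,
    StateDistribution,
    acquisition_probability,
    bernoulli_initial_distribution,
    local_probabilities,
    transfer_willingness,
)

import oracles
from conftest import random_distribution

STRATEGIES = list(AllocationStrategy)


def _dense(net):
    return tuple(layer.adjacency.toarray() for layer in net.layers)


class TestInitialDistribution:
    def test_reference_initial_condition(self, triangle3):
        d = uniform_initial_distribution(triangle3, 0.1, 0.1)
        np.testing.assert_allclose(d.probs[:, UNI], 0.1)
        np.testing.assert_allclose(d.probs[:, ANS], 0.09)
        np.testing.assert_allclose(d.probs[:, UNS], 0.81)
        assert d.probs[:, [ARS, URS]].sum() == 0.0

    def test_degenerate_all_unaware(self, triangle3):
        d = uniform_initial_distribution(triangle3, 0.0, 0.0)
        np.testing.assert_allclose(d.probs[:, UNS], 1.0)

    @given(a=st.floats(0, 1), i=st.floats(0, 1))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_rows_sum_to_one(self, a, i):
        from trispread import fixture_multiplex

        d = uniform_initial_distribution(fixture_multiplex("triangle3"), a, i)
        np.testing.assert_allclose(d.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_fraction_rejected(self, triangle3):
        with pytest.raises(ValueError):
            uniform_initial_distribution(triangle3, 1.2, 0.0)

    def test_bernoulli_initializer_deterministic(self, er300):
        d1 = bernoulli_initial_distribution(er300, 0.1, 0.1, seed=4)
        d2 = bernoulli_initial_distribution(er300, 0.1, 0.1, seed=4)
        np.testing.assert_array_equal(d1.probs, d2.probs)
        assert set(np.unique(d1.probs)) <= {0.0, 1.0}


class TestLocalProbabilities:
    def test_transfer_willingness_limits(self, star5):
        # no requesting neighbours → α = 0; exactly one (prob 1) → α = ω
        p = np.zeros((5, 7))
        p[:, UNS] = 1.0
        d = StateDistribution(p)
        np.testing.assert_allclose(transfer_willingness(d, star5, 0.3), 0.0)

        p = np.zeros((5, 7))
        p[:, UNS] = 1.0
        p[1] = 0.0
        p[1, UNI] = 1.0  # one leaf requesting
        d = StateDistribution(p)
        alpha = transfer_willingness(d, star5, 0.3)
        assert alpha[0] == pytest.approx(0.3)  # hub sees one UNI neighbour

    def test_transfer_willingness_two_neighbours(self, star5):
        p = np.zeros((5, 7))
        p[:, UNS] = 1.0
        for leaf in (1, 2):
            p[leaf] = 0.0
            p[leaf, UNI] = 1.0
        alpha = transfer_willingness(StateDistribution(p), star5, 0.3)
        assert alpha[0] == pytest.approx(1 - 0.7**2)  # 0.51

    def test_transfer_willingness_omega_one(self, star5):
        p = np.zeros((5, 7))
        p[:, UNS] = 1.0
        d0 = StateDistribution(p)
        np.testing.assert_allclose(transfer_willingness(d0, star5, 1.0), 0.0)
        p[1] = 0.0
        p[1, UNI] = 0.5
        p[1, UNS] = 0.5
        alpha = transfer_willingness(StateDistribution(p), star5, 1.0)
        assert alpha[0] == 1.0  # any positive requesting mass saturates at ω=1

    def test_acquisition_zero_denominator_and_zero_supply(self, triangle3):
        p = np.zeros((3, 7))
        p[:, UNS] = 1.0  # nobody UNI → denominators vanish
        d = StateDistribution(p)
        alpha = transfer_willingness(d, triangle3, 0.5)
        pi = acquisition_probability(d, triangle3, alpha, theta=0.0)
        assert pi.data.sum() == 0.0

        p = np.zeros((3, 7))
        p[0, UNI] = 1.0
        p[1:, ANS] = 1.0  # aware but resource-less neighbours: nothing to give
        d = StateDistribution(p)
        alpha = transfer_willingness(d, triangle3, 0.5)
        pi = acquisition_probability(d, triangle3, alpha, theta=0.0)
        assert pi.data.sum() == 0.0

    def test_triangle_hand_evaluation(self, triangle3):
        # node 0 requesting with certainty, nodes 1 and 2 holding (URS):
        # node 0 itself sees no requesting neighbours, so its willingness —
        # and hence every π_0j — is zero despite ample supply
        p = np.zeros((3, 7))
        p[0, UNI] = 1.0
        p[1, URS] = 1.0
        p[2, URS] = 1.0
        d = StateDistribution(p)
        alpha = transfer_willingness(d, triangle3, 0.5)
        assert alpha[0] == 0.0
        pi = acquisition_probability(d, triangle3, alpha, theta=0.0).toarray()
        assert pi[0].sum() == 0.0
        # give node 0 a requesting neighbour to exercise a nonzero case
        p = np.zeros((3, 7))
        p[0, UNI] = 1.0
        p[1, URS] = 1.0
        p[2, UNI] = 1.0
        d = StateDistribution(p)
        alpha = transfer_willingness(d, triangle3, 0.5)
        assert alpha[0] == pytest.approx(0.5)  # node 0 sees node 2 requesting
        pi = acquisition_probability(d, triangle3, alpha, theta=0.0).toarray()
        # donor 1 sees requesting mass 2 → π_01 = 1 · 1 · 0.5 / 2 = 0.25
        assert pi[0, 1] == pytest.approx(0.25)

    @pytest.mark.parametrize("fixture", ["star5", "triangle3", "path4"])
    def test_matches_naive_scalar_oracle(self, fixture, request, default_params):
        net = request.getfixturevalue(fixture)
        rng = np.random.default_rng(42)
        d = StateDistribution(random_distribution(net.n_nodes, rng))
        A, B, C = _dense(net)
        alpha_o, _, r_o, s_o, q_o = oracles.naive_local_probabilities(
            d.probs, A, B, C, default_params
        )
        loc = local_probabilities(d, net, default_params)
        np.testing.assert_allclose(loc.alpha, alpha_o, atol=1e-12)
        np.testing.assert_allclose(loc.r, r_o, atol=1e-12)
        np.testing.assert_allclose(loc.s, s_o, atol=1e-12)
        np.testing.assert_allclose(loc.q, q_o, atol=1e-12)


class TestMMCStep:
    @given(
        seed=st.integers(0, 10_000),
        lam=st.floats(0, 1),
        delta=st.floats(0, 1),
        eta=st.floats(0, 1),
        omega=st.floats(0, 1),
        theta=st.floats(0, 1),
        beta=st.floats(0, 1),
        mu=st.floats(0, 1),
        gamma=st.floats(1, 5),
        strategy=st.sampled_from(STRATEGIES),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_probability_conservation(self, seed, lam, delta, eta, omega, theta, beta, mu, gamma, strategy):
        """Every row of the updated distribution sums to 1 (tree structure)."""
        from trispread import fixture_multiplex

        net = fixture_multiplex("triangle3")
        rng = np.random.default_rng(seed)
        d = StateDistribution(random_distribution(3, rng))
        params = ModelParams(lam, delta, eta, omega, theta, beta, mu, gamma)
        out = mmc_step(d, net, params, strategy)
        np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("fixture", ["triangle3", "star5", "path4"])
    @pytest.mark.parametrize("strategy", STRATEGIES)
    @pytest.mark.parametrize("per_individual", [False, True])
    def test_tree_enumeration_oracle(self, fixture, strategy, per_individual, request):
        """The vectorized step equals explicit root-to-leaf path enumeration."""
        net = request.getfixturevalue(fixture)
        rng = np.random.default_rng(sum(map(ord, fixture)))
        A, B, C = _dense(net)
        for k in range(3):
            d = StateDistribution(random_distribution(net.n_nodes, rng))
            params = ModelParams(
                lambda_info=rng.uniform(0, 1),
                delta=rng.uniform(0, 1),
                eta=rng.uniform(0, 1),
                omega=rng.uniform(0, 1),
                theta=rng.uniform(0, 1),
                beta=rng.uniform(0, 1),
                mu=rng.uniform(0, 1),
                gamma=rng.uniform(1, 4),
            )
            expected = oracles.naive_mmc_step(
                d.probs, A, B, C, params, strategy, per_individual=per_individual
            )
            got = mmc_step(d, net, params, strategy, per_individual_eta=per_individual)
            np.testing.assert_allclose(got.probs, expected, atol=1e-12)

    def test_no_infection_source_stays_clean(self, star5, default_params):
        d = uniform_initial_distribution(star5, 0.3, 0.0)
        for _ in range(20):
            d = mmc_step(d, star5, default_params)
        assert d.p_infected().max() == 0.0

    def test_strategy_branches_differ(self, er300, default_params):
        d = uniform_initial_distribution(er300, 0.1, 0.1)
        outs = [mmc_step(d, er300, default_params, s).probs for s in STRATEGIES]
        assert not np.allclose(outs[0], outs[1])
        assert not np.allclose(outs[0], outs[2])


class TestSteadyState:
    def test_subcritical_absorption(self, er300, default_params):
        """Below threshold the infection vanishes and resources saturate."""
        bc = analytic_threshold(default_params, er300.epidemic_layer).beta_c
        params = default_params.with_(beta=0.9 * bc)
        d0 = uniform_initial_distribution(er300, 0.1, 0.1)
        sol = iterate_to_steady_state(d0, er300, params)
        assert sol.converged
        assert sol.rho_I < 1e-3
        assert sol.rho_R > 0.999

    def test_no_information_transmission_decays(self, er300, default_params):
        params = default_params.with_(lambda_info=0.0, beta=0.0)
        d0 = uniform_initial_distribution(er300, 0.5, 0.0)
        sol = iterate_to_steady_state(d0, er300, params)
        assert sol.rho_A < 1e-6

    def test_gamma_one_decouples_to_plain_sis(self, er300, default_params):
        """With γ=1 resources cannot help: ρ_I equals a bare SIS on layer C."""
        params = default_params.with_(gamma=1.0, beta=0.2)
        d0 = uniform_initial_distribution(er300, 0.1, 0.1)
        sol = iterate_to_steady_state(d0, er300, params, tol=1e-12)
        ref = oracles.sis_qmf_steady_sparse(
            er300.epidemic_layer.adjacency, beta=0.2, mu=params.mu, rho0=0.1
        )
        assert abs(sol.rho_I - ref.mean()) < 1e-8

    def test_theta_monotonically_suppresses_infection(self, er300, default_params):
        """More willingness to share under panic → weaker epidemic.

        Monotonicity holds for the conditioned acquisition form, where every
        resource a donor gives up is delivered.  Under the equations as
        printed the delivered amount carries an extra p^UNI factor, so raising
        θ drains donors slightly faster than it helps the infected; that known
        artifact is bounded here rather than asserted away.
        """
        params = default_params.with_(beta=0.2)
        d0 = uniform_initial_distribution(er300, 0.1, 0.1)
        cond = [
            iterate_to_steady_state(d0, er300, params.with_(theta=th), conditional_transfer=True).rho_I
            for th in (0.0, 0.5, 1.0)
        ]
        assert cond[0] >= cond[1] >= cond[2]
        assert cond[0] > cond[2]  # strict in the supercritical regime
        printed = [
            iterate_to_steady_state(d0, er300, params.with_(theta=th)).rho_I
            for th in (0.0, 1.0)
        ]
        assert abs(printed[1] - printed[0]) < 0.01

    def test_nonconvergence_reported_not_raised(self, er300, default_params):
        d0 = uniform_initial_distribution(er300, 0.1, 0.1)
        sol = iterate_to_steady_state(d0, er300, default_params, max_iter=3)
        assert not sol.converged
        assert sol.iterations == 3

    def test_export_round_trip(self, triangle3, default_params, tmp_path):
        d0 = uniform_initial_distribution(triangle3, 0.1, 0.1)
        sol = iterate_to_steady_state(d0, triangle3, default_params, max_iter=50)
        frame = sol.distribution.to_frame()
        f = tmp_path / "dist.csv"
        frame.to_csv(f, index=False)
        import pandas as pd

        back = pd.read_csv(f)
        np.testing.assert_allclose(back["probability"], frame["probability"])
        sol.to_json(tmp_path / "sol.json")
        import json

        js = json.loads((tmp_path / "sol.json").read_text())
        assert js["rho_I"] == pytest.approx(sol.rho_I)
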