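"""Learning-model policies, updates, priors and likelihood contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bidlearn.core import bid_grid
from bidlearn.models import (
    MODELS,
    REFERENCE_FFX_ESTIMATES,
    BetaPrior,
    FloorCounter,
    fit_beta_prior,
    init_state,
    log_lik_bid,
    policy_probs,
    update,
)

GRID = bid_grid()


def draw_params(name: str, rng: np.random.Generator) -> dict:
    spec = MODELS[name]
    return {
        n: float(rng.uniform(lo, hi))
        for n, (lo, hi) in zip(spec.param_names, spec.bounds)
    }


def fresh_state(name: str, params):
    prior = BetaPrior(2.0, 3.0, 10.0)
    return init_state(name, params, prior=prior, initial_bids={"SC": 4.96, "NC": 5.13, "BC": 6.55})


class TestInitState:
    def test_dl_initial_preferred_bids(self):
        state = init_state(
            "dl_lepto",
            REFERENCE_FFX_ESTIMATES["dl_lepto"],
            initial_bids={"SC": 4.96, "NC": 5.13, "BC": 6.55},
        )
        assert state.dl["SC"].A == 4.96
        assert state.dl["NC"].A == 5.13
        assert state.dl["BC"].A == 6.55
        assert all(s.last_outcome == "none" for s in state.dl.values())

    def test_symmetric_beta_prior_gives_symmetric_q(self):
        state = init_state("rw_coarse", {"alpha": 0.1, "beta": 1.0}, prior=BetaPrior(3.0, 3.0))
        q = state.Q["NC"]
        assert np.allclose(q, q[::-1], atol=1e-9)
        assert np.argmax(q) == 5

    def test_flat_beta_prior_gives_constant_q(self):
        state = init_state("rw_fine", {"alpha": 0.1, "beta": 1.0}, prior=BetaPrior(1.0, 1.0, 10.0))
        assert np.allclose(state.Q["SC"], 10.0)

    def test_out_of_bounds_parameters_rejected(self):
        with pytest.raises(ValueError):
            init_state("dl_gauss", {"alpha": 1.5, "sigma": 1.0})
        with pytest.raises(ValueError):
            init_state("dl_lepto", REFERENCE_FFX_ESTIMATES["dl_lepto"], initial_bids={"SC": 11.0, "NC": 5.0, "BC": 5.0})


class TestBetaPrior:
    def test_mle_recovers_beta_2_2(self):
        rng = np.random.default_rng(0)
        sample = 10.0 * rng.beta(2.0, 2.0, size=10_000)
        prior = fit_beta_prior(sample)
        assert abs(prior.a - 2.0) <= 0.1
        assert abs(prior.b - 2.0) <= 0.1
        assert abs(prior.a - prior.b) <= 0.1  # symmetric sample
        # fitted mean (rescaled) matches the sample mean
        fitted_mean = 10.0 * prior.a / (prior.a + prior.b)
        assert abs(fitted_mean - sample.mean()) <= 0.1

    def test_degenerate_sample_falls_back_to_moments(self):
        prior = fit_beta_prior([5.0, 5.0, 5.0, 5.0])
        assert prior.a > 0 and prior.b > 0
        assert abs(10.0 * prior.a / (prior.a + prior.b) - 5.0) < 0.05

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            fit_beta_prior([5.0, 6.0])
        with pytest.raises(ValueError):
            fit_beta_prior([5.0, 6.0, 11.0])
        with pytest.raises(ValueError):
            BetaPrior(0.0, 1.0)


class TestPolicies:
    def test_rw_zero_temperature_is_uniform_over_bins(self):
        params = {"alpha": 0.1, "beta": 0.0}
        state = fresh_state("rw_coarse", params)
        p = policy_probs("rw_coarse", params, state, "NC")
        # interior tiles hold 10 grid bids -> each bid gets 1/110
        assert p[50] == pytest.approx(1.0 / 110.0, abs=1e-12)
        assert p[3] == pytest.approx(1.0 / (11.0 * 5.0), abs=1e-12)  # edge tile of 5

    def test_softmax_two_value_closed_form(self):
        params = {"alpha": 0.1, "beta": 1.0}
        state = fresh_state("rw_fine", params)
        q = np.full(101, -1e9)
        q[0], q[1] = 1.0, 0.0
        state.Q["NC"] = q
        p = policy_probs("rw_fine", params, state, "NC")
        assert p[0] == pytest.approx(math.e / (math.e + 1.0), abs=1e-9)
        assert p[1] == pytest.approx(1.0 / (math.e + 1.0), abs=1e-9)

    def test_dl_gauss_matches_bruteforce_grid_renormalization(self):
        params = {"alpha": 0.3, "sigma": 1.0}
        state = fresh_state("dl_gauss", params)
        state.dl["NC"].A = 5.0
        p = policy_probs("dl_gauss", params, state, "NC")
        brute = np.exp(-((GRID - 5.0) ** 2) / 2.0)
        brute /= brute.sum()
        assert np.max(np.abs(p - brute)) < 1e-10
        assert np.argmax(p) == 50

    def test_dl_lepto_mass_split_below_vs_at_or_above(self):
        params = dict(REFERENCE_FFX_ESTIMATES["dl_lepto"])
        state = fresh_state("dl_lepto", params)
        state.dl["NC"].A = 5.0
        state.dl["NC"].last_outcome = "accepted"
        p = policy_probs("dl_lepto", params, state, "NC")
        assert p[GRID < 5.0].sum() == pytest.approx(params["k"], abs=1e-9)
        assert p[GRID >= 5.0].sum() == pytest.approx(1.0 - params["k"], abs=1e-9)
        # before any outcome the split is even
        state.dl["NC"].last_outcome = "none"
        p0 = policy_probs("dl_lepto", params, state, "NC")
        assert p0[GRID < 5.0].sum() == pytest.approx(0.5, abs=1e-9)

    def test_dl_lepto_all_mass_above_when_preferred_bid_at_floor(self):
        params = dict(REFERENCE_FFX_ESTIMATES["dl_lepto"])
        state = fresh_state("dl_lepto", params)
        state.dl["NC"].A = 0.0
        p = policy_probs("dl_lepto", params, state, "NC")
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(p) == 0

    @given(
        model=st.sampled_from(["rw_coarse", "rw_fine", "counterfactual_rl", "dl_gauss", "dl_naive", "dl_lepto", "null"]),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_policy_normalization_property(self, model, seed):
        """Every policy is an exact distribution over the 101 bids."""
        rng = np.random.default_rng(seed)
        params = draw_params(model, rng)
        state = fresh_state(model, params) if model != "null" else None
        if state is not None and model.startswith("dl"):
            m = state.dl["NC"]
            m.A = float(rng.uniform(0, 10))
            m.last_outcome = ["none", "accepted", "rejected"][rng.integers(3)]
        p = policy_probs(model, params, state, "NC")
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-9


class TestUpdates:
    def test_dl_delta_rule_fixed_point_and_rejection(self):
        params = dict(REFERENCE_FFX_ESTIMATES["dl_lepto"])
        state = fresh_state("dl_lepto", params)
        state.dl["NC"].A = 6.0
        after = update("dl_lepto", params, state, "NC", 6.0, True, 4.0)
        assert after.dl["NC"].A == pytest.approx(6.0, abs=1e-12)
        assert after.dl["NC"].last_outcome == "accepted"
        params["alpha"] = 0.5
        after = update("dl_lepto", params, state, "NC", 6.0, False, 0.0)
        assert after.dl["NC"].A == pytest.approx(8.0, abs=1e-12)
        assert after.dl["NC"].last_outcome == "rejected"

    def test_dl_naive_nudges_and_clamp(self):
        params = {"n_up": 0.3, "n_down": 0.1, "sigma_a": 1.0, "sigma_r": 1.0}
        state = fresh_state("dl_naive", params)
        state.dl["BC"].A = 0.2
        after = update("dl_naive", params, state, "BC", 0.2, True, 9.8)
        assert after.dl["BC"].A == pytest.approx(0.0)  # clamped at the floor
        state.dl["BC"].A = 9.95
        after = update("dl_naive", params, state, "BC", 5.0, False, 0.0)
        assert after.dl["BC"].A == pytest.approx(10.0)  # clamped at the ceiling

    def test_counterfactual_update_arithmetic(self):
        params = {"alpha": 0.2, "beta": 1.0}
        state = init_state("counterfactual_rl", params, prior=BetaPrior(1.0, 1.0, 3.0))
        assert np.allclose(state.Q["NC"], 3.0)
        after = update("counterfactual_rl", params, state, "NC", 5.0, True, 5.0)
        q = after.Q["NC"]
        assert np.allclose(q[:50], 3.0)  # bids below 5.0 untouched exactly
        assert q[50] == pytest.approx(3.4)  # toward 10 - 5 = 5
        assert q[100] == pytest.approx(2.4)  # toward 10 - 10 = 0

    def test_counterfactual_region_masks_exact_for_all_bids(self):
        """Updated/untouched index sets partition the grid for every bid."""
        params = {"alpha": 0.5, "beta": 1.0}
        state0 = init_state(
            "counterfactual_rl", params, prior=BetaPrior(1.0, 1.0, 3.0)
        )
        q0 = state0.Q["NC"].copy()
        for idx in range(101):
            bid = float(GRID[idx])
            for accepted in (True, False):
                reward = round(10.0 - bid, 1) if accepted else 0.0
                after = update(
                    "counterfactual_rl", params, state0, "NC", bid, accepted, reward
                )
                changed = after.Q["NC"] != q0
                in_region = np.arange(101) >= idx if accepted else np.arange(101) <= idx
                target = (10.0 - GRID) if accepted else np.zeros(101)
                assert np.array_equal(changed, in_region & (target != q0))

    def test_rw_moves_only_the_chosen_bin(self):
        params = {"alpha": 0.5, "beta": 1.0}
        state = init_state("rw_coarse", params, prior=BetaPrior(1.0, 1.0, 4.0))
        after = update("rw_coarse", params, state, "SC", 3.4, True, 6.6)
        q = after.Q["SC"]
        assert q[3] == pytest.approx(4.0 + 0.5 * (6.6 - 4.0))
        untouched = [j for j in range(11) if j != 3]
        assert np.allclose(q[untouched], 4.0)

    def test_inconsistent_reward_rejected(self):
        params = {"alpha": 0.2, "sigma": 1.0}
        state = fresh_state("dl_gauss", params)
        with pytest.raises(ValueError):
            update("dl_gauss", params, state, "NC", 5.0, True, 3.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_state_bounded_under_arbitrary_updates(self, seed):
        """A stays in [0,10]; Q stays within [min(0,Q0), max(10,Q0)]."""
        rng = np.random.default_rng(seed)
        for model in ("dl_gauss", "dl_naive", "dl_lepto", "counterfactual_rl", "rw_fine"):
            params = draw_params(model, rng)
            state = fresh_state(model, params)
            for _ in range(30):
                m = ["SC", "NC", "BC"][rng.integers(3)]
                bid = float(GRID[rng.integers(101)])
                accepted = bool(rng.integers(2))
                reward = 10.0 - bid if accepted else 0.0
                state = update(model, params, state, m, bid, accepted, reward)
                if model.startswith("dl"):
                    assert 0.0 <= state.dl[m].A <= 10.0
                else:
                    q0 = 10.0  # prior amplitude
                    assert np.all(state.Q[m] >= min(0.0, q0) - 1e-9)
                    assert np.all(state.Q[m] <= max(10.0, q0) + 1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_directional_guarantees(self, seed):
        """Rejection never lowers A; acceptance moves A toward the bid;
        the naive nudger is exactly directional."""
        rng = np.random.default_rng(seed)
        for model in ("dl_gauss", "dl_lepto", "dl_naive"):
            params = draw_params(model, rng)
            state = fresh_state(model, params)
            m = "NC"
            state.dl[m].A = float(rng.uniform(0, 10))
            A = state.dl[m].A
            bid = float(GRID[rng.integers(101)])
            rejected = update(model, params, state, m, bid, False, 0.0)
            assert rejected.dl[m].A >= A - 1e-12
            accepted = update(model, params, state, m, bid, True, 10.0 - bid)
            A_acc = accepted.dl[m].A
            if model == "dl_naive":
                assert A_acc <= A + 1e-12
            else:
                # delta rule: contraction toward the accepted bid
                assert abs(A_acc - bid) <= abs(A - bid) + 1e-12
                assert (A_acc - A) * (bid - A) >= -1e-12


class TestLogLik:
    def test_null_model_uniform_log_probability(self):
        assert log_lik_bid("null", {}, None, "NC", 3.7) == pytest.approx(
            -math.log(101), abs=1e-12
        )

    def test_log_lik_consistent_with_policy(self):
        params = dict(REFERENCE_FFX_ESTIMATES["dl_lepto"])
        state = fresh_state("dl_lepto", params)
        p = policy_probs("dl_lepto", params, state, "BC")
        for bid in (0.0, 3.3, 6.5, 10.0):
            ll = log_lik_bid("dl_lepto", params, state, "BC", bid)
            assert math.exp(ll) == pytest.approx(p[int(round(bid * 10))], abs=1e-12)

    def test_floor_instead_of_minus_infinity(self):
        params = {"alpha": 0.3, "sigma": 0.01}
        state = fresh_state("dl_gauss", params)
        state.dl["NC"].A = 9.0
        counter = FloorCounter()
        ll = log_lik_bid("dl_gauss", params, state, "NC", 0.0, floor_counter=counter)
        assert ll == -745.0
        assert counter.count == 1
        assert np.isfinite(ll)
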