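import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import prlflex as pf
from prlflex.models import apply_update

from ._oracle import loop_loglik

rate = st.floats(0.0, 1.0)
outcome = st.sampled_from([-1.0, 1.0])


class TestClosedFormUpdates:
    def test_cu_substitution(self):
        s = pf.update_cu(pf.init_state("CU"), "A", +1, eta=0.5)
        assert s.v[0] == pytest.approx(0.5, abs=1e-12)
        assert s.v[1] == pytest.approx(-0.5, abs=1e-12)

    def test_cu_eta_zero_is_identity_and_eta_one_is_full(self):
        s0 = pf.init_state("CU")
        assert np.array_equal(pf.update_cu(s0, "B", -1, eta=0.0).v, s0.v)
        s1 = pf.update_cu(s0, "B", -1, eta=1.0)
        assert s1.v[1] == -1.0 and s1.v[0] == 1.0

    def test_rp_punishment_branch_hand_value(self):
        s = pf.LatentState(v=np.array([0.5, 0.0]))
        out = pf.update_rp(s, "A", -1, eta_rew=0.9, eta_pun=0.2)
        assert out.v[0] == pytest.approx(0.5 + 0.2 * (-1 - 0.5), abs=1e-12)  # = 0.2
        assert out.v[1] == 0.0

    def test_rp_reward_leaves_unchosen_untouched(self):
        s = pf.LatentState(v=np.array([0.3, -0.4]))
        out = pf.update_rp(s, "A", +1, eta_rew=0.5, eta_pun=0.1)
        assert out.v[1] == -0.4

    def test_rp_zero_outcome_rejected(self):
        with pytest.raises(ValueError, match="branch"):
            pf.update_rp(pf.init_state("RP"), "A", 0, eta_rew=0.5, eta_pun=0.5)

    @given(eta=rate, o=outcome, choice=st.sampled_from([0, 1]))
    def test_rp_equal_rates_reproduces_rw(self, eta, o, choice):
        s = pf.LatentState(v=np.array([0.2, -0.1]))
        a = pf.update_rp(s, choice, o, eta_rew=eta, eta_pun=eta)
        b = pf.update_rw(s, choice, o, eta=eta)
        assert np.array_equal(a.v, b.v)

    def test_ewa_incremental_average_identity(self):
        # with rho=1, phi=1 the update averages the outcome stream
        # together with the single initial pseudo-observation at 0
        s = pf.init_state("EWA_DL")
        seen = [0.0]
        for o in (1.0, -1.0, 1.0):
            s = pf.update_ewa(s, "A", o, phi=1.0, rho=1.0)
            seen.append(o)
            assert s.v[0] == pytest.approx(np.mean(seen), abs=1e-12)

    def test_ewa_geometric_fixed_point(self):
        phi = 0.6
        s = pf.init_state("EWA_DL")
        for _ in range(200):
            s = pf.update_ewa(s, "A", +1.0, phi=phi, rho=0.0)
        assert s.v[0] == pytest.approx(1.0 / (1.0 - phi), abs=1e-9)

    def test_ewa_memoryless_when_both_decays_zero(self):
        s = pf.init_state("EWA_DL")
        for o in (1.0, -1.0, -1.0):
            s = pf.update_ewa(s, "B", o, phi=0.0, rho=0.0)
            assert s.v[1] == o

    def test_ewa_unchosen_weight_frozen(self):
        s = pf.init_state("EWA_DL")
        s = pf.update_ewa(s, "A", 1.0, phi=0.5, rho=0.5)
        assert s.n[1] == 1.0 and s.v[1] == 0.0

    def test_rw_basic_and_monotone_convergence(self):
        s = pf.init_state("RW")
        s = pf.update_rw(s, "A", +1, eta=0.3)
        assert s.v[0] == pytest.approx(0.3, abs=1e-12)
        prev = s.v[0]
        for _ in range(50):
            s = pf.update_rw(s, "A", +1, eta=0.3)
            assert s.v[0] >= prev
            prev = s.v[0]
        assert prev == pytest.approx(1.0, abs=1e-6)

    def test_out_of_bounds_rate_rejected(self):
        with pytest.raises(ValueError):
            pf.update_cu(pf.init_state("CU"), "A", 1, eta=1.5)


class TestInitState:
    def test_values_start_unbiased(self):
        for m in pf.MODEL_IDS:
            s = pf.init_state(m)
            assert np.array_equal(s.v, [0.0, 0.0])
        assert np.array_equal(pf.init_state("EWA_DL").n, [1.0, 1.0])
        assert pf.init_state("CU").n is None


class TestChoiceProb:
    def test_indifference_when_values_equal(self):
        s = pf.LatentState(v=np.array([0.4, 0.4]))
        for beta in (0.1, 2.0, 4.9):
            assert pf.choice_prob(s, beta, 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_value(self):
        s = pf.LatentState(v=np.array([1.0, 0.0]))
        assert pf.choice_prob(s, 2.0, 0.0) == pytest.approx(1 / (1 + math.exp(-2)), abs=1e-10)

    def test_indifference_point_definition(self):
        s = pf.LatentState(v=np.array([0.25, 0.0]))
        assert pf.choice_prob(s, 3.7, alpha=0.25) == pytest.approx(0.5, abs=1e-12)

    @given(va=st.floats(-2, 2), vb=st.floats(-2, 2),
           beta=st.floats(0.01, 5), alpha=st.floats(-0.5, 0.5))
    def test_probabilities_sum_to_one(self, va, vb, beta, alpha):
        s = pf.LatentState(v=np.array([va, vb]))
        p_a = pf.choice_prob(s, beta, alpha)
        s_flipped = pf.LatentState(v=np.array([vb, va]))
        p_b = pf.choice_prob(s_flipped, beta, -alpha)
        assert p_a + p_b == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_value_difference_and_beta(self):
        diffs = np.linspace(-2, 2, 41)
        probs = [pf.choice_prob(pf.LatentState(v=np.array([d, 0.0])), 2.0, 0.0) for d in diffs]
        assert np.all(np.diff(probs) >= 0)
        betas = np.linspace(0.05, 4.95, 30)
        probs = [pf.choice_prob(pf.LatentState(v=np.array([1.0, 0.0])), b, 0.0) for b in betas]
        assert np.all(np.diff(probs) >= 0)

    def test_extreme_arguments_stable(self):
        s = pf.LatentState(v=np.array([500.0, -500.0]))
        p = pf.choice_prob(s, 5.0, 0.0)
        assert p == 1.0
        assert pf.choice_prob(pf.LatentState(v=s.v[::-1]), 5.0, 0.0) == 0.0


class TestValueBounds:
    @given(
        model=st.sampled_from(["RW", "CU", "RP"]),
        seq=st.lists(st.tuples(st.sampled_from([0, 1]), outcome, rate), min_size=1, max_size=40),
    )
    def test_values_stay_in_unit_interval(self, model, seq):
        s = pf.init_state(model)
        for choice, o, eta in seq:
            params = {"eta": eta, "eta_rew": eta, "eta_pun": eta}
            params = {k: params[k] for k in pf.MODEL_PARAMS[model] if k in params}
            s = apply_update(model, s, choice, o, params)
            assert np.all(np.abs(s.v) <= 1.0 + 1e-12)

    @given(rho=st.floats(0.0, 0.999), seq=st.lists(st.sampled_from([0, 1]), min_size=1, max_size=60))
    def test_ewa_experience_weight_bounded(self, rho, seq):
        s = pf.init_state("EWA_DL")
        for choice in seq:
            s = pf.update_ewa(s, choice, 1.0, phi=0.5, rho=rho)
            assert np.all(s.n <= 1.0 / (1.0 - rho) + 1e-9)


class TestSequenceLoglik:
    def test_beta_zero_limit_gives_chance_loglik(self, schedule):
        agent = pf.simulate_agent("RW", {"eta": 0.5, "beta": 1.0, "alpha": 0.0}, schedule, seed=4)
        ll = pf.sequence_loglik(agent, "RW", {"eta": 0.5, "beta": 1e-12, "alpha": 0.0})
        assert ll == pytest.approx(80 * math.log(0.5), abs=1e-6)

    def test_matches_naive_loop_oracle(self, random_subjects):
        for data, model, params in random_subjects(n_per_model=3, seed=5):
            ll = pf.sequence_loglik(data, model, params)
            assert ll == pytest.approx(loop_loglik(data, model, params), abs=1e-10)

    def test_per_trial_terms_sum_to_total(self, random_subjects):
        data, model, params = random_subjects(n_per_model=1, seed=9)[0]
        total, terms = pf.sequence_loglik(data, model, params, per_trial=True)
        assert terms.shape == (data.n_trials,)
        assert total == pytest.approx(terms.sum(), abs=1e-10)
        assert (terms <= 0).all()

    def test_trial_order_matters(self, schedule):
        agent = pf.simulate_agent("CU", {"eta": 0.4, "beta": 2.0, "alpha": 0.0}, schedule, seed=8)
        params = {"eta": 0.4, "beta": 2.0, "alpha": 0.0}
        ll = pf.sequence_loglik(agent, "CU", params)
        flipped = pf.SubjectData(
            agent.subject_id, agent.diagnosis, agent.age_group,
            agent.choices[::-1].copy(), agent.outcomes[::-1].copy(),
            np.where(np.arange(1, 81) < 41, agent.correct_stim[-1], 1 - agent.correct_stim[-1]),
            reversal_trial=41,
        )
        assert pf.sequence_loglik(flipped, "CU", params) != pytest.approx(ll, abs=1e-9)

    def test_batch_matches_scalar_api(self, cu_cohort):
        cohort, _ = cu_cohort
        choices = np.stack([s.choices for s in cohort])
        outcomes = np.stack([s.outcomes for s in cohort])
        params = {"eta": 0.25, "beta": 1.4, "alpha": -0.1}
        batch = pf.batch_loglik("CU", {k: np.asarray(v) for k, v in params.items()}, choices, outcomes)
        singles = [pf.sequence_loglik(s, "CU", params) for s in cohort]
        np.testing.assert_allclose(batch, singles, atol=1e-10)


class TestParamVector:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            pf.ParamVector("CU", {"eta": 1.2, "beta": 1.0, "alpha": 0.0})
        with pytest.raises(ValueError):
            pf.ParamVector("CU", {"eta": 0.5, "beta": 6.0, "alpha": 0.0})

    def test_foreign_parameters_rejected(self):
        with pytest.raises(ValueError, match="expects parameters"):
            pf.ParamVector("RW", {"eta": 0.5, "phi": 0.5, "beta": 1.0, "alpha": 0.0})

    def test_json_round_trip(self):
        pv = pf.ParamVector("RP", {"eta_rew": 0.4, "eta_pun": 0.2, "beta": 2.0, "alpha": 0.1})
        assert pf.ParamVector.from_dict(pv.to_dict()) == pv
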