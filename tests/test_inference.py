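import numpy as np
import pytest

import prlflex as pf
from prlflex.hba import transform_params, untransform_params


class TestTransforms:
    def test_round_trip(self):
        names = ("eta_rew", "eta_pun", "beta", "alpha")
        theta = np.array([[0.3, 0.7, 2.5, -0.2], [0.9, 0.1, 4.0, 0.4]])
        raw = untransform_params(theta, names)
        np.testing.assert_allclose(transform_params(raw, names), theta, atol=1e-9)

    def test_draws_always_inside_bounds(self):
        # prior-predictive property: any raw value maps into support
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 3, size=(100_000, 4))
        names = ("phi", "rho", "beta", "alpha")
        for transform in ("logistic", "probit"):
            theta = transform_params(raw, names, transform)
            assert (theta[:, 0] >= 0).all() and (theta[:, 0] <= 1).all()
            assert (theta[:, 2] >= 0).all() and (theta[:, 2] <= 5).all()
            assert (theta[:, 3] >= -0.5).all() and (theta[:, 3] <= 0.5).all()
        # the logistic transform keeps open bounds strictly open at
        # any raw magnitude the sampler can plausibly visit
        theta = transform_params(raw, names, "logistic")
        assert (theta[:, 2] > 0).all() and (theta[:, 2] < 5).all()


class TestFitGroup:
    def test_seeded_determinism(self, cu_cohort, quick_mcmc):
        cohort, _ = cu_cohort
        cfg = pf.MCMCConfig(**{**quick_mcmc.__dict__, "draws": 50, "warmup": 100})
        a = pf.fit_group(cohort, "CU", cfg)
        b = pf.fit_group(cohort, "CU", cfg)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.subject, b.subject)

    def test_draw_shapes_and_bounds(self, cu_fit, cu_cohort):
        cohort, _ = cu_cohort
        assert cu_fit.subject.shape == (2, 250, len(cohort), 3)
        assert cu_fit.n_draws == 500
        theta = cu_fit.subject_draws()
        for j, name in enumerate(cu_fit.param_names):
            lo, hi = pf.PARAM_BOUNDS[name]
            assert theta[..., j].min() >= lo and theta[..., j].max() <= hi

    def test_group_mean_near_truth(self, cu_fit, cu_cohort):
        _, truth = cu_cohort
        gm = cu_fit.group_mean_draws()
        eta_mean = gm[:, 0].mean()
        assert abs(eta_mean - truth.eta.mean()) < 0.1

    def test_posterior_shrinkage_toward_group(self, cu_fit, cu_cohort):
        # hierarchical posterior SDs should be tighter on average than
        # independent per-subject uncertainty; proxy: subject posterior
        # means are less dispersed than their MLEs
        cohort, _ = cu_cohort
        post_eta = cu_fit.subject_draws()[:, :, 0].mean(axis=0)
        mle_eta = [
            pf.fit_subject_mle(s, "CU", n_restarts=3, seed=1)[0]["eta"] for s in cohort
        ]
        assert np.std(post_eta) <= np.std(mle_eta)

    def test_too_few_subjects_rejected(self, cu_cohort, quick_mcmc):
        cohort, _ = cu_cohort
        with pytest.raises(ValueError, match="at least 2"):
            pf.fit_group(cohort[:1], "CU", quick_mcmc)

    def test_mixed_groups_rejected(self, schedule, quick_mcmc):
        a = pf.simulate_agent("CU", {"eta": 0.2, "beta": 1.0, "alpha": 0.0}, schedule,
                              seed=1, subject_id="a", diagnosis="TD", age_group="children")
        b = pf.simulate_agent("CU", {"eta": 0.2, "beta": 1.0, "alpha": 0.0}, schedule,
                              seed=2, subject_id="b", diagnosis="ASD", age_group="adults")
        with pytest.raises(ValueError, match="multiple groups"):
            pf.fit_group([a, b], "CU", quick_mcmc)

    def test_tiny_dataset_converges_or_raises(self, quick_mcmc):
        # 2 subjects x 10 trials: must either produce diagnostics-clean
        # draws or raise the diagnostic error; never silently bad draws
        sched = pf.build_schedule(10, 6, 0.8, seed=0)
        subjects = [
            pf.simulate_agent("RW", {"eta": 0.3, "beta": 1.0, "alpha": 0.0}, sched, seed=s)
            for s in (1, 2)
        ]
        cfg = pf.MCMCConfig(chains=2, draws=200, warmup=300, thin=1, seed=3,
                            check_convergence=True)
        try:
            draws = pf.fit_group(subjects, "RW", cfg)
        except pf.ConvergenceError as exc:
            assert exc.offending  # names the offending parameters
        else:
            assert (draws.diagnostics.rhat <= cfg.rhat_max).all()

    def test_convergence_error_carries_offenders(self, cu_cohort):
        cohort, _ = cu_cohort
        cfg = pf.MCMCConfig(chains=2, draws=40, warmup=10, thin=1, seed=0,
                            rhat_max=1.0000001, check_convergence=True)
        with pytest.raises(pf.ConvergenceError) as err:
            pf.fit_group(cohort, "CU", cfg)
        assert len(err.value.offending) > 0


class TestFitSubjectMLE:
    def test_recovers_learning_rate_on_long_sequence(self):
        sched = pf.build_schedule(500, 251, 0.8, seed=4)
        agent = pf.simulate_agent("CU", {"eta": 0.2, "beta": 3.0, "alpha": 0.0}, sched, seed=9)
        pv, _ = pf.fit_subject_mle(agent, "CU", n_restarts=6, seed=2)
        assert abs(pv["eta"] - 0.2) < 0.05

    def test_random_responder_loglik_near_chance(self, schedule):
        agent = pf.simulate_agent("CU", {"eta": 0.3, "beta": 1e-9, "alpha": 0.0}, schedule, seed=3)
        _, ll = pf.fit_subject_mle(agent, "CU", n_restarts=4, seed=0)
        assert ll >= 80 * np.log(0.5)
        assert ll < 80 * np.log(0.5) + 8  # barely better than chance

    def test_more_restarts_never_worse(self, schedule):
        agent = pf.simulate_agent("RP", {"eta_rew": 0.5, "eta_pun": 0.2, "beta": 2.0, "alpha": 0.0},
                                  schedule, seed=6)
        _, ll1 = pf.fit_subject_mle(agent, "RP", n_restarts=1, seed=5)
        _, ll10 = pf.fit_subject_mle(agent, "RP", n_restarts=10, seed=5)
        assert ll10 >= ll1 - 1e-9


class TestPointwiseLoglik:
    def test_shape_and_sign(self, cu_fit, cu_cohort):
        cohort, _ = cu_cohort
        ll = pf.pointwise_loglik(cu_fit, cohort)
        assert ll.shape == (cu_fit.n_draws, len(cohort))
        assert (ll <= 0).all()

    def test_matches_sequence_loglik_at_each_draw(self, cu_fit, cu_cohort):
        cohort, _ = cu_cohort
        ll = pf.pointwise_loglik(cu_fit, cohort)
        theta = cu_fit.subject_draws()
        rng = np.random.default_rng(0)
        for _ in range(5):
            s = rng.integers(cu_fit.n_draws)
            i = rng.integers(len(cohort))
            params = {n: theta[s, i, j] for j, n in enumerate(cu_fit.param_names)}
            assert ll[s, i] == pytest.approx(
                pf.sequence_loglik(cohort[i], "CU", params), abs=1e-10
            )

    def test_subject_mismatch_rejected(self, cu_fit, cu_cohort):
        cohort, _ = cu_cohort
        with pytest.raises(ValueError, match="match"):
            pf.pointwise_loglik(cu_fit, cohort[:-1])
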