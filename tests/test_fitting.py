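"""Maximum-likelihood fits, Laplace evidence, model comparison, group statistics."""

import dataclasses

import numpy as np
import pytest
from mbdecide.behavior import choice_prob_sampling
from mbdecide.cohort import SubjectSpec, generate_subject
from mbdecide.fitting import (
    bic,
    bic_evidence,
    compare_models,
    exclude_subjects,
    fit_choice_model,
    fit_rt_model,
    fixed_effects_refit,
    group_param_test,
    laplace_evidence,
)
from mbdecide.learning import LearnerParams


class TestLaplaceEvidence:
    def test_exact_for_gaussian_likelihood(self):
        """With a Gaussian likelihood in one mean parameter, Laplace is analytic.

        ll(theta) = sum log N(y_i; theta, s);  int exp(ll) dtheta has the
        closed form ll(th_hat) + 0.5 log(2 pi s^2 / n).
        """
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 1.5, size=40)
        s = 1.5
        theta_hat = y.mean()
        ll_hat = float(np.sum(-0.5 * np.log(2 * np.pi * s**2) - 0.5 * (y - theta_hat) ** 2 / s**2))
        hessian = np.array([[y.size / s**2]])  # of the negative loglik
        v = 10.0
        expected = ll_hat + 0.5 * np.log(2 * np.pi * s**2 / y.size) - np.log(v)
        assert np.isclose(laplace_evidence(ll_hat, hessian, np.log(v)), expected, atol=1e-8)

    def test_occam_penalty_for_extra_parameter(self):
        """Equal fit, one extra (uninformative) parameter: simpler model wins."""
        ll = -100.0
        h1 = np.array([[4.0]])
        h2 = np.array([[4.0, 0.0], [0.0, 4.0]])
        e1 = laplace_evidence(ll, h1, np.log(10.0))
        e2 = laplace_evidence(ll, h2, np.log(10.0) + np.log(10.0))
        assert e1 > e2

    def test_not_positive_definite_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            laplace_evidence(-10.0, np.array([[-1.0]]), 0.0)

    def test_bic_evidence_convention(self):
        assert bic_evidence(-50.0, 3, 100) == -0.5 * bic(-50.0, 3, 100)

    def test_evidence_invariant_to_data_rescaling_up_to_jacobian(self):
        """Gaussian case: scaling y by c shifts the evidence by -n log c exactly."""
        rng = np.random.default_rng(1)
        y = rng.normal(0.0, 1.0, size=30)
        c = 7.0

        def ev(data, sigma, v):
            th = data.mean()
            ll = float(np.sum(-0.5 * np.log(2 * np.pi * sigma**2)
                              - 0.5 * (data - th) ** 2 / sigma**2))
            h = np.array([[data.size / sigma**2]])
            return laplace_evidence(ll, h, np.log(v))

        e_raw = ev(y, 1.0, 10.0)
        e_scaled = ev(c * y, c * 1.0, c * 10.0)
        assert np.isclose(e_scaled, e_raw - y.size * np.log(c), atol=1e-8)


class TestRTFits:
    def test_one_process_recovery(self):
        """Single-rate data at low noise: the rate comes back within 0.05."""
        errs = []
        for seed in range(3):
            spec = SubjectSpec(learner=LearnerParams.single(0.2), seed=seed)
            subj = generate_subject(spec)
            fit = fit_rt_model(subj.behavior, "one_process", n_restarts=4,
                               rng=np.random.default_rng(seed))
            errs.append(abs(fit.params["alpha"] - 0.2))
        assert np.median(errs) < 0.05

    def test_flat_slope_favors_constant_model(self):
        """No probability dependence in RTs: the nuisance-only model should win."""
        wins = 0
        for seed in range(5):
            spec = SubjectSpec(
                learner=LearnerParams.single(0.2),
                rt=dataclasses.replace(SubjectSpec().rt, slope_prob=0.0),
                seed=100 + seed,
            )
            subj = generate_subject(spec)
            rng = np.random.default_rng(seed)
            f0 = fit_rt_model(subj.behavior, "constant", rng=rng)
            f1 = fit_rt_model(subj.behavior, "one_process", n_restarts=3, rng=rng)
            cmp_ = compare_models([f0], [f1])
            wins += cmp_.summed >= 0
        assert wins >= 4

    def test_two_process_beats_one_process_on_dual_rate_data(self):
        spec = SubjectSpec(
            learner=LearnerParams(alpha_fast=0.6, alpha_slow=0.05, w_slow=0.6), seed=7
        )
        subj = generate_subject(spec)
        rng = np.random.default_rng(7)
        f2 = fit_rt_model(subj.behavior, "two_process", n_restarts=5, rng=rng)
        f1 = fit_rt_model(subj.behavior, "one_process", n_restarts=5, rng=rng)
        assert compare_models([f2], [f1]).summed > 0

    def test_unknown_model_rejected(self, subject):
        with pytest.raises(ValueError):
            fit_rt_model(subject.behavior, "three_process")


class TestChoiceFits:
    def test_vanishing_draws_make_choices_chance(self):
        """As the number of draws shrinks, the sampling rule approaches 0.5."""
        p = choice_prob_sampling(0.9, 0.1, 1e-9)
        assert abs(p - 0.5) < 1e-4

    def test_truth_is_near_stationary_point(self, subject):
        """The generating rate should score close to the fitted optimum."""
        fit = fit_choice_model(subject.behavior, "one_rate", n_restarts=5,
                               rng=np.random.default_rng(0))
        from mbdecide.fitting import _choice_probs_for, _CLIP
        from mbdecide.learning import inv_sigmoid
        stream = subject.behavior.stream
        keep = ~subject.behavior.choices.missed.to_numpy()
        chose_a = subject.behavior.choices.chose_a.to_numpy()

        def nll(alpha, n):
            th = np.array([inv_sigmoid(alpha), np.log(n)])
            p = _choice_probs_for(stream, chose_a, th, "one_rate", "sampling")[keep]
            return -float(np.log(np.clip(p, _CLIP, 1 - _CLIP)).sum())

        truth_nll = nll(subject.spec.learner.alpha_slow, subject.spec.choice.n_draws)
        assert truth_nll - (-fit.loglik) < 5.0  # within a few log units of optimum

    def test_too_few_choices_rejected(self, subject):
        data = subject.behavior
        data.choices.loc[data.choices.index[5:], "missed"] = True
        try:
            with pytest.raises(ValueError):
                fit_choice_model(data, "one_rate")
        finally:
            data.choices["missed"] = False


class TestExclusion:
    def _fits(self, slope, seed):
        spec = SubjectSpec(
            learner=LearnerParams.single(0.15),
            rt=dataclasses.replace(SubjectSpec().rt, slope_prob=slope),
            seed=seed,
        )
        subj = generate_subject(spec)
        rng = np.random.default_rng(seed)
        f0 = fit_rt_model(subj.behavior, "constant", rng=rng)
        f1 = fit_rt_model(subj.behavior, "one_process", n_restarts=3, rng=rng)
        return f0, f1

    def test_pure_noise_subject_excluded_strong_learner_kept(self):
        c_noise, m_noise = self._fits(slope=0.0, seed=11)
        c_learn, m_learn = self._fits(slope=-44.0, seed=12)
        kept, excluded = exclude_subjects([c_noise, c_learn], [[m_noise, m_learn]])
        assert excluded == [0]
        assert kept == [1]

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            exclude_subjects([], [])


class TestFixedEffects:
    def test_single_subject_matches_own_fit(self, subject):
        rng = np.random.default_rng(0)
        fe = fixed_effects_refit([subject.behavior], kind="choice", model="one_rate",
                                 n_restarts=5, rng=rng)
        own = fit_choice_model(subject.behavior, "one_rate", n_restarts=5,
                               rng=np.random.default_rng(0))
        assert abs(fe["alpha"] - own.params["alpha"]) < 0.02

    def test_identical_cohort_recovers_shared_rate(self):
        subs = [generate_subject(SubjectSpec(seed=s)) for s in (1, 2, 3)]
        fe = fixed_effects_refit([s.behavior for s in subs], kind="choice",
                                 model="one_rate", n_restarts=5,
                                 rng=np.random.default_rng(0))
        assert abs(fe["alpha"] - 0.10) < 0.05
        assert abs(fe["n_draws"] - 4.675) < 1.5

    def test_rt_fixed_effects_runs(self):
        subs = [generate_subject(SubjectSpec(seed=s)) for s in (4, 5)]
        fe = fixed_effects_refit([s.behavior for s in subs], kind="rt",
                                 model="one_process", n_restarts=3,
                                 rng=np.random.default_rng(0))
        assert 0.0 < fe["alpha"] < 1.0


class TestGroupTests:
    def test_estimates_at_reference_give_null(self):
        t, p = group_param_test([0.3, 0.3, 0.3, 0.3], reference=0.3)
        assert t == 0.0 and p == 1.0

    def test_paired_self_comparison_is_zero(self):
        x = [0.1, 0.5, 0.9]
        t, p = group_param_test(x, paired_with=x)
        assert t == 0.0

    def test_matches_hand_computed_t(self):
        """Five-point example: t = mean / (sd / sqrt(n)) against 0."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, p = group_param_test(x, reference=0.0)
        expected = x.mean() / (x.std(ddof=1) / np.sqrt(5))
        assert np.isclose(t, expected, atol=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_param_test([0.1, 0.2])
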