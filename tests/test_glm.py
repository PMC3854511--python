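"""Design construction, HRF convolution, OLS fitting, learning-rate read-out."""

import numpy as np
import pytest

from mbdecide import glm
from mbdecide.glm import (
    DesignMatrix,
    build_glm1,
    build_glm2,
    compare_learning_rates,
    cosine_drift,
    estimate_learning_rate,
    fit_glm,
    hrf_convolve,
    model_event_table,
    realized_design,
)
from mbdecide.learning import inv_sigmoid, run_process, sigmoid

TR = 2.37
NVOL = 400
ALPHA0 = 0.25


@pytest.fixture(scope="module")
def events(subject):
    return model_event_table(subject.behavior, ALPHA0)[0]


@pytest.fixture(scope="module")
def design1(events):
    return build_glm1(events, NVOL, TR)


class TestHRF:
    def test_single_event_peaks_near_five_seconds(self):
        col = hrf_convolve(np.array([30.0]), None, 100, 1.0)
        peak = np.argmax(col)
        assert 34 <= peak <= 37  # 4-7 s after onset

    def test_zero_modulator_gives_zero_column(self):
        col = hrf_convolve(np.array([10.0, 50.0]), np.zeros(2), NVOL, TR)
        assert np.allclose(col, 0.0)

    def test_linearity_over_events(self):
        both = hrf_convolve(np.array([20.0, 90.0]), None, 200, 1.0)
        sep = hrf_convolve(np.array([20.0]), None, 200, 1.0) + hrf_convolve(
            np.array([90.0]), None, 200, 1.0
        )
        assert np.allclose(both, sep, atol=1e-10)

    def test_negative_onsets_rejected(self):
        with pytest.raises(ValueError):
            hrf_convolve(np.array([-1.0]), None, 100, 1.0)

    def test_cosine_drift_spans_constant(self):
        B = cosine_drift(NVOL, TR, 128.0)
        assert B.shape[0] == NVOL
        assert np.allclose(B[:, 0], 1.0)
        # slow drifts only: highest-order column completes ~2*n*tr/128 half-cycles
        assert B.shape[1] == 1 + int(np.floor(2 * NVOL * TR / 128.0))


class TestDesigns:
    def test_glm1_column_structure(self, design1):
        fams = design1.families
        assert fams["seq"] == ["seq_onset", "seq_rt", "seq_p_obs", "seq_entropy",
                               "seq_d_entropy"]
        assert fams["choice"] == ["choice_onset", "choice_rt", "choice_value",
                                  "choice_difficulty", "choice_d_difficulty"]
        assert fams["outcome"] == ["outcome_onset", "outcome_rt", "outcome_rpe",
                                   "outcome_d_rpe"]
        assert design1.policy == "serial"

    def test_serial_orthogonality_after_filtering(self, design1):
        X = realized_design(design1)
        for fam in design1.families.values():
            for k in range(1, len(fam)):
                later = X[fam[k]].to_numpy()
                for earlier in fam[:k]:
                    assert abs(later @ X[earlier].to_numpy()) < 1e-8

    def test_glm2_has_no_orthogonalization(self, events):
        d2 = build_glm2(events, NVOL, TR)
        assert d2.policy == "none"
        raw = d2.columns["seq_p_next_0"].to_numpy()
        real = realized_design(d2)["seq_p_next_0"].to_numpy()
        drift = cosine_drift(NVOL, TR)
        expect = raw - drift @ np.linalg.pinv(drift) @ raw
        assert np.allclose(real, expect, atol=1e-10)  # filtered but untouched otherwise

    def test_per_image_probabilities_sum_to_one(self, events):
        total = sum(events.seq[f"p_next_{c}"].to_numpy() for c in range(4))
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_near_constant_entropy_column_vanishes(self, subject):
        """A learner that barely updates has ~uniform predictions everywhere."""
        ev = model_event_table(subject.behavior, 1e-5)[0]
        sv = ev.seq[(ev.seq.correct & ~ev.seq.missed & ~ev.seq.is_outcome)]
        ent = sv.entropy.to_numpy()
        col = hrf_convolve(sv.onset.to_numpy(), ent - ent.mean(), NVOL, TR)
        assert np.max(np.abs(col)) < 1e-4

    def test_modulators_recoverable_from_sparse_design(self):
        """With widely spaced onsets the raw modulators deconvolve from the column."""
        rng = np.random.default_rng(0)
        onsets = np.arange(5) * 40.0 + 10.0
        mods = rng.uniform(-1, 1, size=5)
        col = hrf_convolve(onsets, mods, 200, 1.0)
        basis = np.column_stack(
            [hrf_convolve(np.array([o]), None, 200, 1.0) for o in onsets]
        )
        rec, *_ = np.linalg.lstsq(basis, col, rcond=None)
        assert np.allclose(rec, mods, atol=1e-8)

    def test_betas_invariant_to_event_order(self):
        """Columns depend only on the event set, not its ordering."""
        rng = np.random.default_rng(1)
        onsets = np.sort(rng.uniform(0, 800, size=50))
        mods = rng.normal(size=50)
        perm = rng.permutation(50)
        a = hrf_convolve(onsets, mods, NVOL, TR)
        b = hrf_convolve(onsets[perm], mods[perm], NVOL, TR)
        assert np.allclose(a, b, atol=1e-10)


class TestFitGLM:
    def test_noiseless_betas_recover_amplitudes(self, design1):
        X = realized_design(design1)
        amps = {"seq_entropy": 2.0, "choice_difficulty": -1.5, "outcome_rpe": 0.7}
        bold = sum(a * X[c].to_numpy() for c, a in amps.items())
        res = fit_glm(bold, design1)
        for c, a in amps.items():
            assert np.isclose(res.betas[c], a, atol=1e-8)
        others = [c for c in X.columns if c not in amps]
        assert np.max(np.abs(res.betas[others].to_numpy())) < 1e-6

    def test_duplicated_column_raises_named_error(self, design1):
        cols = design1.columns.copy()
        cols["seq_entropy_copy"] = cols["seq_entropy"]
        fams = dict(design1.families)
        fams["dup"] = ["seq_entropy_copy"]
        bad = DesignMatrix(columns=cols, families=fams, policy="none", tr=TR)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_glm(np.zeros(NVOL), bad)

    def test_length_mismatch_rejected(self, design1):
        with pytest.raises(ValueError):
            fit_glm(np.zeros(NVOL - 1), design1)


class TestLearningRateEstimate:
    def test_zero_derivative_beta_returns_reference_rate(self):
        est = estimate_learning_rate([1.0, 1.2, 0.8], [0.0, 0.0, 0.0], ALPHA0)
        assert est.alpha_hat == ALPHA0

    def test_sign_of_shift_follows_derivative_beta(self):
        up = estimate_learning_rate([1.0, 1.0], [0.5, 0.5], ALPHA0)
        down = estimate_learning_rate([1.0, 1.0], [-0.5, -0.5], ALPHA0)
        assert up.alpha_hat > ALPHA0 > down.alpha_hat

    def test_vanishing_normalizer_rejected(self):
        with pytest.raises(ValueError):
            estimate_learning_rate([1.0, -1.0], [0.1, 0.1], ALPHA0)

    def test_taylor_linearity_improves_at_small_offsets(self, subject):
        """First-order prediction error shrinks as the offset shrinks."""
        stream = subject.behavior.stream
        x0 = float(inv_sigmoid(ALPHA0))
        base = run_process(stream, ALPHA0)
        errs = {}
        for delta in (0.01, 0.1):
            moved = run_process(stream, float(sigmoid(x0 + delta)))
            taylor = base.entropy + delta * base.d_entropy
            errs[delta] = np.max(np.abs(taylor - moved.entropy))
        assert errs[0.01] < errs[0.1]
        assert errs[0.01] < 1e-3


class TestCompareLearningRates:
    def test_region_against_itself_is_null(self):
        est = estimate_learning_rate([1.0, 1.1, 0.9, 1.0], [0.2, 0.1, 0.3, 0.15], ALPHA0)
        table = compare_learning_rates(est, {}, other_regions={"self": est})
        row = table[table.comparison == "paired_self"].iloc[0]
        assert row.t == 0.0 and row.p == 1.0

    def test_one_sample_matches_hand_computed_t(self):
        bm = [1.0, 1.0, 1.0, 1.0, 1.0]
        bd = [0.1, 0.2, 0.3, 0.4, 0.5]
        est = estimate_learning_rate(bm, bd, ALPHA0)
        table = compare_learning_rates(est, {"ref": ALPHA0})
        x = est.x_hat - inv_sigmoid(ALPHA0)
        expected = x.mean() / (x.std(ddof=1) / np.sqrt(5))
        assert np.isclose(table.iloc[0].t, expected, atol=1e-10)

    def test_requires_three_subjects(self):
        est = estimate_learning_rate([1.0, 1.0], [0.1, 0.2], ALPHA0)
        with pytest.raises(ValueError):
            compare_learning_rates(est, {"ref": ALPHA0})
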