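"""Lag design, ridge estimation, reconstruction and cross-validation."""

import numpy as np
import pytest

import aadkit as ak
from aadkit.decoding import (
    DecoderModel,
    Trial,
    build_design_matrix,
    cross_validate,
    lambda_grid,
    make_lag_design,
    partition_segments,
    reconstruct_and_correlate,
    train_decoder,
    train_ridge,
)
from aadkit.envelope import Envelope


class TestLagDesign:
    def test_default_design_has_34_windows(self):
        d = make_lag_design(45.0, 30.0, 500.0, 64.0)
        assert d.n_windows == 34
        assert d.hop == 15.0
        assert d.starts_ms[0] == 0.0 and d.starts_ms[-1] == 495.0

    def test_small_bound_enumeration(self):
        d = make_lag_design(45.0, 30.0, 45.0, 64.0)
        assert list(d.starts_ms) == [0.0, 15.0, 30.0]

    def test_every_lag_to_half_second_is_covered(self):
        d = make_lag_design()
        covered = set(np.concatenate(d.lag_sets).tolist())
        for lag in range(int(np.ceil(0.5 * 64)) + 1):
            assert lag in covered

    def test_window_lags_lie_inside_window(self):
        d = make_lag_design()
        for start, lags in zip(d.starts_ms, d.lag_sets):
            ms = lags * 1000.0 / 64.0
            assert np.all((ms >= start) & (ms < start + 45.0))
            assert 2 <= lags.size <= 3

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            make_lag_design(45.0, 45.0, 500.0, 64.0)
        with pytest.raises(ValueError):
            make_lag_design(45.0, 60.0, 500.0, 64.0)


class TestLambdaGrid:
    def test_default_grid(self):
        g = lambda_grid()
        assert g.size == 7
        assert g[0] == 1e-6 and g[-1] == 1e6
        assert np.isclose(g[0] * g[-1], 1.0)

    def test_custom_grid(self):
        assert np.allclose(lambda_grid(-2, 2, 2), [0.01, 1.0, 100.0])

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            lambda_grid(2, -2, 2)


class TestDesignMatrix:
    def test_zero_lag_is_transposed_eeg(self, rng):
        eeg = rng.standard_normal((3, 20))
        X = build_design_matrix(eeg, np.array([0]))
        assert np.array_equal(X, eeg.T)

    def test_hand_built_two_channel_two_lag(self):
        eeg = np.array([[1.0, 2, 3, 4, 5], [10.0, 20, 30, 40, 50]])
        X = build_design_matrix(eeg, np.array([0, 1]))
        # channel-major, lag-minor; EEG *after* the target sample, end zero-padded
        expect = np.array(
            [
                [1, 2, 10, 20],
                [2, 3, 20, 30],
                [3, 4, 30, 40],
                [4, 5, 40, 50],
                [5, 0, 50, 0],
            ],
            dtype=float,
        )
        assert np.array_equal(X, expect)

    def test_shifting_eeg_shifts_lag_columns(self, rng):
        eeg = rng.standard_normal((2, 50))
        X = build_design_matrix(eeg, np.array([0, 1, 2]))
        Xs = build_design_matrix(eeg[:, 1:], np.array([0, 1, 2]))
        # lag-l column of the shifted EEG equals lag-(l+1) column of the original
        assert np.allclose(Xs[:40, 0], X[:40, 1])
        assert np.allclose(Xs[:40, 1], X[:40, 2])

    def test_noncontiguous_lags_match_loop_construction(self, rng):
        eeg = rng.standard_normal((2, 30))
        lags = np.array([1, 4, 9])
        X = build_design_matrix(eeg, lags)
        for c in range(2):
            for j, lag in enumerate(lags):
                col = np.zeros(30)
                col[: 30 - lag] = eeg[c, lag:]
                assert np.array_equal(X[:, c * 3 + j], col)


class TestTrainRidge:
    def test_interpolates_noiseless_system(self, rng):
        X = rng.standard_normal((50, 8))
        w0 = rng.standard_normal(8)
        y = X @ w0 + 1.5
        w = train_ridge(X, y, 0.0)
        assert np.allclose(w[:-1], w0, atol=1e-6)
        assert np.isclose(w[-1], 1.5, atol=1e-6)

    def test_extreme_lambda_shrinks_weights(self, rng):
        X = rng.standard_normal((50, 8))
        y = rng.standard_normal(50)
        w_ols = train_ridge(X, y, 0.0)
        w_big = train_ridge(X, y, 1e12)
        assert np.linalg.norm(w_big[:-1]) < 1e-3 * np.linalg.norm(w_ols[:-1])

    def test_matches_conjugate_gradient_oracle(self, rng):
        from scipy.sparse.linalg import cg

        X = rng.standard_normal((50, 8))
        y = rng.standard_normal(50)
        lam = 0.5
        w = train_ridge(X, y, lam)
        # iterative oracle on the same penalized normal equations
        Xi = np.hstack([X, np.ones((50, 1))])
        G = Xi.T @ Xi
        m = np.diagonal(G)[:-1].mean()
        A = G + lam * m * np.diag([1.0] * 8 + [0.0])
        w_cg, info = cg(A, Xi.T @ y, rtol=1e-12, maxiter=10000)
        assert info == 0
        assert np.allclose(w, w_cg, atol=1e-6)

    def test_rank_deficiency_reported_at_zero_lambda(self, rng):
        X = rng.standard_normal((20, 5))
        X = np.hstack([X, X[:, :1]])  # duplicate column
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            train_ridge(X, rng.standard_normal(20), 0.0)

    def test_row_count_mismatch(self, rng):
        with pytest.raises(ValueError):
            train_ridge(rng.standard_normal((10, 2)), rng.standard_normal(9), 1.0)


def _toy_trial(rng, n=400, n_ch=4, subject=0, with_ign=True):
    eeg = rng.standard_normal((n_ch, n))
    env = Envelope(np.abs(rng.standard_normal(n)), 64.0)
    ign = Envelope(np.abs(rng.standard_normal(n)), 64.0) if with_ign else None
    return Trial(eeg, env, ign, subject=subject)


class TestReconstructAndCorrelate:
    def test_self_trained_full_rank_reconstruction_is_perfect(self, rng):
        design = make_lag_design(45.0, 30.0, 45.0, 64.0)
        trial = _toy_trial(rng, n=300, with_ign=False)
        # target generated exactly from the window-0 features
        X = build_design_matrix(trial.eeg, design.lag_sets[0])
        w0 = rng.standard_normal(X.shape[1])
        y = X @ w0
        y = y - y.min() + 0.1  # affine shift keeps it a valid nonnegative envelope
        trial = Trial(trial.eeg, Envelope(y, 64.0), None, 0)
        model = train_decoder([trial], design, 0.0)
        # can't expect r=1 in every window, but the generating window must hit it
        curve = reconstruct_and_correlate(model, trial)
        assert curve.r_att[0] > 0.9999

    def test_pearson_is_affine_invariant(self, rng):
        design = make_lag_design(45.0, 30.0, 45.0, 64.0)
        trial = _toy_trial(rng)
        model = train_decoder([trial], design, 1.0)
        scaled = DecoderModel(
            design, [w * 3.0 for w in model.weights], model.lam
        )
        a = reconstruct_and_correlate(model, trial)
        b = reconstruct_and_correlate(scaled, trial)
        assert np.allclose(a.r_att, b.r_att, atol=1e-12)

    def test_r_matches_brute_force_covariance(self, rng):
        from aadkit.decoding import _pearson

        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert np.isclose(_pearson(a, b), num / den, atol=1e-12)


class FakeRec:
    def __init__(self, rng, minutes, subject, condition="dual"):
        n = int(minutes * 60 * 64)
        self.eeg = rng.standard_normal((2, n))
        self.env_att = Envelope(np.abs(rng.standard_normal(n)), 64.0)
        self.env_ign = Envelope(np.abs(rng.standard_normal(n)), 64.0)
        self.subject = subject
        self.block = "Lab1"
        self.condition = condition


class TestPartitionSegments:
    def test_20_subjects_9_minutes_gives_180_folds(self, rng):
        recs = [FakeRec(rng, 9.0, s) for s in range(20)]
        assert len(partition_segments(recs)) == 180

    def test_19_subjects_gives_171_folds(self, rng):
        recs = [FakeRec(rng, 9.0, s) for s in range(19)]
        assert len(partition_segments(recs)) == 171

    def test_trailing_remainder_dropped(self, rng):
        assert len(partition_segments([FakeRec(rng, 8.5, 0)])) == 8

    def test_trial_metadata_and_offsets(self, rng):
        trials = partition_segments([FakeRec(rng, 3.0, 4)])
        assert [t.start_time for t in trials] == [0.0, 60.0, 120.0]
        assert all(t.subject == 4 and t.n_samples == 3840 for t in trials)


class TestCrossValidate:
    def test_single_value_grid_is_selected(self, rng):
        design = make_lag_design(45.0, 30.0, 60.0, 64.0)
        trials = [_toy_trial(rng, subject=s) for s in range(3)]
        res = cross_validate(trials, design, grid=np.array([0.1]))
        assert res.lam == 0.1
        assert len(res.curves) == 3

    def test_curve_count_and_lambda_table_argmax(self, mini_cv, mini_trials):
        assert len(mini_cv.curves) == len(mini_trials)
        tab = mini_cv.lambda_table
        best = tab.loc[tab["mean_r"].idxmax(), "lam"]
        assert best == mini_cv.lam
        for c in mini_cv.curves:
            assert c.r_att.shape == (34,)
            assert np.all((c.r_att >= -1) & (c.r_att <= 1))
            assert c.r_ign is not None

    def test_subject_dependent_selects_per_subject_lambda(self, rng):
        design = make_lag_design(45.0, 30.0, 60.0, 64.0)
        trials = [_toy_trial(rng, subject=s) for s in range(2) for _ in range(3)]
        res = cross_validate(
            trials, design, grid=np.array([1.0, 10.0]), mode="subject_dependent"
        )
        assert set(res.lam) == {0, 1}
        assert len(res.curves) == 6

    def test_too_few_trials_rejected(self, rng):
        design = make_lag_design(45.0, 30.0, 60.0, 64.0)
        with pytest.raises(ValueError):
            cross_validate([_toy_trial(rng)], design)

    def test_noiseless_forward_model_recovers_kernel_window(self):
        """No ignored stream, no noise: held-out reconstruction in the
        window containing the kernel latencies must be near-perfect.
        Channels carry kernels with latencies spread around 150 ms, as
        distinct cortical sources would."""
        from aadkit.synthetic import make_stimulus, _convolve_response, _sample_kernel
        from aadkit.envelope import extract_envelope

        audio, _ = make_stimulus(240.0, seed=21)
        env = extract_envelope(audio)
        kern = np.array(
            [_sample_kernel(0.15 + d, 0.04, 1.0) for d in
             (-0.03, -0.02, -0.01, 0.0, 0.01, 0.02, 0.03, 0.0)]
        )
        resp = _convolve_response(env, kern, 64.0)
        resp = resp / resp.std(axis=1, keepdims=True)

        class R:
            eeg = resp
            env_att = env
            env_ign = None
            subject = 0
            block = ""
            condition = ""

        trials = partition_segments([R()])
        design = ak.make_lag_design()
        res = cross_validate(trials, design)
        mean_curve = np.mean([c.r_att for c in res.curves], axis=0)
        covering = [
            w
            for w, s in enumerate(design.starts_ms)
            if s <= 150.0 < s + design.window_width
        ]
        assert max(mean_curve[w] for w in covering) > 0.9
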