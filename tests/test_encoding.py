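import numpy as np
import pytest

from facekit import encoding as enc
from facekit import io_core as io
from facekit import synthdata as sd


class TestVarianceExplained:
    def test_perfect_prediction(self, rng):
        x = rng.normal(size=100)
        assert enc.variance_explained(x, x) == 1.0

    def test_mean_prediction_is_zero(self, rng):
        x = rng.normal(size=100)
        assert enc.variance_explained(x, np.full_like(x, x.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert enc.variance_explained([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(0.8)

    def test_zero_variance_test_undefined(self):
        assert np.isnan(enc.variance_explained([2, 2, 2], [1, 2, 3]))

    def test_scale_invariance(self, rng):
        x = rng.normal(size=200)
        p = x + 0.3 * rng.normal(size=200)
        assert enc.variance_explained(5 * x, 5 * p) == pytest.approx(
            enc.variance_explained(x, p))


class TestCumulativeVE:
    def test_perfect_prediction_reaches_one(self, rng):
        Y = rng.normal(size=(50, 8))
        curve = enc.cumulative_ve(Y, Y)
        assert curve[-1] == pytest.approx(1.0)

    def test_pc1_only_flat_after_first(self, rng):
        Y = rng.normal(size=(200, 4)) * np.array([3.0, 2.0, 1.0, 0.5])
        pred = np.tile(Y.mean(axis=0), (200, 1))
        pred[:, 0] = Y[:, 0]
        curve = enc.cumulative_ve(Y, pred)
        sst = ((Y - Y.mean(0)) ** 2).sum(0)
        assert curve[0] == pytest.approx(sst[0] / sst.sum())
        np.testing.assert_allclose(np.diff(curve), 0.0, atol=1e-12)

    def test_nondecreasing_for_no_worse_than_mean(self, rng):
        Y = rng.normal(size=(100, 6))
        pred = 0.5 * Y + 0.5 * Y.mean(axis=0)
        assert np.all(np.diff(enc.cumulative_ve(Y, pred)) >= -1e-12)


class TestNeuralSVD:
    def test_exact_low_rank_reconstruction(self, rng):
        U = rng.normal(size=(30, 3))
        V = rng.normal(size=(200, 3))
        act = U @ V.T
        act += rng.normal(size=act.shape) * 1e-9
        rec = io.NeuralRecording(act, rng.uniform(0, 100, (30, 2)), 3.0)
        pcs = enc.neural_svd(rec, k=3)
        z, _ = rec.zscored()
        recon = pcs.U @ pcs.Y.T
        assert np.abs(recon - z).max() < 1e-6

    def test_sign_convention_deterministic(self, rng):
        act = rng.normal(size=(20, 100))
        rec = io.NeuralRecording(act, np.zeros((20, 2)), 3.0)
        pcs = enc.neural_svd(rec, k=5)
        for i in range(5):
            assert pcs.U[np.argmax(np.abs(pcs.U[:, i])), i] > 0

    def test_time_shuffle_flattens_spectrum(self, rng):
        t = np.arange(500)
        act = np.outer(rng.normal(size=(40,)), np.sin(t / 20)) + 0.5 * rng.normal(size=(40, 500))
        rec = io.NeuralRecording(act, np.zeros((40, 2)), 3.0)
        s_orig = enc.neural_svd(rec, k=5).S
        shuffled = act[:, rng.permutation(500)]
        # shuffle each row independently to break shared structure
        for i in range(40):
            shuffled[i] = shuffled[i, rng.permutation(500)]
        s_shuf = enc.neural_svd(io.NeuralRecording(shuffled, np.zeros((40, 2)), 3.0), k=5).S
        assert s_shuf[0] < s_orig[0]

    def test_k_too_large_raises(self, rng):
        rec = io.NeuralRecording(rng.normal(size=(5, 50)), np.zeros((5, 2)), 3.0)
        with pytest.raises(ValueError, match="k="):
            enc.neural_svd(rec, k=10)


class TestRRR:
    def test_full_rank_small_lambda_equals_ols(self, rng):
        X = rng.normal(size=(200, 20))
        Y = X @ rng.normal(size=(20, 30)) + 0.1 * rng.normal(size=(200, 30))
        m = enc.fit_rrr(X, Y, rank=20, lam=1e-12)
        Xc = X - X.mean(0)
        ols = np.linalg.lstsq(Xc, Y - Y.mean(0), rcond=None)[0]
        np.testing.assert_allclose(m.B @ m.A.T, ols, atol=1e-6)

    def test_exact_rank2_recovery(self, rng):
        X = rng.normal(size=(300, 15))
        Y = X @ rng.normal(size=(15, 2)) @ rng.normal(size=(2, 25))
        tr = np.arange(200)
        te = np.arange(200, 300)
        m = enc.fit_rrr(X, Y, rank=2, lam=1e-9, train_idx=tr)
        pred = m.predict(X)[te]
        sst = ((Y[te] - Y[te].mean(0)) ** 2).sum()
        ve = 1 - ((Y[te] - pred) ** 2).sum() / sst
        assert ve == pytest.approx(1.0, abs=1e-6)

    def test_training_fit_monotone_in_rank(self, rng):
        X = rng.normal(size=(150, 10))
        Y = X @ rng.normal(size=(10, 12)) + rng.normal(size=(150, 12))
        sse = []
        for r in (1, 2, 10):
            m = enc.fit_rrr(X, Y, rank=r, lam=1e-9)
            sse.append(((Y - m.predict(X)) ** 2).sum())
        assert sse[0] >= sse[1] >= sse[2]

    def test_full_rank_equals_ridge_identity(self, rng):
        # RRR at full rank is exactly the ridge solution (matrix identity)
        X = rng.normal(size=(40, 20))
        Y = rng.normal(size=(40, 30))
        lam = 0.5
        m = enc.fit_rrr(X, Y, rank=20, lam=lam)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        ridge = np.linalg.solve(Xc.T @ Xc + lam * np.eye(20), Xc.T @ Yc)
        np.testing.assert_allclose(m.B @ m.A.T, ridge, atol=1e-6)

    def test_rank_exceeding_dims_raises(self, rng):
        with pytest.raises(ValueError, match="rank"):
            enc.fit_rrr(rng.normal(size=(50, 4)), rng.normal(size=(50, 6)), rank=5)


def _tiny_spec():
    return enc.EncoderSpec(n_deep=32, n_hidden=16, n_conv=4, conv_len=11,
                           epochs=120, anneal_at=(80, 100))


class TestEncoder:
    def test_default_deep_features_are_256_dim(self):
        spec = enc.EncoderSpec()
        e = enc.Encoder(22, 128, spec, seed=0)
        feats = e.deep_features(np.zeros((10, 22)))
        assert feats.shape == (10, 256)

    def test_noise_targets_give_zero_ve(self, rng):
        T_b, T_n = 20000, 1200
        X = rng.normal(size=(T_b, 4))
        targets = rng.normal(size=(T_n, 6))
        split = io.make_split(T_n, 3.0)
        fit = enc.fit_encoder(X, 50.0, targets, 3.0, split, spec=_tiny_spec(), seed=1)
        assert abs(np.nanmean(fit.ledger.ve)) < 0.05

    def test_seed_reproducibility(self, rng):
        X = rng.normal(size=(10000, 4))
        targets = rng.normal(size=(600, 6))
        split = io.make_split(600, 3.0)
        spec = _tiny_spec()
        f1 = enc.fit_encoder(X, 50.0, targets, 3.0, split, spec=spec, seed=7)
        f2 = enc.fit_encoder(X, 50.0, targets, 3.0, split, spec=spec, seed=7)
        np.testing.assert_array_equal(f1.loss_history, f2.loss_history)
        np.testing.assert_array_equal(f1.ledger.ve, f2.ledger.ve)

    def test_nan_inputs_direct_to_filtering(self, rng):
        X = rng.normal(size=(10000, 4))
        X[5, 0] = np.nan
        split = io.make_split(600, 3.0)
        with pytest.raises(ValueError, match="filtering"):
            enc.fit_encoder(X, 50.0, rng.normal(size=(600, 3)), 3.0, split, spec=_tiny_spec())

    def test_behavior_to_neural_rows_causal(self):
        rows = enc.behavior_to_neural_rows(9, 3.0, 50.0, 150)
        # neural frame k at time k/3 s maps to behavior frame floor(k*50/3)
        np.testing.assert_array_equal(rows, (np.arange(9) * 50 / 3).astype(int))


class TestPeerPrediction:
    @pytest.fixture(scope="class")
    def planted(self):
        kp = sd.make_keypoint_traces(60000, rate=50.0, seed=41)
        spec = sd.PlantedEncoderSpec(n_neurons=400, behavior_frac=0.35,
                                     shared_frac=0.25, seed=42)
        rec, truth = sd.make_neural_from_behavior(kp, spec)
        split = io.make_split(rec.n_timepoints, rec.rate)
        return rec, truth, split

    def test_ev_matches_construction(self, planted):
        rec, truth, split = planted
        ev = enc.peer_prediction(rec, split, k=64, rank=63)
        assert np.nanmean(ev) == pytest.approx(0.6, abs=0.07)

    def test_independent_neurons_have_zero_ev(self, rng):
        act = rng.normal(size=(300, 2000))
        rec = io.NeuralRecording(act, rng.uniform(0, 1000, (300, 2)), 3.0)
        split = io.make_split(2000, 3.0)
        ev = enc.peer_prediction(rec, split, k=64, rank=63)
        assert abs(np.nanmean(ev)) < 0.05

    def test_strip_relabeling_invariance(self, planted):
        rec, _, split = planted
        ev1 = enc.peer_prediction(rec, split, k=64, rank=63)
        # shifting all x-positions by one strip width swaps even/odd groups
        rec2 = io.NeuralRecording(rec.activity, rec.positions + [200.0, 0.0], rec.rate)
        ev2 = enc.peer_prediction(rec2, split, k=64, rank=63)
        assert np.nanmean(np.abs(ev1 - ev2)) < 0.02

    def test_small_group_raises(self, rng):
        act = rng.normal(size=(100, 500))
        rec = io.NeuralRecording(act, rng.uniform(0, 1000, (100, 2)), 3.0)
        split = io.make_split(500, 3.0)
        with pytest.raises(ValueError, match="smaller k"):
            enc.peer_prediction(rec, split, k=128)


class TestScalingCurves:
    def test_full_fraction_consistency_and_monotonicity(self):
        kp = sd.make_keypoint_traces(45000, rate=50.0, seed=43)
        spec = sd.PlantedEncoderSpec(n_neurons=300, behavior_frac=0.4,
                                     shared_frac=0.2, seed=44)
        rec, _ = sd.make_neural_from_behavior(kp, spec)
        split = io.make_split(rec.n_timepoints, rec.rate)
        X = kp.neural_coords()
        Xz = (X - X.mean(0)) / X.std(0)
        rows = enc.behavior_to_neural_rows(rec.n_timepoints, rec.rate, kp.rate, len(Xz))
        out = enc.scaling_curves(Xz[rows], rec, split, neuron_fractions=(0.5, 1.0),
                                 time_fractions=(0.25, 1.0), k=64, rank=12, seed=3)
        # more training time cannot hurt on this fixture
        assert out["time"][0.25] <= out["time"][1.0] + 0.02
        # EV-normalized VE is roughly invariant to subsampling an
        # exchangeable population
        assert abs(out["neurons"][0.5] - out["neurons"][1.0]) < 0.1
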