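import numpy as np
import pytest
from scipy.optimize import minimize

from ontoalign.dae import (
    DAEConfig,
    DAEParams,
    apply_scaler,
    corrupt,
    dae_distance,
    decode,
    encode,
    fit_scaler,
    init_params,
    invert_scaler,
    reconstruction_loss,
    standardize,
    train_dae,
)


class TestScaler:
    def test_extremes_map_to_unit_interval_ends(self):
        X = [np.array([0.0, -2.0]), np.array([4.0, 2.0])]
        rec = fit_scaler(X)
        assert np.allclose(apply_scaler(X[0], rec), [0.0, 0.0])
        assert np.allclose(apply_scaler(X[1], rec), [1.0, 1.0])

    def test_constant_dimension_maps_to_half(self):
        X = [np.array([1.0, 3.0]), np.array([1.0, 5.0])]
        rec = fit_scaler(X)
        assert apply_scaler(np.array([1.0, 4.0]), rec)[0] == 0.5

    def test_roundtrip_inverse(self):
        rng = np.random.default_rng(0)
        X = [rng.normal(size=5) for _ in range(20)]
        rec = fit_scaler(X)
        for x in X:
            assert np.allclose(invert_scaler(apply_scaler(x, rec), rec), x, atol=1e-9)

    def test_out_of_range_clipped(self):
        rec = fit_scaler([np.zeros(2), np.ones(2)])
        assert np.allclose(apply_scaler(np.array([-1.0, 2.0]), rec), [0.0, 1.0])

    def test_standardize_moments(self):
        rng = np.random.default_rng(1)
        X = [rng.normal(3.0, 2.0, size=4) for _ in range(500)]
        rec = fit_scaler(X)
        Z = np.array([standardize(x, rec) for x in X])
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_empty_fit_error(self):
        with pytest.raises(ValueError):
            fit_scaler([])


class TestCorrupt:
    def test_exact_count_zeroed(self):
        rng = np.random.default_rng(0)
        x = np.ones(200)
        out = corrupt(x, 0.4, rng)
        assert int((out == 0).sum()) == 80

    def test_survivors_bit_equal(self):
        rng = np.random.default_rng(0)
        x = np.arange(1.0, 21.0)
        out = corrupt(x, 0.4, rng)
        kept = out != 0
        assert np.array_equal(out[kept], x[kept])

    def test_rounding_to_zero_is_identity(self):
        rng = np.random.default_rng(0)
        x = np.ones(10)
        assert np.array_equal(corrupt(x, 0.01, rng), x)

    def test_same_seed_same_mask(self):
        x = np.ones(50)
        a = corrupt(x, 0.4, np.random.default_rng(5))
        b = corrupt(x, 0.4, np.random.default_rng(5))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("v", [0.0, 1.0, -0.5])
    def test_bad_fraction(self, v):
        with pytest.raises(ValueError):
            corrupt(np.ones(10), v, np.random.default_rng(0))

    def test_count_invariant_many_draws(self):
        rng = np.random.default_rng(2)
        x = np.ones(37)  # v*d non-integral: round(0.4*37) = 15
        for _ in range(1000):
            assert int((corrupt(x, 0.4, rng) == 0).sum()) == 15


class TestEncodeDecode:
    def test_zero_weights_zero_code(self):
        cfg = DAEConfig(hidden_dim=4)
        p = DAEParams(np.zeros((4, 6)), np.zeros(4), np.zeros((6, 4)), np.zeros(6), None, cfg)
        assert np.array_equal(encode(np.ones(6), p), np.zeros(4))

    def test_zero_code_decodes_to_half(self):
        cfg = DAEConfig(hidden_dim=4)
        p = DAEParams(np.zeros((4, 6)), np.zeros(4), np.ones((6, 4)), np.zeros(6), None, cfg)
        assert np.allclose(decode(np.zeros(4), p), 0.5)

    def test_matches_hand_forward_pass(self):
        rng = np.random.default_rng(3)
        p = init_params(5, DAEConfig(hidden_dim=3), rng)
        x = rng.normal(size=5)
        h = encode(x, p)
        assert np.allclose(h, np.maximum(p.W @ x + p.b, 0.0), atol=1e-9)
        z = decode(h, p)
        assert np.allclose(z, 1.0 / (1.0 + np.exp(-(p.W_prime @ h + p.b_prime))), atol=1e-9)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(0)
        p = init_params(5, DAEConfig(hidden_dim=3), rng)
        with pytest.raises(ValueError):
            encode(np.ones(4), p)
        with pytest.raises(ValueError):
            decode(np.ones(4), p)


class TestReconstructionLoss:
    def test_near_zero_at_binary_fixpoint(self):
        x = np.array([0.0, 1.0, 1.0, 0.0])
        z = np.clip(x, 1e-9, 1 - 1e-9)
        assert reconstruction_loss(x, x, z) < 1e-6

    def test_additivity_of_the_two_terms(self):
        rng = np.random.default_rng(1)
        x, y, z = rng.uniform(0, 1, 5), rng.uniform(0, 1, 5), rng.uniform(0.1, 0.9, 5)
        lx = reconstruction_loss(x, x, z) / 2.0
        ly = reconstruction_loss(y, y, z) / 2.0
        assert reconstruction_loss(x, y, z) == pytest.approx(lx + ly)

    def test_closed_form_at_half(self):
        d = 7
        half = np.full(d, 0.5)
        assert reconstruction_loss(half, half, half) == pytest.approx(2 * d * np.log(2))

    def test_argmin_is_midpoint_numeric_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x, y = rng.uniform(0.05, 0.95, 5), rng.uniform(0.05, 0.95, 5)
            res = minimize(
                lambda z: reconstruction_loss(x, y, z),
                x0=np.full(5, 0.5),
                bounds=[(1e-6, 1 - 1e-6)] * 5,
            )
            assert np.allclose(res.x, (x + y) / 2.0, atol=1e-4)


class TestTrainDae:
    def _pairs(self, n=30, d=12, seed=0):
        rng = np.random.default_rng(seed)
        U = rng.normal(size=(6, d))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        return [
            (U[i % 6] + rng.normal(0, 0.1, d), U[i % 6] + rng.normal(0, 0.1, d))
            for i in range(n)
        ]

    def test_zero_epochs_returns_initialization(self):
        pairs = self._pairs()
        cfg = DAEConfig(hidden_dim=4, epochs=0, seed=1)
        params, hist = train_dae(pairs, cfg)
        fresh = init_params(12, cfg, np.random.default_rng(1))
        assert np.array_equal(params.W, fresh.W)
        assert len(hist) == 1

    def test_loss_decreases(self):
        params, hist = train_dae(self._pairs(), DAEConfig(hidden_dim=4, epochs=15, seed=1))
        assert hist[-1] < hist[0]

    def test_degenerate_pair_trains_as_standard_dae(self):
        x = np.random.default_rng(0).normal(size=8)
        params, hist = train_dae([(x, x)] * 10, DAEConfig(hidden_dim=4, epochs=5, seed=2))
        assert np.isfinite(hist).all()

    def test_checkpoint_roundtrip(self, tmp_path):
        params, _ = train_dae(self._pairs(), DAEConfig(hidden_dim=4, epochs=2, seed=1))
        p = tmp_path / "dae.npz"
        params.save(p)
        loaded = DAEParams.load(p)
        assert np.array_equal(loaded.W, params.W)
        x = np.random.default_rng(3).normal(size=12)
        y = np.random.default_rng(4).normal(size=12)
        assert dae_distance(x, y, loaded) == pytest.approx(dae_distance(x, y, params))


class TestDaeDistance:
    def test_self_distance_zero(self):
        params, _ = train_dae(
            TestTrainDae()._pairs(), DAEConfig(hidden_dim=4, epochs=3, seed=1)
        )
        s = np.random.default_rng(5).normal(size=12)
        assert dae_distance(s, s, params) == pytest.approx(0.0)

    def test_untrained_params_still_in_range(self):
        rng = np.random.default_rng(6)
        params = init_params(12, DAEConfig(hidden_dim=4), rng)
        params.scaler = fit_scaler([rng.normal(size=12) for _ in range(10)])
        for _ in range(20):
            d = dae_distance(rng.normal(size=12), rng.normal(size=12), params)
            assert 0.0 <= d <= 2.0

    def test_paraphrase_pairs_score_lower_than_confounders_on_average(self):
        """After training, same-concept pairs have smaller hidden-code
        distances on average than planted cross-concept confounder pairs."""
        rng = np.random.default_rng(7)
        d = 12
        U = rng.normal(size=(8, d))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        # plant a confounder: concept 7 near concept 0
        w = rng.normal(size=d)
        w -= (w @ U[0]) * U[0]
        w /= np.linalg.norm(w)
        U[7] = 0.8 * U[0] + 0.6 * w
        pairs = [
            (U[i % 8] + rng.normal(0, 0.08, d), U[i % 8] + rng.normal(0, 0.08, d))
            for i in range(40)
        ]
        params, _ = train_dae(pairs, DAEConfig(hidden_dim=6, epochs=15, seed=3))
        same = [
            dae_distance(U[i % 8] + rng.normal(0, 0.08, d), U[i % 8] + rng.normal(0, 0.08, d), params)
            for i in range(40)
        ]
        conf = [
            dae_distance(U[0] + rng.normal(0, 0.08, d), U[7] + rng.normal(0, 0.08, d), params)
            for _ in range(40)
        ]
        assert np.mean(same) < np.mean(conf)
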