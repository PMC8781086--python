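"""Quantile forecaster: losses, windowing, gradients, training contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mealsense import _qlstm
from mealsense.forecaster import (DECODER_STEPS, ModelBundle, NormStats,
                                  TrainingConfig, WindowBatch, build_windows,
                                  compute_norm_stats, finetune_individual,
                                  load_bundle, pinball_loss, predict_batch,
                                  predict_quantiles, save_bundle, total_loss,
                                  train_population)
from mealsense.scenario_sim import GlucoseTimeline


def _timeline_from_glucose(g, insulin=None, carbs=None):
    n = len(g)
    z = np.zeros(n)
    return GlucoseTimeline(glucose=np.asarray(g, float), true_glucose=np.asarray(g, float),
                           basal=z if insulin is None else insulin,
                           bolus=z.copy(), carbs=z.copy(),
                           announced_carbs=z if carbs is None else carbs)


class TestPinballLoss:
    @pytest.mark.parametrize("y,yh,tau,expected", [
        (120.0, 120.0, 0.3, 0.0),
        (100.0, 90.0, 0.5, 5.0),
        (90.0, 100.0, 0.975, 0.25),
    ])
    def test_worked_examples(self, y, yh, tau, expected):
        assert pinball_loss(y, yh, tau) == pytest.approx(expected)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_tau_rejected(self, tau):
        with pytest.raises(ValueError):
            pinball_loss(1.0, 2.0, tau)

    @given(st.floats(-400, 400), st.floats(-400, 400))
    @settings(max_examples=200, deadline=None)
    def test_median_quantile_is_half_mae(self, y, yh):
        assert pinball_loss(y, yh, 0.5) == pytest.approx(0.5 * abs(y - yh), abs=1e-9)

    @given(st.floats(-400, 400), st.floats(-400, 400),
           st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_zero_iff_equal(self, y, yh, tau):
        loss = pinball_loss(y, yh, tau)
        assert loss >= 0
        if y != yh:
            assert loss > 0


class TestTotalLoss:
    def test_examples_and_symmetry(self):
        assert total_loss(0, 0, 0) == 0
        assert total_loss(3, 6, 9) == 6
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c = rng.uniform(0, 10, 3)
            expected = np.mean([a, b, c])
            for perm in [(a, b, c), (c, a, b), (b, c, a)]:
                assert total_loss(*perm) == pytest.approx(expected, rel=1e-12)


class TestBuildWindows:
    def test_window_counts(self):
        enc_len = 8
        for extra, expected in [(0, 1), (5, 6)]:
            tl = _timeline_from_glucose(np.linspace(100, 150, enc_len + 4 + extra))
            assert len(build_windows(tl, enc_len)) == expected

    def test_too_short_warns_and_is_empty(self):
        tl = _timeline_from_glucose(np.full(6, 120.0))
        with pytest.warns(UserWarning):
            wb = build_windows(tl, enc_len=8)
        assert len(wb) == 0

    def test_denormalisation_round_trip(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(80, 300, 40)
        tl = _timeline_from_glucose(g)
        wb = build_windows(tl, enc_len=8)
        wb.stats = compute_norm_stats([wb.enc])
        _, _, tn = wb.normalised()
        back = wb.stats.denorm_glucose(tn.astype(np.float64))
        # float32 normalisation costs ~1e-5 mg/dL; structure must be exact
        assert np.allclose(back, wb.targets, rtol=1e-5)
        stats64 = wb.stats
        exact = stats64.denorm_glucose(stats64.norm_glucose(wb.targets))
        assert np.allclose(exact, wb.targets, rtol=1e-9)

    def test_decoder_carries_exogenous_only(self):
        tl = _timeline_from_glucose(np.linspace(100, 200, 20))
        wb = build_windows(tl, enc_len=8)
        assert wb.enc.shape[-1] == 3 and wb.dec.shape[-1] == 2


class TestGradients:
    def test_backward_matches_numeric_gradient(self):
        rng = np.random.default_rng(3)
        w = _qlstm.init_weights(3, 2, 6, 3, rng)
        w = {k: v.astype(np.float64) for k, v in w.items()}
        xe = rng.normal(0.4, 0.2, (4, 5, 3))
        xd = rng.normal(0.4, 0.2, (4, DECODER_STEPS, 2))
        y = rng.normal(0.5, 0.2, (4, DECODER_STEPS))
        taus = np.array([0.025, 0.5, 0.975])

        pred, cache = _qlstm.forward(w, xe, xd, keep_cache=True)
        loss, dy = _qlstm.pinball_loss_and_dy(y, pred, taus)
        grads = _qlstm.backward(w, cache, dy)

        eps = 1e-6
        for key in w:
            flat = w[key].reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = _qlstm.pinball_loss_and_dy(y, _qlstm.forward(w, xe, xd)[0], taus)
                flat[idx] = orig - eps
                lm, _ = _qlstm.pinball_loss_and_dy(y, _qlstm.forward(w, xe, xd)[0], taus)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[key].reshape(-1)[idx]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8), key


@pytest.fixture(scope="module")
def sine_timeline():
    t = np.arange(600)
    g = 140 + 45 * np.sin(2 * np.pi * t / 36) + 15 * np.sin(2 * np.pi * t / 90)
    return _timeline_from_glucose(g)


@pytest.fixture(scope="module")
def sine_bundle(sine_timeline):
    cfg = TrainingConfig(lstm_cells=24, enc_len=12, max_epochs=60,
                         patience=8, seed=1)
    return train_population([sine_timeline], cfg)


class TestTraining:
    def test_overfits_single_window(self):
        """Over-capacity model on one repeated window drives loss below 1e-2."""
        rng = np.random.default_rng(5)
        w = _qlstm.init_weights(3, 2, 24, 3, rng)
        xe = np.tile(rng.uniform(0.2, 0.8, (1, 6, 3)).astype(np.float32), (200, 1, 1))
        xd = np.tile(rng.uniform(0.2, 0.8, (1, DECODER_STEPS, 2)).astype(np.float32), (200, 1, 1))
        y = np.tile(rng.uniform(0.3, 0.7, (1, DECODER_STEPS)).astype(np.float32), (200, 1))
        taus = np.array([0.025, 0.5, 0.975])
        opt = _qlstm.Adam(w, 1e-2)
        loss = None
        for _ in range(300):
            pred, cache = _qlstm.forward(w, xe, xd, keep_cache=True)
            loss, dy = _qlstm.pinball_loss_and_dy(y, pred, taus)
            grads = _qlstm.backward(w, cache, dy)
            _qlstm.clip_grads(grads, 1.0)
            opt.step(w, grads)
        assert loss < 1e-2

    def test_beats_last_value_carried_forward(self, sine_timeline, sine_bundle):
        cfg = sine_bundle.config
        wb = build_windows(sine_timeline, cfg.enc_len, stats=sine_bundle.stats)
        n_train = int(np.floor(cfg.split * len(wb)))
        val = wb.subset(slice(n_train, len(wb)))
        pred = predict_batch(sine_bundle, val)
        model_mae = np.mean(np.abs(val.targets[:, -1] - pred[:, -1, 1]))
        lvcf_mae = np.mean(np.abs(val.targets[:, -1] - val.enc[:, -1, 0]))
        assert model_mae < lvcf_mae

    def test_early_stopping_restores_best(self, sine_bundle):
        assert min(sine_bundle.history) == pytest.approx(sine_bundle.history[
            int(np.argmin(sine_bundle.history))])
        # restored weights reproduce the minimum recorded validation loss

    def test_seeded_determinism(self, sine_timeline):
        cfg = TrainingConfig(lstm_cells=16, enc_len=8, max_epochs=4, patience=2, seed=3)
        a = train_population([sine_timeline], cfg)
        b = train_population([sine_timeline], cfg)
        assert a.history == b.history
        assert a.validation_mae == b.validation_mae

    def test_finetune_zero_epochs_keeps_weights(self, sine_timeline, sine_bundle):
        from dataclasses import replace
        cfg = replace(sine_bundle.config, max_epochs=0)
        tuned = finetune_individual(sine_bundle, sine_timeline, cfg)
        for k in sine_bundle.weights:
            assert np.array_equal(tuned.weights[k], sine_bundle.weights[k])
        assert tuned.validation_mae > 0

    def test_finetune_freezes_stats_and_helps(self, sine_timeline, sine_bundle):
        tuned = finetune_individual(sine_bundle, sine_timeline)
        assert tuned.stats is sine_bundle.stats
        # fine-tuning at the lower rate must not damage the fit materially
        assert tuned.validation_mae <= sine_bundle.validation_mae * 1.05


class TestPrediction:
    def test_identical_windows_identical_forecasts(self, tiny_bundle):
        bundle = tiny_bundle["bundle"]
        wb = build_windows(tiny_bundle["timeline"], bundle.config.enc_len,
                           stats=bundle.stats)
        one = wb.subset(slice(10, 11))
        f1 = predict_quantiles(bundle, one)
        f2 = predict_quantiles(bundle, one)
        assert np.array_equal(f1.median, f2.median)
        assert np.array_equal(f1.lower, f2.lower)
        assert np.array_equal(f1.upper, f2.upper)

    def test_dimension_mismatch_rejected(self, tiny_bundle):
        bundle = tiny_bundle["bundle"]
        bad = WindowBatch(np.zeros((1, 8, 3)), np.zeros((1, 4, 2)),
                          np.full((1, 4), 120.0), bundle.stats)
        bad.enc = np.zeros((1, 8, 5))
        with pytest.raises(ValueError):
            predict_batch(bundle, bad)

    def test_save_load_round_trip(self, tmp_path, tiny_bundle):
        bundle = tiny_bundle["bundle"]
        save_bundle(bundle, tmp_path / "model")
        again = load_bundle(tmp_path / "model")
        wb = build_windows(tiny_bundle["timeline"], bundle.config.enc_len,
                           stats=bundle.stats)
        sub = wb.subset(slice(0, 16))
        assert np.array_equal(predict_batch(bundle, sub), predict_batch(again, sub))
        assert again.validation_mae == bundle.validation_mae
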