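"""Architecture contracts: RespBlock residual path, stage shapes, baselines,
checkpoints and forward-pass purity."""

import numpy as np
import pytest

from ppgrr.errors import ConfigurationError, ShapeError
from ppgrr.model import (
    BASELINE_NAMES,
    DilatedResNetConfig,
    MeanPredictor,
    RespBlock,
    build_baseline,
    build_dilated_resnet,
    load_estimator,
    resp_block,
)


class TestRespBlock:
    def test_zero_input_zero_biases_gives_zero(self):
        blk = RespBlock(2, 4, 2, 3, np.random.default_rng(0))
        y = blk.forward(np.zeros((1, 32, 2), dtype=np.float32))
        np.testing.assert_array_equal(y, 0.0)

    @pytest.mark.parametrize("L", [64, 1800])
    def test_output_length_preserved(self, L):
        blk = RespBlock(1, 8, 2, 3, np.random.default_rng(1))
        x = np.random.default_rng(2).random((2, L, 1)).astype(np.float32)
        assert blk.forward(x).shape == (2, L, 8)

    def test_zero_weights_reduce_to_channel_mean_shortcut(self):
        blk = RespBlock(3, 5, 2, 3, np.random.default_rng(0))
        for p in blk.parameters:
            p[...] = 0.0
        x = np.random.default_rng(3).random((2, 20, 3)).astype(np.float32)
        y = blk.forward(x)
        expected = np.repeat(x.mean(axis=2, keepdims=True), 5, axis=2)
        np.testing.assert_allclose(y, expected, rtol=1e-6)

    def test_channel_mismatch_raises(self):
        blk = RespBlock(3, 4, 2, 3, np.random.default_rng(0))
        with pytest.raises(ShapeError):
            blk.forward(np.zeros((1, 10, 2), dtype=np.float32))

    def test_functional_wrapper_shape(self):
        cfg = DilatedResNetConfig(filters_c=4)
        x = np.random.default_rng(0).random((2, 40, 1)).astype(np.float32)
        assert resp_block(x, cfg).shape == (2, 40, 16)


class TestDilatedResNet:
    def test_default_stage_filters_double_from_256(self):
        cfg = DilatedResNetConfig()
        assert cfg.stage_filters == [256, 512, 1024, 2048]

    def test_summary_reports_stage_filters_and_scalar_head(self):
        est = build_dilated_resnet(
            DilatedResNetConfig(filters_c=4, n_blk=3, input_len=256), seed=0
        )
        rows = est.summary()
        resp_shapes = [r["output_shape"][2] for r in rows if r["layer"].startswith("respblock")]
        assert resp_shapes == [16, 32, 64]
        assert rows[-2]["output_shape"] == [1, 1]  # dense head before total row
        assert rows[-1]["params"] == sum(p.size for p in est.parameters)

    def test_config_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            DilatedResNetConfig(n_blk=6).validate()
        with pytest.raises(ConfigurationError):
            DilatedResNetConfig(filters_c=11).validate()

    def test_too_short_input_reports_minimum_length(self):
        with pytest.raises(ConfigurationError, match="minimum admissible"):
            build_dilated_resnet(DilatedResNetConfig(n_blk=5, s_c=4, input_len=64))

    def test_single_block_zero_weights_predicts_bias(self):
        est = build_dilated_resnet(
            DilatedResNetConfig(n_blk=1, filters_c=4, input_len=64), seed=0
        )
        for p in est.parameters:
            p[...] = 0.0
        est.parameters[-1][...] = 7.25  # final dense bias
        X = np.random.default_rng(0).random((5, 64, 1)).astype(np.float32)
        np.testing.assert_allclose(est.forward(X).ravel(), 7.25, rtol=1e-6)

    def test_forward_pass_is_pure(self):
        est = build_dilated_resnet(
            DilatedResNetConfig(filters_c=4, n_blk=2, input_len=128), seed=1
        )
        X = np.random.default_rng(4).random((3, 128, 1)).astype(np.float32)
        a = est.forward(X).copy()
        b = est.forward(X)
        np.testing.assert_array_equal(a, b)

    def test_seeded_builds_identical(self):
        a = build_dilated_resnet(DilatedResNetConfig(filters_c=4, input_len=256), seed=3)
        b = build_dilated_resnet(DilatedResNetConfig(filters_c=4, input_len=256), seed=3)
        for pa, pb in zip(a.parameters, b.parameters):
            np.testing.assert_array_equal(pa, pb)

    @pytest.mark.parametrize("n_blk", [1, 5])
    @pytest.mark.parametrize("kernel_blk", [2, 5])
    @pytest.mark.parametrize("d_blk", [1, 5])
    @pytest.mark.parametrize("kernel_dwn", [2, 4])
    @pytest.mark.parametrize("s_c", [2, 4])
    def test_grid_corner_configs_build_and_regress(self, n_blk, kernel_blk, d_blk,
                                                   kernel_dwn, s_c):
        """Shape oracle on the corners of the structural search box (smallest
        filter width; shapes are independent of the filter count)."""
        cfg = DilatedResNetConfig(
            n_blk=n_blk, kernel_blk=kernel_blk, d_blk=d_blk, kernel_dwn=kernel_dwn,
            filters_c=4, s_c=s_c, n_den=20, input_len=1800,
        )
        # independent admissibility arithmetic: each stage maps L -> ceil(L/2)//s_c
        L = 1800
        for _ in range(n_blk):
            L = ((L + 1) // 2) // s_c
        if L < 1:
            with pytest.raises(ConfigurationError, match="minimum admissible"):
                build_dilated_resnet(cfg, seed=0)
            return
        est = build_dilated_resnet(cfg, seed=0)
        X = np.zeros((2, 1800, 1), dtype=np.float32)
        assert est.forward(X).shape == (2, 1)

    def test_widest_filters_single_block_builds(self):
        cfg = DilatedResNetConfig(n_blk=1, filters_c=10, input_len=128)
        est = build_dilated_resnet(cfg, seed=0)
        assert est.forward(np.zeros((1, 128, 1), dtype=np.float32)).shape == (1, 1)


class TestBaselines:
    @pytest.mark.parametrize("name", BASELINE_NAMES)
    def test_every_baseline_regresses_to_scalar(self, name):
        est = build_baseline(name, {"input_len": 64}, seed=0)
        X = np.random.default_rng(0).random((3, 64, 1)).astype(np.float32)
        out = est.forward(X)
        assert out.shape == (3, 1)
        preds = est.predict(X)
        assert preds.shape == (3,)

    def test_lstm_width_is_256(self):
        est = build_baseline("lstm", seed=0)
        lstm = est.network.layers[0]
        assert lstm.units == 256
        assert lstm.name == "lstm_256"

    def test_bilstm_has_two_passes_of_128(self):
        est = build_baseline("bilstm", seed=0)
        bi = est.network.layers[0]
        assert bi.fwd.units == 128 and bi.bwd.units == 128

    def test_attention_bilstm_width_64(self):
        est = build_baseline("attn_bilstm", seed=0)
        assert est.network.layers[0].fwd.units == 64

    def test_unknown_name_lists_choices(self):
        with pytest.raises(ConfigurationError, match="resnet"):
            build_baseline("transformer")


class TestCheckpoints:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        est = build_dilated_resnet(
            DilatedResNetConfig(filters_c=4, n_blk=2, input_len=128), seed=2
        )
        X = np.random.default_rng(1).random((4, 128, 1)).astype(np.float32)
        before = est.predict(X)
        p = est.save(tmp_path / "ckpt.npz")
        loaded = load_estimator(p)
        np.testing.assert_array_equal(loaded.predict(X), before)

    def test_missing_checkpoint_errors(self, tmp_path):
        with pytest.raises(ConfigurationError, match="not found"):
            load_estimator(tmp_path / "nope.npz")

    def test_baseline_checkpoint_round_trip(self, tmp_path):
        est = build_baseline("cnn_lstm", {"input_len": 64}, seed=1)
        X = np.random.default_rng(2).random((2, 64, 1)).astype(np.float32)
        before = est.predict(X)
        p = est.save(tmp_path / "b.npz")
        np.testing.assert_array_equal(load_estimator(p).predict(X), before)


def test_mean_predictor_learns_training_mean():
    from ppgrr.preprocess import WindowSample

    wins = [WindowSample("s", np.zeros(8, dtype=np.float32), rr, "normal")
            for rr in (10.0, 20.0)]
    mp = MeanPredictor()
    mp.fit(wins)
    assert mp.mean_rr == 15.0
    np.testing.assert_array_equal(mp.predict(wins), [15.0, 15.0])
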