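"""Model assembly, parameter accounting, inference and weight I/O."""

import numpy as np
import pytest

from mducnn import (ModelConfig, ScheduleConfig, build_baseline_unet,
                    build_mdu_cnn, build_model, count_parameters, load_weights,
                    predict, save_weights)
from mducnn.models import mdu_config, unet_config
from mducnn.nn import BatchNorm, Conv


def hand_count_double_conv_unet(rank, in_ch, widths, batch_norm=True):
    """Independent closed-form parameter count for a plain double-conv
    U-Net: conv = k^rank * C_in * C_out + C_out, batch-norm = 2C."""
    k = 3 ** rank

    def conv(cin, cout, kk=k):
        return kk * cin * cout + cout

    def bn(c):
        return 2 * c if batch_norm else 0

    total, cin = 0, in_ch
    for w in widths:
        total += conv(cin, w) + conv(w, w) + 2 * bn(w)
        cin = w
    cur = widths[-1]
    for w in reversed(widths[:-1]):
        total += (2 ** rank) * cur * w + w          # transposed conv
        total += conv(2 * w, w) + conv(w, w) + 2 * bn(w)
        cur = w
    total += conv(widths[0], 1, kk=1)
    return total


class TestForwardContract:
    def test_2d_default_shape_and_range(self):
        model = build_mdu_cnn()
        x = np.random.default_rng(0).random((1, 64, 64, 3)).astype(np.float32)
        out = predict(model, x)
        assert out.shape == (1, 64, 64, 1)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_3d_tiny_shape(self, rng):
        cfg = mdu_config(3, depth=2,
                         schedule=ScheduleConfig(mode="formula",
                                                 base_filters=(8, 16, 32)))
        out = predict(build_model(cfg), rng.random((1, 8, 8, 4, 4)).astype(np.float32))
        assert out.shape == (1, 8, 8, 4, 1)

    def test_deterministic_inference(self, tiny_mdu_cfg, rng):
        model = build_model(tiny_mdu_cfg)
        x = rng.random((2, 16, 16, 3)).astype(np.float32)
        assert np.array_equal(predict(model, x), predict(model, x))

    def test_seeded_rebuild_is_bitwise_identical(self, tiny_mdu_cfg, rng):
        x = rng.random((1, 16, 16, 3)).astype(np.float32)
        a = predict(build_model(tiny_mdu_cfg), x)
        b = predict(build_model(tiny_mdu_cfg), x)
        assert np.array_equal(a, b)

    def test_input_validation(self, tiny_mdu_cfg, rng):
        model = build_model(tiny_mdu_cfg)
        with pytest.raises(ValueError):
            predict(model, rng.random((1, 15, 16, 3)))   # not divisible by 4
        with pytest.raises(ValueError):
            predict(model, rng.random((1, 16, 16, 2)))   # wrong channels


class TestParameterAccounting:
    def test_single_conv_closed_form(self):
        conv = Conv(2, 1, 2, 3, np.random.default_rng(0))
        assert conv.weight.data.size + conv.bias.data.size == 20  # 1*2*9 + 2

    def test_batch_norm_closed_form(self):
        bn = BatchNorm(4)
        trainable = bn.gamma.data.size + bn.beta.data.size
        assert trainable == 8
        assert trainable + bn.running_mean.size + bn.running_var.size == 16

    def test_toy_unet_matches_hand_oracle(self):
        cfg = unet_config(2, depth=1, in_channels=1, unet_widths=(2, 4))
        total = count_parameters(build_baseline_unet(cfg)).total_trainable
        assert total == hand_count_double_conv_unet(2, 1, [2, 4])

    @pytest.mark.parametrize("rank,widths,in_ch", [
        (2, (4, 8, 16), 3), (3, (2, 4), 2)])
    def test_unet_counts_match_hand_oracle(self, rank, widths, in_ch):
        cfg = unet_config(rank, depth=len(widths) - 1, in_channels=in_ch,
                          unet_widths=widths, double_before_pool=False)
        total = count_parameters(build_baseline_unet(cfg)).total_trainable
        assert total == hand_count_double_conv_unet(rank, in_ch, list(widths))

    def test_brute_force_enumeration(self, tiny_mdu_cfg):
        model = build_model(tiny_mdu_cfg)
        summary = count_parameters(model)
        brute = sum(int(np.prod(p.data.shape)) for p in model.parameters())
        assert summary.total_trainable == brute
        assert sum(r["trainable"] for r in summary.rows) == brute

    def test_full_model_totals(self):
        """The study-scale totals, derived independently from the
        architecture arithmetic before construction."""
        assert count_parameters(build_mdu_cnn()).total_trainable == 7_420_894
        assert count_parameters(build_baseline_unet()).total_trainable == 7_781_617

    def test_mdu_smaller_than_matched_baseline(self):
        """The defining design constraint: fewer parameters than U-Net."""
        assert (count_parameters(build_mdu_cnn()).total_trainable
                < count_parameters(build_baseline_unet()).total_trainable)

    def test_both_accounting_modes_reported(self, tiny_mdu_cfg):
        s = count_parameters(build_model(tiny_mdu_cfg))
        bn_channels = sum(r["out_channels"] for r in s.rows
                          if r["kind"] == "batch_norm")
        assert s.total_all == s.total_trainable + 2 * bn_channels


class TestWeightsIO:
    def test_round_trip_is_bitwise(self, tiny_mdu_cfg, rng, tmp_path):
        model = build_model(tiny_mdu_cfg)
        x = rng.random((1, 16, 16, 3)).astype(np.float32)
        before = predict(model, x)
        path = tmp_path / "weights.npz"
        save_weights(model, path)
        other = build_model(tiny_mdu_cfg)
        load_weights(other, path)
        assert np.array_equal(predict(other, x), before)

    def test_wrong_config_rejected(self, tiny_mdu_cfg, tmp_path):
        model = build_model(tiny_mdu_cfg)
        path = tmp_path / "weights.npz"
        save_weights(model, path)
        import dataclasses
        other = build_model(dataclasses.replace(tiny_mdu_cfg, depth=1))
        with pytest.raises(ValueError):
            load_weights(other, path)

    def test_corrupt_file_rejected(self, tiny_mdu_cfg, tmp_path):
        model = build_model(tiny_mdu_cfg)
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"not a weights archive")
        before = {k: v.copy() for k, v in model.state_dict().items()}
        with pytest.raises(IOError):
            load_weights(model, bad)
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)


class TestConfigSerialization:
    def test_yaml_round_trip(self, tiny_mdu_cfg):
        assert ModelConfig.from_yaml(tiny_mdu_cfg.to_yaml()) == tiny_mdu_cfg

    def test_builder_guards(self):
        with pytest.raises(ValueError):
            build_mdu_cnn(unet_config(2))
        with pytest.raises(ValueError):
            build_baseline_unet(mdu_config(2))
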