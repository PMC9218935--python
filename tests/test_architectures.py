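"""Builder calibration, graph validation, and last-fusion extraction."""

import numpy as np
import pytest

from halfunet import (
    ArchitectureConfig,
    ConvSpec,
    build,
    builder_names,
    count_network,
    extract_last_fusion,
)
from halfunet.complexity import conv_params
from halfunet.engine import UnsupportedConfigError
from halfunet.runtime import Model


class TestCalibration:
    """Whole-network parameter totals reproduce the published counts."""

    def test_half_unet(self):
        report = count_network(build("half-unet"))
        # 207,329 learnable weights/biases plus 2 per batchnorm channel
        assert report.total_params == 207_329 + 1_536 == 208_865
        assert report.params_str("M") == "0.21 M"

    def test_half_unet_dagger(self):
        report = count_network(build("half-unet-dagger"))
        assert report.total_params == 408_449
        assert report.params_str("M") == "0.41 M"

    def test_unet(self):
        report = count_network(build("unet"))
        assert report.total_params == 31_042_369
        assert report.params_str("M") == "31.04 M"

    def test_star_variant_ordering(self):
        u = count_network(build("half-unet-star-u"))
        d = count_network(build("half-unet-star-d"))
        dag = count_network(build("half-unet-dagger"))
        assert d.total_params > u.total_params > dag.total_params
        assert u.total_flops > dag.total_flops  # _u trades params for FLOPs
        assert d.total_flops < u.total_flops


class TestGraphs:
    @pytest.mark.parametrize("name", builder_names())
    def test_validates_and_runs_forward(self, name, tiny_cfg, rng):
        net = build(name, tiny_cfg)
        net.validate()
        x = rng.random((2, 1, 16, 16), dtype=np.float32)
        out = Model(net, seed=0).forward(x)
        assert out.shape == (2, 1, 16, 16)
        assert np.all((out > 0) & (out < 1))

    def test_dagger_preserves_all_tensor_shapes(self, tiny_cfg):
        ghost = build("half-unet", tiny_cfg).infer_shapes()
        plain = build("half-unet-dagger", tiny_cfg).infer_shapes()
        assert ghost == plain

    def test_star_encoder_channel_doubling(self):
        shapes = build("half-unet-star-u").infer_shapes()
        seq = [shapes[f"enc{i}_c2"][0] for i in range(1, 6)]
        assert seq == [64, 128, 256, 512, 1024]

    def test_half_unet_taps_five_scales(self):
        shapes = build("half-unet").infer_shapes()
        sizes = [shapes[f"enc{i}_b2"][1] for i in range(1, 6)]
        assert sizes == [128, 64, 32, 16, 8]


class TestUNet3Plus:
    def test_last_fusion_channel_arithmetic(self):
        net = build("unet3plus")
        shapes = net.infer_shapes()
        taps = [shapes[f"enc{i}_c2"][0] for i in range(1, 6)]
        assert sum(taps) == 1_984  # 64+128+256+512+1024
        assert shapes["dec_r1_cat"][0] == 320  # 5 scales x 64 channels

    def test_every_decoder_layer_aggregates_to_320(self):
        shapes = build("unet3plus").infer_shapes()
        for rate in (1, 2, 4, 8):
            assert shapes[f"dec_r{rate}_agg"][0] == 320

    def test_aggregation_conv_formula(self):
        assert conv_params(ConvSpec(3, 320, 320)) == 921_920


class TestAblationEncoders:
    def test_variant_a_emits_five_scale_taps(self):
        shapes = build("encoder-a").infer_shapes()
        rates = [128 // shapes[f"enc{i}_c2"][1] for i in range(1, 6)]
        assert rates == [1, 2, 4, 8, 16]

    def test_variant_c_contains_variant_a_encoder(self, tiny_cfg):
        a = build("encoder-a", tiny_cfg)
        c = build("encoder-c", tiny_cfg)
        c_nodes = {(n.name, n.kind, tuple(sorted(n.cfg.items()))) for n in c.nodes}
        for n in a.nodes:
            if n.name.startswith("enc") or n.name == "in":
                assert (n.name, n.kind, tuple(sorted(n.cfg.items()))) in c_nodes

    def test_unknown_variant_rejected(self):
        from halfunet.architectures import build_ablation_encoder

        with pytest.raises(UnsupportedConfigError):
            build_ablation_encoder("D")

    def test_variant_b_taps_all_rates(self, tiny_cfg):
        # decoder-as-encoder still produces one tap per scale
        net = build("encoder-b", tiny_cfg)
        net.validate()


class TestLastFusionExtraction:
    def test_half_unet_left_is_parameter_free(self):
        left, right = extract_last_fusion(build("half-unet"))
        lr = count_network(left, (1, 128, 128))
        assert lr.total_params == 0 and lr.total_flops == 0
        rr = count_network(right, (1, 128, 128))
        assert rr.params_str("M") == "0.02 M"
        assert rr.flops_str("G") == "0.61 G"

    def test_unet_left_is_one_deconv(self):
        left, right = extract_last_fusion(build("unet"))
        kinds = [n.kind for n in left.nodes if n.kind not in ("input",)]
        assert sorted(kinds) == ["concat", "deconv"]
        deconv = next(n for n in left.nodes if n.kind == "deconv")
        assert (deconv.cfg["cin"], deconv.cfg["cout"], deconv.cfg["k"]) == (128, 64, 2)
        assert count_network(left, (1, 128, 128)).total_params == 32_832

    def test_unet3plus_right_is_320_aggregation_conv(self):
        left, right = extract_last_fusion(build("unet3plus"))
        (conv,) = [n for n in right.nodes if n.kind == "conv"]
        assert (conv.cfg["cin"], conv.cfg["cout"], conv.cfg["k"]) == (320, 320, 3)

    def test_untagged_network_raises(self):
        net = build("encoder-b")
        # encoder-b head is tagged, so use a bare graph instead
        from halfunet.architectures import NetworkSpec

        bare = NetworkSpec("bare", (1, 8, 8))
        bare.add("in", "input", channels=1)
        bare.add("c", "conv", "in", k=1, cin=1, cout=1, bias=True,
                 batchnorm=False, relu=False)
        with pytest.raises(ValueError):
            extract_last_fusion(bare)


class TestConfigValidation:
    def test_depth_and_width_bounds(self):
        with pytest.raises(UnsupportedConfigError):
            ArchitectureConfig(depth=1)
        with pytest.raises(UnsupportedConfigError):
            ArchitectureConfig(base_channels=0)

    def test_unknown_architecture_name(self):
        with pytest.raises(KeyError):
            build("no-such-net")
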