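"""Architecture contracts: sizes, topology, parameter counts, determinism."""

import numpy as np
import pytest

import dermcad as dc
from dermcad import nn
from dermcad.models import min_input_side, nested_node_graph, node_input_count, \
    output_side, unet_node_graph


class TestSizeArithmetic:
    def test_published_170_to_128_contract(self):
        assert output_side(dc.SegNetConfig(), 170) == 128

    def test_valid_forward_pass_shape(self, tiny_segnet_cfg):
        net = dc.build_unet(tiny_segnet_cfg, seed=0)
        with nn.no_grad():
            y = net.forward(np.zeros((1, 3, 170, 170), dtype=np.float32))
        assert y.data.shape == (1, 2, 128, 128)

    @pytest.mark.parametrize("side", [64, 96, 128])
    def test_same_padding_preserves_size(self, side):
        cfg = dc.SegNetConfig(base_features=4, padding_mode="same")
        net = dc.build_unet(cfg, seed=0)
        with nn.no_grad():
            y = net.forward(np.zeros((1, 3, side, side), dtype=np.float32))
        assert y.data.shape[-2:] == (side, side)

    def test_too_small_input_names_minimal_side(self, tiny_segnet_cfg):
        net = dc.build_unet(tiny_segnet_cfg, seed=0)
        minimal = min_input_side(tiny_segnet_cfg)
        with pytest.raises(dc.SizeError, match=str(minimal)):
            net.forward(np.zeros((1, 3, 16, 16), dtype=np.float32))
        assert output_side(tiny_segnet_cfg, minimal) >= 1

    def test_zero_initialized_net_outputs_constant_map(self, tiny_segnet_cfg):
        net = dc.build_unet(tiny_segnet_cfg, seed=0)
        net.zero_()
        with nn.no_grad():
            y = net.forward(np.zeros((1, 3, 170, 170), dtype=np.float32))
        assert np.all(y.data == y.data.flat[0])


class TestNestedTopology:
    def test_fan_in_rule(self):
        assert node_input_count(0, 0) == 1
        assert node_input_count(2, 0) == 1
        assert node_input_count(0, 1) == 2
        assert node_input_count(1, 3) == 4

    @pytest.mark.parametrize("depth", [1, 2, 3, 4])
    def test_graph_fan_in_matches_rule_at_every_node(self, depth):
        graph = nested_node_graph(depth)
        for (i, j), inputs in graph.items():
            assert len(inputs) == node_input_count(i, j)

    @pytest.mark.parametrize("depth", [1, 2, 3, 4])
    def test_total_node_count(self, depth):
        expected = sum(depth - i + 1 for i in range(depth + 1))
        assert len(nested_node_graph(depth)) == expected

    def test_depth_one_nested_reduces_to_plain_unet(self):
        assert nested_node_graph(1) == unet_node_graph(1)

    def test_deeper_nested_strictly_extends_plain_unet(self):
        nested = nested_node_graph(3)
        plain = unet_node_graph(3)
        assert set(plain) < set(nested) | {(i, 1) for i in range(3)}
        # the encoder backbone is identical
        for i in range(4):
            assert nested[(i, 0)] == plain[(i, 0)]

    def test_dense_block_bridges_to_encoder(self):
        # the full-resolution node at j=3 sees all three same-level
        # predecessors, including the raw encoder node (0,0)
        graph = nested_node_graph(3)
        assert (0, 0) in graph[(0, 3)]
        assert graph[(0, 3)] == [(0, 0), (0, 1), (0, 2), (1, 2)]

    def test_constructed_network_realizes_graph(self):
        cfg = dc.SegNetConfig(depth=2, base_features=4, padding_mode="same",
                              nested=True, deep_supervision=True)
        net = dc.build_nested_unet(cfg, seed=0)
        assert set(net.blocks) == set(nested_node_graph(2))
        with nn.no_grad():
            heads = net.forward_heads(np.zeros((1, 3, 32, 32), dtype=np.float32))
        assert len(heads) == 2  # one per full-resolution node j >= 1
        assert all(h.data.shape == (1, 2, 32, 32) for h in heads)

    def test_indivisible_side_rejected(self):
        cfg = dc.SegNetConfig(depth=2, base_features=4, padding_mode="same",
                              nested=True)
        net = dc.build_nested_unet(cfg, seed=0)
        with pytest.raises(dc.SizeError):
            net.forward(np.zeros((1, 3, 33, 33), dtype=np.float32))


class TestClassifier:
    def test_probabilities_sum_to_one(self, rng):
        cfg = dc.ClassifierConfig(kernels_per_layer=4)
        clf = dc.build_classifier(cfg, seed=0)
        x = rng.random((2, 3, 32, 32)).astype(np.float32)
        p = clf.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_initialized_net_is_indifferent(self):
        clf = dc.build_classifier(dc.ClassifierConfig(kernels_per_layer=4), seed=0)
        clf.zero_()
        p = clf.predict_proba(np.zeros((1, 3, 32, 32), dtype=np.float32))
        np.testing.assert_allclose(p, 0.5)

    def test_parameter_count_matches_hand_count(self):
        k, layers = 8, 4
        cfg = dc.ClassifierConfig(conv_layers=layers, kernels_per_layer=k)
        clf = dc.build_classifier(cfg, seed=0)
        conv = k * (3 * 9 + 1) + (layers - 1) * k * (k * 9 + 1)
        bn = 2 * k * layers
        head = k * 2 + 2
        assert clf.param_count() == conv + bn + head

    def test_too_small_input_rejected(self):
        clf = dc.build_classifier(dc.ClassifierConfig(kernels_per_layer=4), seed=0)
        with pytest.raises(dc.SizeError):
            clf.forward(np.zeros((1, 3, 8, 8), dtype=np.float32))


class TestDeterminismAndPersistence:
    def test_same_seed_same_parameters(self, tiny_segnet_cfg):
        a = dc.build_unet(tiny_segnet_cfg, seed=5)
        b = dc.build_unet(tiny_segnet_cfg, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_different_seed_different_parameters(self, tiny_segnet_cfg):
        a = dc.build_unet(tiny_segnet_cfg, seed=5)
        b = dc.build_unet(tiny_segnet_cfg, seed=6)
        assert any(not np.array_equal(pa.data, pb.data)
                   for pa, pb in zip(a.parameters(), b.parameters()))

    def test_checkpoint_roundtrip(self, tmp_path, tiny_segnet_cfg, rng):
        net = dc.build_unet(tiny_segnet_cfg, seed=3)
        path = tmp_path / "seg.npz"
        dc.save_model(net, path)
        reloaded = dc.load_model(path)
        x = rng.random((1, 3, 170, 170)).astype(np.float32)
        with nn.no_grad():
            np.testing.assert_array_equal(net.forward(x).data,
                                          reloaded.forward(x).data)

    def test_classifier_checkpoint_keeps_running_stats(self, tmp_path, rng):
        clf = dc.build_classifier(dc.ClassifierConfig(kernels_per_layer=4), seed=0)
        # push the running stats away from their init
        clf.forward(rng.random((4, 3, 16, 16)).astype(np.float32), training=True)
        path = tmp_path / "clf.npz"
        dc.save_model(clf, path)
        reloaded = dc.load_model(path)
        x = rng.random((2, 3, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(clf.predict_proba(x),
                                      reloaded.predict_proba(x))

    def test_summary_lists_every_stage(self, tiny_segnet_cfg):
        text = dc.model_summary(dc.build_unet(tiny_segnet_cfg, seed=0))
        assert "bottleneck" in text and "head" in text and "params" in text
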