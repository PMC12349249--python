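"""Network building blocks: SE attention, residual blocks, GRU gates,
embedding shape contract, and the three few-shot heads."""

import numpy as np
import pytest
from scipy.special import expit

from relnose import autodiff as ad
from relnose.autodiff import Tensor, sum_
from relnose.nets import (EmbeddingConfig, EmbeddingNet, GRUCell, HeadConfig,
                          ProtoFewShot, Recurrent, ResidualBlock, SEBlock,
                          SERelationNet, SiameseFewShot, bigru_layer,
                          build_model, class_feature, gru_direction,
                          load_checkpoint, merge_features, proto_probabilities,
                          save_checkpoint)


class TestLeakyRelu:
    @pytest.mark.parametrize("x,expected", [(5.0, 5.0), (-10.0, -0.1), (0.0, 0.0)])
    def test_values(self, x, expected):
        assert ad.leaky_relu(Tensor(x), 0.01).data == pytest.approx(expected)


class TestSEBlock:
    def test_squeeze_of_constant_channel_is_that_constant(self, rng):
        block = SEBlock(4, ratio=2, rng=rng)
        x = Tensor(np.tile(np.array([1.0, 2.0, 3.0, 4.0])[None, :, None], (1, 1, 7)))
        z = ad.mean_(x, axis=2)
        np.testing.assert_allclose(z.data, [[1, 2, 3, 4]])

    def test_output_magnitude_never_exceeds_input(self, rng):
        block = SEBlock(6, ratio=3, rng=rng)
        x = Tensor(rng.normal(size=(3, 6, 11)))
        out = block(x)
        assert (np.abs(out.data) <= np.abs(x.data) + 1e-12).all()

    def test_saturated_excitation_approaches_identity(self, rng):
        block = SEBlock(4, ratio=2, rng=rng)
        block.fc2.weight.data = np.zeros_like(block.fc2.weight.data)
        block.fc2.bias.data = np.full_like(block.fc2.bias.data, 50.0)  # sigmoid ~ 1
        x = Tensor(rng.normal(size=(2, 4, 5)))
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-10)

    def test_bottleneck_width_is_ceil_channels_over_ratio(self, rng):
        assert SEBlock(30, 16, rng).fc1.weight.shape == (30, 2)
        assert SEBlock(3, 16, rng).fc1.weight.shape == (3, 1)


class TestResidualBlock:
    def _zero_f1(self, block):
        for conv in block.convs:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        for bn in block.norms:
            bn.beta.data[:] = 0.0
        block.se.fc1.weight.data[:] = 0.0
        block.se.fc2.weight.data[:] = 0.0

    def test_zeroed_f1_reduces_to_skip_path(self, rng):
        block = ResidualBlock(5, f1_convs=2, se_ratio=2, leaky_slope=0.01,
                              batch_norm=False, rng=rng)
        self._zero_f1(block)
        x = Tensor(rng.normal(size=(2, 5, 9)))
        skip_only = block.skip(x)
        np.testing.assert_allclose(block(x, train=False).data, skip_only.data,
                                   atol=1e-12)

    def test_output_shape_preserved(self, rng):
        block = ResidualBlock(5, 3, 2, 0.01, True, rng)
        x = Tensor(rng.normal(size=(2, 5, 9)))
        assert block(x, train=True).shape == (2, 5, 9)

    def test_gradient_flows_through_skip_when_f1_is_dead(self, rng):
        block = ResidualBlock(4, 2, 2, 0.01, False, rng)
        self._zero_f1(block)
        x = Tensor(rng.normal(size=(1, 4, 6)), requires_grad=True)
        sum_(block(x, train=False)).backward()
        assert np.abs(x.grad).max() > 0


class TestGRU:
    def _direct_oracle(self, x, cell, h0=None):
        """Gate recursion written out directly in numpy."""
        B, T, _ = x.shape
        h = np.zeros((B, cell.hidden)) if h0 is None else np.array(h0, float)
        out = []
        for t in range(T):
            xt = x[:, t, :]
            r = expit(xt @ cell.Wr.data + h @ cell.Ur.data + cell.br.data)
            z = expit(xt @ cell.Wz.data + h @ cell.Uz.data + cell.bz.data)
            hc = np.tanh(xt @ cell.Wh.data + (r * h) @ cell.Uh.data + cell.bh.data)
            h = z * h + (1 - z) * hc
            out.append(h)
        return np.stack(out, axis=1)

    def test_matches_direct_gate_equations(self, rng):
        cell = GRUCell(4, 3, rng)
        x = rng.normal(size=(2, 6, 4))
        np.testing.assert_allclose(bigru_layer(x, cell), self._direct_oracle(x, cell),
                                   atol=1e-6)

    def test_fused_scan_equals_step_loop(self, rng):
        cell = GRUCell(5, 4, rng)
        x = Tensor(rng.normal(size=(3, 8, 5)))
        fused = gru_direction(x, cell).data
        np.testing.assert_allclose(fused, self._direct_oracle(x.data, cell),
                                   atol=1e-10)

    def test_zero_parameters_halve_initial_state_each_step(self, rng):
        # r = z = sigmoid(0) = 1/2 and candidate tanh(0) = 0, so h_t = h_0 / 2^t
        cell = GRUCell(3, 2, rng)
        for p in cell.parameters():
            p.data[:] = 0.0
        h0 = np.array([[1.0, -2.0]])
        x = rng.normal(size=(1, 5, 3))
        out = bigru_layer(x, cell, h0=h0)
        for t in range(5):
            np.testing.assert_allclose(out[0, t], h0[0] / 2 ** (t + 1), atol=1e-12)

    def test_bidirectional_final_state_concatenates_directions(self, rng):
        layer = Recurrent(4, 3, rng, kind="bigru")
        x = Tensor(rng.normal(size=(2, 6, 4)))
        seq, final = layer(x)
        assert seq.shape == (2, 6, 6)
        assert final.shape == (2, 6)
        np.testing.assert_allclose(final.data[:, :3], seq.data[:, -1, :3])
        np.testing.assert_allclose(final.data[:, 3:], seq.data[:, 0, 3:])

    @pytest.mark.parametrize("kind", ["gru", "rnn", "lstm", "bilstm", "birnn"])
    def test_ablation_cell_kinds_run(self, kind, rng):
        layer = Recurrent(4, 3, rng, kind=kind)
        seq, final = layer(Tensor(rng.normal(size=(2, 5, 4))))
        dirs = 2 if kind.startswith("bi") else 1
        assert final.shape == (2, 3 * dirs)
        assert np.isfinite(seq.data).all()


class TestEmbedding:
    def test_default_shape_contract(self, rng):
        net = EmbeddingNet(EmbeddingConfig(), rng)
        out = net(Tensor(np.zeros((2, 8, 240))), train=False)
        assert out.shape == (2, 30, 63)

    @pytest.mark.parametrize("blocks", [2, 3, 4, 5, 6])
    def test_contract_holds_for_any_block_count(self, blocks, rng):
        cfg = EmbeddingConfig(n_residual_blocks=blocks)
        net = EmbeddingNet(cfg, rng)
        out = net(Tensor(np.zeros((1, 8, 240))), train=False)
        assert out.shape == (1, 30, 63)

    def test_eval_mode_is_deterministic(self, rng):
        net = EmbeddingNet(EmbeddingConfig(), rng)
        x = Tensor(rng.normal(size=(2, 8, 240)))
        np.testing.assert_array_equal(net(x, train=False).data,
                                      net(x, train=False).data)

    def test_unreachable_contract_rejected(self, rng):
        with pytest.raises(ValueError):
            EmbeddingNet(EmbeddingConfig(in_timesteps=30, out_timesteps=63), rng)


class TestFeatureOps:
    def test_class_feature_mean_and_identity(self, rng):
        maps = Tensor(np.stack([np.zeros((4, 6)), np.full((4, 6), 2.0)]))
        np.testing.assert_allclose(class_feature(maps, axis=0).data, 1.0)
        single = Tensor(rng.normal(size=(1, 4, 6)))
        np.testing.assert_allclose(class_feature(single, axis=0).data,
                                   single.data[0])

    def test_merge_order_and_asymmetry(self, rng):
        a = Tensor(rng.normal(size=(2, 3, 5)))
        b = Tensor(rng.normal(size=(2, 3, 5)))
        merged = merge_features(a, b)
        assert merged.shape == (2, 6, 5)
        np.testing.assert_array_equal(merged.data[:, 0], a.data[:, 0])
        assert not np.array_equal(merge_features(a, b).data,
                                  merge_features(b, a).data)

    def test_merge_rejects_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            merge_features(Tensor(np.zeros((1, 3, 5))), Tensor(np.zeros((1, 3, 6))))


@pytest.fixture(scope="module")
def episode_data():
    rng = np.random.default_rng(17)
    return rng.normal(size=(3, 2, 240, 8)), rng.normal(size=(5, 240, 8))


class TestHeads:

    def test_relation_scores_in_open_interval(self, episode_data):
        model = SERelationNet(rng=np.random.default_rng(0))
        sup, qry = episode_data
        scores = model.episode_scores(sup, qry).data
        assert scores.shape == (3, 5)
        assert ((scores > 0) & (scores < 1)).all()

    def test_relation_eval_deterministic(self, episode_data):
        model = SERelationNet(rng=np.random.default_rng(0))
        sup, qry = episode_data
        np.testing.assert_array_equal(model.episode_scores(sup, qry).data,
                                      model.episode_scores(sup, qry).data)

    def test_relation_score_sensitive_to_query(self, episode_data):
        model = SERelationNet(rng=np.random.default_rng(0))
        sup, qry = episode_data
        bumped = qry.copy()
        bumped[0] += 0.5
        a = model.episode_scores(sup, qry).data[:, 0]
        b = model.episode_scores(sup, bumped).data[:, 0]
        assert np.abs(a - b).max() > 1e-8

    def test_siamese_scores_and_support_permutation_invariance(self, episode_data):
        model = SiameseFewShot(rng=np.random.default_rng(0))
        sup, qry = episode_data
        scores = model.episode_scores(sup, qry).data
        assert ((scores > 0) & (scores < 1)).all()
        flipped = sup[:, ::-1].copy()   # permute the K support samples
        np.testing.assert_allclose(model.episode_scores(flipped, qry).data,
                                   scores, atol=1e-10)

    def test_proto_probabilities_sum_to_one(self, episode_data):
        model = ProtoFewShot(rng=np.random.default_rng(0))
        sup, qry = episode_data
        probs = model.episode_scores(sup, qry).data
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-9)

    def test_proto_probability_oracle(self, rng):
        protos = rng.normal(size=(4, 6))
        q = rng.normal(size=6)
        p = proto_probabilities(protos, q)
        d2 = ((protos - q) ** 2).sum(axis=1)
        expected = np.exp(-d2) / np.exp(-d2).sum()
        np.testing.assert_allclose(p, expected, atol=1e-12)
        assert p.sum() == pytest.approx(1.0)

    def test_proto_query_at_prototype_wins(self):
        protos = np.array([[0.0, 0.0], [10.0, 10.0], [-9.0, 4.0]])
        assert np.argmax(proto_probabilities(protos, np.array([10.0, 10.0]))) == 1

    def test_k_identical_supports_collapse_to_one_shot(self, episode_data):
        model = SERelationNet(rng=np.random.default_rng(0))
        sup, qry = episode_data
        sup1 = sup[:, :1]
        sup_k = np.repeat(sup1, 4, axis=1)
        np.testing.assert_allclose(model.episode_scores(sup_k, qry).data,
                                   model.episode_scores(sup1, qry).data,
                                   atol=1e-6)


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(4)
        model = build_model("relation", rng=rng)
        sup = rng.normal(size=(2, 1, 240, 8))
        qry = rng.normal(size=(3, 240, 8))
        before = model.episode_scores(sup, qry).data
        save_checkpoint(model, tmp_path / "ckpt.npz")
        loaded = load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_allclose(loaded.episode_scores(sup, qry).data, before,
                                   atol=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_model("nearest_centroid")
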