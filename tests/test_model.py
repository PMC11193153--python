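"""Network behavior: equivariance, masking, fusion, loss composition."""

import numpy as np
import pytest

import peptox.autodiff as ad
from peptox.autodiff import Tensor
from peptox.backbone import compute_dihedrals, impute_cbeta
from peptox.graphs import featurize_graph
from peptox.model import ToxicityModel, compute_loss
from peptox.simulate import make_structure_preset
from peptox.train import collate, prepare_samples
from conftest import random_rotation


@pytest.fixture(scope="module")
def model(small_config):
    return ToxicityModel(small_config)


def graph_for(kind="coil", n=10, seed=0, d_max=10.0, transform=None):
    s = impute_cbeta(make_structure_preset(kind, n, seed=seed))
    if transform is not None:
        s = s.transformed(*transform)
    return featurize_graph(s, compute_dihedrals(s), d_max=d_max)


class TestGVPLayer:
    def test_rotation_equivariance(self, model):
        rng = np.random.default_rng(0)
        R = random_rotation(rng)
        s = Tensor(rng.normal(size=(7, 6)))
        v = rng.normal(size=(7, 3, 3))
        s1, v1 = model.gvp_layer("gnn.embed", s, Tensor(v))
        s2, v2 = model.gvp_layer("gnn.embed", s, Tensor(v @ R.T))
        np.testing.assert_allclose(s1.data, s2.data, atol=1e-6)
        np.testing.assert_allclose(v1.data @ R.T, v2.data, atol=1e-5)

    def test_zero_vectors_contribute_exact_zero_norms(self, model):
        rng = np.random.default_rng(1)
        s = rng.normal(size=(4, 6))
        _, _ = model.gvp_layer("gnn.embed", Tensor(s),
                               Tensor(np.zeros((4, 3, 3))))
        # with zero vectors the scalar path must equal W_s [s ; 0] + b
        P = model.params
        hv = P["gnn.embed.Wh"].shape[1]
        manual = np.concatenate([s, np.zeros((4, hv))], axis=1) \
            @ P["gnn.embed.Ws"].data + P["gnn.embed.bs"].data
        out_s, _ = model.gvp_layer("gnn.embed", Tensor(s),
                                   Tensor(np.zeros((4, 3, 3))))
        np.testing.assert_array_equal(out_s.data, np.maximum(manual, 0.0))

    def test_output_channel_counts(self, model):
        c = model.config
        rng = np.random.default_rng(2)
        s, v = model.gvp_layer(
            "gnn.embed", Tensor(rng.normal(size=(5, 6))),
            Tensor(rng.normal(size=(5, 3, 3)))
        )
        assert s.shape == (5, c.d_h)
        assert v.shape == (5, c.n_vector_channels, 3)


class TestGNNForward:
    def test_permutation_equivariance(self, model):
        g = graph_for(kind="coil", n=8, seed=3)
        rng = np.random.default_rng(4)
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        import copy

        gp = copy.deepcopy(g)
        gp.node_scalars = g.node_scalars[perm]
        gp.node_vectors = g.node_vectors[perm]
        gp.edge_index = inv[g.edge_index]
        _, h = model.gnn_forward([g])
        _, hp = model.gnn_forward([gp])
        np.testing.assert_allclose(hp.data, h.data[perm], atol=1e-9)

    def test_edgeless_graph_still_updates(self, model):
        g = graph_for(kind="strand", n=4, seed=5, d_max=1.0)
        assert len(g.edge_index) == 0
        dense, h = model.gnn_forward([g])
        assert np.all(np.isfinite(h.data))
        assert np.any(h.data != 0.0)

    def test_rotation_invariance_of_scalar_readout(self, model):
        rng = np.random.default_rng(6)
        R, t = random_rotation(rng), rng.normal(size=3) * 30
        g0 = graph_for(kind="helix", n=12, seed=7)
        g1 = graph_for(kind="helix", n=12, seed=7, transform=(R, t))
        _, h0 = model.gnn_forward([g0])
        _, h1 = model.gnn_forward([g1])
        np.testing.assert_allclose(h0.data, h1.data, atol=1e-5)


class TestGRUForward:
    def test_padding_independence(self, model):
        c = model.config
        rng = np.random.default_rng(8)
        x_short = np.zeros((1, c.L_max, c.d_input))
        x_short[0, :5] = rng.normal(size=(5, c.d_input))
        x_long = np.zeros((1, c.L_max, c.d_input))
        x_long[0, :15] = rng.normal(size=(15, c.d_input))
        x_long[0, :5] = x_short[0, :5]
        # same first five rows, different batch max length
        alone = model.gru_forward(x_short, np.array([5]))
        joint = model.gru_forward(np.concatenate([x_short, x_long]),
                                  np.array([5, 15]))
        np.testing.assert_allclose(alone.data[0, :5], joint.data[0, :5],
                                   atol=1e-6)
        assert np.all(joint.data[0, 5:] == 0.0)

    def test_width_split_between_directions(self, model):
        c = model.config
        x = np.random.default_rng(9).normal(size=(2, c.L_max, c.d_input))
        out = model.gru_forward(x, np.array([c.L_max, 4]))
        assert out.shape == (2, c.L_max, c.d_h)
        assert model.params["gru.l0.fw.U"].shape[0] == c.d_h // 2

    def test_deterministic(self, model):
        c = model.config
        x = np.random.default_rng(10).normal(size=(1, c.L_max, c.d_input))
        a = model.gru_forward(x, np.array([7]))
        b = model.gru_forward(x, np.array([7]))
        np.testing.assert_array_equal(a.data, b.data)


class TestAttentionFuse:
    def _fused(self, model, lengths, seed=11):
        c = model.config
        rng = np.random.default_rng(seed)
        B = len(lengths)
        mask = (np.arange(c.L_max)[None, :] < np.array(lengths)[:, None])
        h_seq = rng.normal(size=(B, c.L_max, c.d_h)) * mask[:, :, None]
        h_strct = rng.normal(size=(B, c.L_max, c.d_h)) * mask[:, :, None]
        return model.attention_fuse(Tensor(h_seq), Tensor(h_strct),
                                    np.array(lengths))

    def test_rows_sum_to_one_over_unmasked(self, model):
        fused = self._fused(model, [6, 13])
        for b, L in enumerate(fused.lengths):
            rows = fused.attention[b, :, :L, :].sum(axis=-1)
            np.testing.assert_allclose(rows, 1.0, atol=1e-6)

    def test_padded_keys_get_zero_weight(self, model):
        fused = self._fused(model, [6, 13])
        for b, L in enumerate(fused.lengths):
            assert np.all(fused.attention[b, :, :, L:] == 0.0)

    def test_singleton_softmax(self, model):
        fused = self._fused(model, [1])
        assert fused.attention[0, :, 0, 0] == pytest.approx(1.0)

    def test_fused_width(self, model):
        fused = self._fused(model, [5])
        assert fused.h_pep.shape[-1] == 2 * model.config.d_h
        assert fused.h_prime.shape == fused.h_pep.shape


class TestHeadsAndLoss:
    def test_classifier_probability_and_strict_threshold(self, model):
        fused = TestAttentionFuse()._fused(model, [4, 9])
        p, labels = model.classify(fused, np.array([0.0, 1.0]))
        assert np.all((p.data >= 0) & (p.data <= 1))
        assert all(
            lab == ("toxic" if prob > 0.5 else "nontoxic")
            for lab, prob in zip(labels, p.data)
        )

    def test_amidation_flag_changes_output(self, model):
        fused = TestAttentionFuse()._fused(model, [4])
        p0, _ = model.classify(fused, np.array([0.0]))
        p1, _ = model.classify(fused, np.array([1.0]))
        assert p0.data[0] != p1.data[0]

    def test_ss_head_shape_and_normalization(self, model):
        fused = TestAttentionFuse()._fused(model, [4])
        scores = model.ss_head(fused)
        assert scores.shape == (1, model.config.L_max, 8)
        probs = ad.softmax(scores, axis=-1)
        np.testing.assert_allclose(probs.data.sum(axis=-1), 1.0, atol=1e-9)

    def test_padded_positions_excluded_from_ss_loss(self, model):
        rng = np.random.default_rng(12)
        p = Tensor(np.array([0.7]))
        scores = Tensor(rng.normal(size=(1, 6, 8)))
        labels = np.array([[0, 3, 7, -1, -1, -1]])
        base = compute_loss(p, [1], scores, labels, lambda_ss=0.5)
        perturbed = scores.data.copy()
        perturbed[0, 3:] = rng.normal(size=(3, 8)) * 50
        after = compute_loss(p, [1], Tensor(perturbed), labels, lambda_ss=0.5)
        assert base.data == pytest.approx(after.data, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_loss_limits(self, lam):
        p = Tensor(np.array([0.8, 0.3]))
        y = np.array([1, 0])
        scores = Tensor(np.log(np.full((2, 3, 8), 0.125)))
        labels = np.array([[0, 1, -1], [7, -1, -1]])
        ltx = -np.mean([np.log(0.8), np.log(0.7)])
        lss = -np.log(0.125)
        expected = (1 - lam) * ltx + lam * lss
        got = compute_loss(p, y, scores, labels, lambda_ss=lam)
        assert got.data == pytest.approx(expected, rel=1e-9)

    def test_perfect_predictions_give_vanishing_loss(self):
        p = Tensor(np.array([1.0, 0.0]))
        y = np.array([1, 0])
        scores = np.full((2, 2, 8), -50.0)
        scores[0, :, 2] = 50.0
        scores[1, :, 5] = 50.0
        labels = np.array([[2, 2], [5, 5]])
        loss = compute_loss(p, y, Tensor(scores), labels, lambda_ss=0.5)
        assert loss.data < 1e-6

    def test_lambda_zero_ignores_ss_parameters(self):
        p = Tensor(np.array([0.6]), requires_grad=True)
        scores = Tensor(np.random.default_rng(0).normal(size=(1, 3, 8)),
                        requires_grad=True)
        loss = compute_loss(p, [1], scores, np.array([[0, 1, 2]]),
                            lambda_ss=0.0)
        loss.backward()
        assert scores.grad is None


class TestEndToEnd:
    def test_rigid_motion_invariance_of_probability(
        self, small_config, small_dataset
    ):
        model = ToxicityModel(small_config)
        samples = prepare_samples(small_dataset[:3], small_config)
        rng = np.random.default_rng(13)
        R, t = random_rotation(rng), rng.normal(size=3) * 40
        batch = collate(samples[:3], small_config.L_max)
        p0 = model.forward(batch)["p_toxic"].data
        import dataclasses

        moved_records = [
            dataclasses.replace(rec, structures=[
                s.transformed(R, t) for s in rec.structures
            ], ss_labels=rec.ss_labels)
            for rec in small_dataset[:3]
        ]
        batch_m = collate(prepare_samples(moved_records, small_config)[:3],
                          small_config.L_max)
        p1 = model.forward(batch_m)["p_toxic"].data
        np.testing.assert_allclose(p0, p1, atol=1e-5)

    def test_dropout_off_is_deterministic(self, small_model_and_batch):
        model, batch = small_model_and_batch
        a = model.forward(batch)["p_toxic"].data
        b = model.forward(batch)["p_toxic"].data
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip_bit_exact(self, tmp_path,
                                             small_model_and_batch):
        model, batch = small_model_and_batch
        model.save(tmp_path / "ckpt")
        loaded = ToxicityModel.load(tmp_path / "ckpt")
        for k, p in model.params.items():
            np.testing.assert_array_equal(p.data, loaded.params[k].data)
        np.testing.assert_array_equal(
            model.forward(batch)["p_toxic"].data,
            loaded.forward(batch)["p_toxic"].data,
        )
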