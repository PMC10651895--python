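"""SNN-VAE: latent sampling, loss algebra, semi-hard mining, branch
fusion, encoder/decoder contracts and a seeded optimization smoke test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from splinesound.model import (
    EncoderConfig,
    LatentDistribution,
    MiningError,
    SNNVAE,
    classify,
    fuse_branches,
    kl_divergence,
    mine_semi_hard,
    reconstruction_loss,
    sample_latent,
    total_loss,
    triplet_loss,
)
from splinesound.nn import RepVGGBlock
from splinesound.train_eval import TrainConfig, train_on_features

TINY = EncoderConfig(image_size=32, latent_dim=16, stage_widths=(4, 8, 16))


class TestLatentSampling:
    def test_zero_noise_returns_mean(self):
        d = LatentDistribution(mean=np.array([1.0, -2.0]), variance=np.array([4.0, 9.0]))
        assert np.array_equal(sample_latent(d, eps=np.zeros(2)), d.mean)

    def test_hand_case(self):
        d = LatentDistribution(mean=np.array([1.0, 1.0]), variance=np.array([4.0, 4.0]))
        z = sample_latent(d, eps=np.array([1.0, -1.0]))
        assert np.allclose(z, [3.0, -1.0])

    def test_vanishing_variance_collapses_to_mean(self):
        d = LatentDistribution(mean=np.array([2.0]), variance=np.array([1e-12]))
        assert sample_latent(d, eps=np.array([5.0]))[0] == pytest.approx(2.0, abs=1e-5)

    def test_reparameterization_statistics(self):
        """Sample mean/variance over 1e5 draws match (E(z), V(z))
        within three standard errors."""
        mean = np.array([0.5, -1.0, 2.0])
        var = np.array([0.25, 1.0, 4.0])
        d = LatentDistribution(mean=mean, variance=var)
        n = 100_000
        rng = np.random.default_rng(42)
        z = np.stack([sample_latent(d, eps=e) for e in rng.standard_normal((n, 3))])
        se_mean = np.sqrt(var / n)
        assert np.all(np.abs(z.mean(axis=0) - mean) < 3 * se_mean)
        se_var = var * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(z.var(axis=0) - var) < 3 * se_var)


class TestKLDivergence:
    def test_standard_normal_is_zero(self):
        d = LatentDistribution(mean=np.zeros(5), variance=np.ones(5))
        assert kl_divergence(d) == pytest.approx(0.0)

    def test_hand_cases(self):
        d1 = LatentDistribution(mean=np.array([1.0]), variance=np.array([1.0]))
        assert kl_divergence(d1) == pytest.approx(0.5)
        d2 = LatentDistribution(mean=np.array([0.0]), variance=np.array([2.0]))
        assert kl_divergence(d2) == pytest.approx(0.5 * (2 - np.log(2) - 1), abs=1e-6)
        assert kl_divergence(d2) == pytest.approx(0.1534, abs=1e-4)

    @given(
        mean=st.lists(st.floats(-5, 5), min_size=1, max_size=8),
        logv=st.lists(st.floats(-3, 3), min_size=1, max_size=8),
    )
    def test_nonnegative_everywhere(self, mean, logv):
        d = min(len(mean), len(logv))
        dist = LatentDistribution(
            mean=np.array(mean[:d]), variance=np.exp(np.array(logv[:d]))
        )
        assert kl_divergence(dist) >= -1e-12

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            LatentDistribution(mean=np.zeros(2), variance=np.array([1.0, 0.0]))


class TestLossAlgebra:
    def test_reconstruction_cases(self, rng):
        x = np.zeros((4, 4, 3))
        assert reconstruction_loss(x, x) == 0.0
        assert reconstruction_loss(x, np.ones_like(x)) == pytest.approx(1.0)
        a, b = rng.random((2, 5, 5)), rng.random((2, 5, 5))
        assert reconstruction_loss(a, b) == pytest.approx(reconstruction_loss(b, a))

    def test_triplet_hand_cases(self):
        v = np.array([[0.0, 0.0]])
        # equal embeddings -> loss alpha per triplet
        assert triplet_loss(v, v, v, alpha=0.3) == pytest.approx(0.3)
        # satisfied margin -> 0
        fP = v.copy()
        fN = np.array([[np.sqrt(1.2), 0.0]])  # d_an = 1.2 > 0 + alpha
        assert triplet_loss(v, fP, fN, alpha=0.2) == 0.0
        # d_ap = 1, d_an = 0.5, alpha = 0.2 -> 0.7
        fP = np.array([[1.0, 0.0]])
        fN = np.array([[np.sqrt(0.5), 0.0]])
        assert triplet_loss(v, fP, fN, alpha=0.2) == pytest.approx(0.7)

    def test_triplet_zero_whenever_margin_satisfied(self, rng):
        fA = rng.standard_normal((20, 4))
        fP = fA + 0.01 * rng.standard_normal((20, 4))
        fN = fA + 10.0 + rng.standard_normal((20, 4))
        d_ap = np.sum((fA - fP) ** 2, axis=1)
        d_an = np.sum((fA - fN) ** 2, axis=1)
        assert np.all(d_ap + 0.2 <= d_an)
        assert triplet_loss(fA, fP, fN, alpha=0.2) == 0.0

    def test_total_loss_additivity(self):
        lb = total_loss(triplet=0.7, reconstruction=0.1, kl=0.5, beta=1.0)
        assert lb.total == pytest.approx(1.3)
        lb0 = total_loss(triplet=0.7, reconstruction=0.1, kl=0.5, beta=0.0)
        assert lb0.total == pytest.approx(0.8)  # beta=0 removes the KL term
        z = total_loss(0.0, 0.0, 0.0)
        assert z.total == 0.0


class TestSemiHardMining:
    def test_window_negative_selected(self):
        emb = np.array([[0.0], [0.5], [0.6], [3.0]])
        labels = np.array(["a", "a", "b", "b"])
        batch = mine_semi_hard(emb, labels, alpha=1.0, seed=0)
        i = list(batch.anchors).index(0)
        # d(A,P)=0.25; d(A, 0.6)=0.36 in (0.25, 1.25); d(A, 3)=9 outside
        assert batch.positives[i] == 1
        assert batch.negatives[i] == 2

    def test_distant_classes_fall_back_to_hardest(self):
        emb = np.array([[0.0], [0.1], [100.0], [100.1]])
        labels = np.array(["a", "a", "b", "b"])
        batch = mine_semi_hard(emb, labels, alpha=0.2, seed=0)
        fA, fP, fN = emb[batch.anchors], emb[batch.positives], emb[batch.negatives]
        assert triplet_loss(fA, fP, fN, alpha=0.2) == 0.0

    def test_triplet_label_contract(self, rng):
        emb = rng.standard_normal((30, 5))
        labels = rng.choice(["a", "b", "c"], size=30)
        batch = mine_semi_hard(emb, labels, alpha=0.5, seed=1)
        for a, p, n in zip(batch.anchors, batch.positives, batch.negatives):
            assert labels[a] == labels[p] != labels[n]
            assert a != p

    def test_single_class_batch_raises(self, rng):
        emb = rng.standard_normal((6, 3))
        with pytest.raises(MiningError):
            mine_semi_hard(emb, np.array(["a"] * 6), alpha=0.2, seed=0)


class TestBranchFusion:
    def randomized_block(self, rng, in_c=4, out_c=4, stride=1):
        blk = RepVGGBlock(in_c, out_c, stride, rng=rng)
        bns = [blk.bn3, blk.bn1] + ([blk.bnid] if blk.bnid is not None else [])
        for bn in bns:
            bn.running_mean = rng.standard_normal(out_c) * 0.2
            bn.running_var = rng.random(out_c) + 0.5
            bn.params["gamma"] = rng.random(out_c) + 0.5
            bn.params["beta"] = rng.standard_normal(out_c) * 0.2
        return blk

    def test_fused_equals_multibranch_on_100_random_inputs(self, rng):
        for stride, in_c, out_c in ((1, 4, 4), (2, 3, 6)):
            blk = self.randomized_block(rng, in_c, out_c, stride)
            x = rng.standard_normal((100, in_c, 8, 8))
            before = blk.forward(x)
            fuse_branches(blk)
            after = blk.forward(x)
            assert np.max(np.abs(before - after)) < 1e-4

    def test_zero_conv_branches_fuse_to_identity(self, rng):
        blk = RepVGGBlock(3, 3, 1, rng=rng)
        blk.conv3.params["W"][...] = 0.0
        blk.conv1.params["W"][...] = 0.0
        blk.fuse()
        x = np.abs(rng.standard_normal((2, 3, 6, 6)))  # positive -> ReLU inert
        assert np.max(np.abs(blk.forward(x) - x)) < 1e-4

    def test_fusion_idempotent(self, rng):
        blk = self.randomized_block(rng)
        blk.fuse()
        w = blk.fused_conv.params["W"].copy()
        fuse_branches(blk)
        assert np.array_equal(blk.fused_conv.params["W"], w)


class TestEncoderDecoder:
    def test_default_embedding_length_is_128(self):
        model = SNNVAE(EncoderConfig(), seed=0)
        img = np.random.default_rng(0).random((3, 128, 128))
        dist = model.encode(img)
        assert dist.mean.shape == (128,)
        assert dist.variance.shape == (128,)
        assert np.all(dist.variance > 0)

    def test_encode_deterministic_at_inference(self, rng):
        model = SNNVAE(TINY, seed=0)
        img = rng.random((3, 32, 32))
        a, b = model.encode(img), model.encode(img)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.variance, b.variance)

    def test_decode_shape_range_determinism(self, rng):
        model = SNNVAE(TINY, seed=0)
        z = rng.standard_normal((2, 16))
        out = model.decode(z)
        assert out.shape == (2, 3, 32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert np.array_equal(out, model.decode(z))

    def test_shape_mismatch_rejected(self, rng):
        model = SNNVAE(TINY, seed=0)
        with pytest.raises(ValueError):
            model.encode(rng.random((3, 16, 16)))
        with pytest.raises(ValueError):
            model.decode(rng.standard_normal(5))

    def test_embed_is_latent_mean(self, rng):
        model = SNNVAE(TINY, seed=0)
        img = rng.random((3, 32, 32))
        assert np.array_equal(model.embed(img), model.encode(img).mean)

    def test_model_fusion_preserves_embeddings(self, rng):
        model = SNNVAE(TINY, seed=0)
        img = rng.random((3, 32, 32))
        before = model.embed(img)
        model.fuse()
        assert np.max(np.abs(model.embed(img) - before)) < 1e-4

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = SNNVAE(TINY, seed=3)
        img = rng.random((3, 32, 32))
        model.save(tmp_path / "ckpt.npz")
        back = SNNVAE.load(tmp_path / "ckpt.npz")
        assert np.array_equal(back.embed(img), model.embed(img))


class TestClassify:
    def test_centroid_match_and_tiebreak(self):
        cents = {"b": np.array([1.0, 0.0]), "a": np.array([-1.0, 0.0])}
        label, score = classify(np.array([1.0, 0.0]), cents)
        assert label == "b" and score > 0.5
        # equidistant -> first class name in sorted order
        label, _ = classify(np.array([0.0, 0.0]), cents)
        assert label == "a"

    def test_matches_exhaustive_distance_oracle(self, rng):
        cents = {f"c{i}": rng.standard_normal(8) for i in range(5)}
        for _ in range(20):
            e = rng.standard_normal(8)
            label, _ = classify(e, cents)
            oracle = min(cents, key=lambda k: np.linalg.norm(e - cents[k]))
            assert label == oracle

    def test_empty_centroids_rejected(self):
        with pytest.raises(RuntimeError):
            classify(np.zeros(3), {})


class TestOptimizationSmoke:
    def test_total_loss_decreases_over_training(self, rng):
        """Seeded descent: total loss drops on a fixed tiny batch."""
        X = rng.random((8, 3, 32, 32))
        y = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        # make the classes visually distinct
        X[:4, :, :16, :] *= 0.1
        model = SNNVAE(TINY, seed=0)
        cfg = TrainConfig(epochs=50, batch_size=8, lr=1e-3, seed=0)
        model, hist = train_on_features(model, X, y, cfg=cfg)
        assert hist["total"].iloc[-1] < hist["total"].iloc[0]
        # loss-breakdown identity holds row-wise
        assert np.allclose(
            hist["total"],
            hist["triplet"] + hist["reconstruction"] + cfg.beta * hist["kl"],
        )
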