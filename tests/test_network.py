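"""Architecture blocks: neighbor search oracles, symmetry properties, budgets."""

import dataclasses

import numpy as np
import pytest

from stemleaf3d.autodiff import Tensor
from stemleaf3d.network import (
    CAMSE,
    EAFPStage,
    GLSAStage,
    ModelConfig,
    PointSegNet,
    RSAAttention,
    ResMLPBlock,
    ball_query_knn,
    count_flops,
    count_parameters,
    interpolate_features,
    reference_config,
    tiny_config,
)


def _mini_config(**kw):
    base = dict(
        in_channels=6, num_classes=2, npoints=64, stem_width=8,
        stage_widths=(8, 12, 16, 24), decoder_widths=(16, 12, 8, 8),
        head_width=8, local_k=8, ball_radius=0.3, eafp_k=4,
    )
    base.update(kw)
    return ModelConfig(**base)


class TestBallQuery:
    def test_matches_bruteforce_sort_and_mask(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(64, 3))
            centers = pts[rng.choice(64, 16, replace=False)]
            k, radius = 6, 0.9
            idx = ball_query_knn(centers, pts, k, radius)
            for c, row in zip(centers, idx):
                d = np.linalg.norm(pts - c, axis=1)
                order = np.argsort(d)
                within = order[d[order] <= radius][:k]
                expect = list(within)
                while len(expect) < k:
                    expect.append(order[0] if len(within) == 0 else within[0])
                got_d = np.sort(d[row])
                want_d = np.sort(d[np.array(expect)])
                assert np.allclose(got_d, want_d)

    def test_isolated_center_padded_with_self(self):
        pts = np.vstack([np.zeros((1, 3)), np.full((5, 3), 10.0)])
        idx = ball_query_knn(pts[:1], pts, k=4, radius=1.0)
        assert np.all(idx == 0)

    def test_exact_k_within_radius_sorted_by_distance(self):
        pts = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0], [5.0, 0, 0]])
        idx = ball_query_knn(np.zeros((1, 3)), pts, k=3, radius=1.0)
        assert list(idx[0]) == [0, 1, 2]


class TestResMLP:
    def test_neighbor_permutation_invariance(self, rng):
        block = ResMLPBlock(5, 7, rng)
        block.set_training(False)
        grouped = rng.normal(size=(1, 4, 6, 8)).astype(np.float32)
        centers = rng.normal(size=(1, 4, 5)).astype(np.float32)
        out1 = block(Tensor(grouped), Tensor(centers)).data
        perm = rng.permutation(6)
        out2 = block(Tensor(grouped[:, :, perm]), Tensor(centers)).data
        assert np.allclose(out1, out2, atol=1e-6)

    def test_zero_mlp_reduces_to_shortcut(self, rng):
        block = ResMLPBlock(5, 7, rng)
        block.set_training(False)
        block.conv1.weight.data *= 0
        block.conv2.weight.data *= 0
        block.bn1.beta.data *= 0
        block.bn2.beta.data *= 0
        grouped = rng.normal(size=(1, 4, 6, 8)).astype(np.float32)
        centers = rng.normal(size=(1, 4, 5)).astype(np.float32)
        out = block(Tensor(grouped), Tensor(centers)).data
        shortcut = block.shortcut(Tensor(centers)).data
        assert np.allclose(out, np.maximum(shortcut, 0.0), atol=1e-6)

    def test_output_width_contract(self, rng):
        for k in (1, 3, 9):
            block = ResMLPBlock(4, 11, rng)
            out = block(
                Tensor(rng.normal(size=(2, 5, k, 7)).astype(np.float32)),
                Tensor(rng.normal(size=(2, 5, 4)).astype(np.float32)),
            )
            assert out.shape == (2, 5, 11)


class TestRSA:
    def test_single_point_deviations_vanish(self, rng):
        pos = rng.normal(size=(1, 1, 3))
        assert np.allclose(pos - pos.mean(axis=1, keepdims=True), 0.0)

    def test_attention_weights_in_unit_interval(self, rng):
        rsa = RSAAttention(6, 8, rng)
        rsa.set_training(False)
        pos = rng.normal(size=(2, 10, 3))
        f = Tensor(rng.normal(size=(2, 10, 6)).astype(np.float32))
        P = Tensor((pos - pos.mean(axis=1, keepdims=True)).astype(np.float32))
        from stemleaf3d.autodiff import concat

        a = rsa.mlp1b(
            rsa.mlp1a(concat([P, f - f.mean(axis=1, keepdims=True)], axis=-1)).relu()
        ).sigmoid()
        assert np.all(a.data > 0) and np.all(a.data < 1)

    def test_permutation_equivariance(self, rng):
        rsa = RSAAttention(6, 8, rng)
        rsa.set_training(False)
        pos = rng.normal(size=(1, 12, 3))
        f = rng.normal(size=(1, 12, 6)).astype(np.float32)
        out1 = rsa(pos, Tensor(f)).data
        perm = rng.permutation(12)
        out2 = rsa(pos[:, perm], Tensor(f[:, perm])).data
        assert np.allclose(out1[:, perm], out2, atol=1e-5)


class TestCAMSE:
    def test_output_bounded_by_twice_input_for_nonnegative(self, rng):
        cam = CAMSE(6, rng)
        cam.set_training(False)
        f = np.abs(rng.normal(size=(2, 9, 6))).astype(np.float32)
        out = cam(Tensor(f)).data
        assert np.all(out >= f - 1e-6)
        assert np.all(out <= 2 * f + 1e-6)

    def test_constant_channel_sd_is_sqrt_eps(self, rng):
        cam = CAMSE(3, rng)
        f = Tensor(np.ones((1, 5, 3), dtype=np.float32))
        u = f.mean(axis=1)
        centered = f - u.reshape(1, 1, 3)
        sd = ((centered * centered).mean(axis=1) + cam.eps).sqrt()
        assert np.allclose(sd.data, np.sqrt(cam.eps))

    def test_gate_is_permutation_invariant(self, rng):
        cam = CAMSE(5, rng)
        cam.set_training(False)
        f = rng.normal(size=(1, 11, 5)).astype(np.float32)
        out1 = cam(Tensor(f)).data
        perm = rng.permutation(11)
        out2 = cam(Tensor(f[:, perm])).data
        assert np.allclose(out1[:, perm], out2, atol=1e-6)


class TestGLSA:
    def test_halves_point_count(self, rng):
        cfg = _mini_config()
        stage = GLSAStage(8, 12, cfg, 0, rng)
        stage.set_training(False)
        pos = rng.normal(size=(1, 64, 3))
        f = Tensor(rng.normal(size=(1, 64, 8)).astype(np.float32))
        new_pos, new_f = stage(pos, f)
        assert new_pos.shape == (1, 32, 3)
        assert new_f.shape == (1, 32, 12)

    def test_chained_downsampling_rate(self):
        cfg = tiny_config()
        model = PointSegNet(cfg, seed=0)
        model.set_training(False)
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(1, 512, 3))
        feats = rng.normal(size=(1, 512, 6)).astype(np.float32)
        f = model.stem_bn(model.stem(Tensor(feats))).relu()
        p = pos
        for stage in model.stages:
            p, f = stage(p, f)
        assert p.shape[1] == 512 // 16  # four halvings

    def test_rsa_off_uses_local_branch_only(self, rng):
        cfg = _mini_config(ablation={"rsa": False})
        stage = GLSAStage(8, 12, cfg, 0, rng)
        assert not hasattr(stage, "rsa")
        assert not hasattr(stage, "gate")

    def test_insufficient_points_rejected(self, rng):
        cfg = _mini_config()
        stage = GLSAStage(8, 12, cfg, 0, rng)
        with pytest.raises(ValueError, match="insufficient|at least|m="):
            stage(np.zeros((1, 0, 3)), Tensor(np.zeros((1, 0, 8), dtype=np.float32)))


class TestInterpolation:
    def test_coincident_point_dominates(self, rng):
        coarse = rng.normal(size=(5, 3))
        feats = rng.normal(size=(5, 4))
        out = interpolate_features(coarse, feats, coarse[2:3])
        assert np.allclose(out[0], feats[2], atol=1e-6)

    def test_constant_field_preserved(self, rng):
        coarse = rng.normal(size=(6, 3))
        feats = np.ones((6, 2))
        fine = rng.normal(size=(10, 3))
        assert np.allclose(interpolate_features(coarse, feats, fine), 1.0)

    def test_midpoint_of_two_points_on_line(self):
        coarse = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        feats = np.array([[1.0], [3.0]])
        out = interpolate_features(coarse, feats, np.array([[1.0, 0, 0]]))
        # symmetric inverse-distance weights -> plain mean of the features
        assert out[0, 0] == pytest.approx(2.0, rel=1e-9)


class TestEAFP:
    def _stage(self, rng, **kw):
        cfg = _mini_config(**kw)
        return EAFPStage(6, 4, 8, cfg, rng)

    def test_constant_field_edge_term_vanishes(self, rng):
        stage = self._stage(rng)
        stage.set_training(False)
        coarse_pos = rng.normal(size=(1, 8, 3))
        skip_pos = rng.normal(size=(1, 16, 3))
        coarse_f = np.tile(rng.normal(size=(1, 1, 6)), (1, 8, 1)).astype(np.float32)
        skip_f = np.tile(rng.normal(size=(1, 1, 4)), (1, 16, 1)).astype(np.float32)
        out = stage(coarse_pos, Tensor(coarse_f), skip_pos, Tensor(skip_f)).data
        # constant input -> constant h2 -> all edge differences zero -> constant out
        assert np.allclose(out - out[:, :1], 0.0, atol=1e-5)

    def test_permutation_equivariance_over_skip_points(self, rng):
        stage = self._stage(rng)
        stage.set_training(False)
        coarse_pos = rng.normal(size=(1, 8, 3))
        skip_pos = rng.normal(size=(1, 16, 3))
        coarse_f = rng.normal(size=(1, 8, 6)).astype(np.float32)
        skip_f = rng.normal(size=(1, 16, 4)).astype(np.float32)
        out1 = stage(coarse_pos, Tensor(coarse_f), skip_pos, Tensor(skip_f)).data
        perm = rng.permutation(16)
        out2 = stage(
            coarse_pos, Tensor(coarse_f), skip_pos[:, perm], Tensor(skip_f[:, perm])
        ).data
        assert np.allclose(out1[:, perm], out2, atol=1e-5)

    def test_k_clamped_when_too_few_points(self, rng):
        stage = self._stage(rng, eafp_k=64)
        stage.set_training(False)
        out = stage(
            rng.normal(size=(1, 4, 3)),
            Tensor(rng.normal(size=(1, 4, 6)).astype(np.float32)),
            rng.normal(size=(1, 8, 3)),
            Tensor(rng.normal(size=(1, 8, 4)).astype(np.float32)),
        )
        assert out.shape == (1, 8, 8)


class TestPointSegNet:
    def test_output_shape_two_classes(self):
        cfg = tiny_config()
        rng = np.random.default_rng(0)
        model = PointSegNet(cfg, seed=0)
        model.set_training(False)
        scores = model(
            rng.normal(size=(2, 512, 3)),
            rng.normal(size=(2, 512, 6)).astype(np.float32),
        )
        assert scores.shape == (2, 512, cfg.num_classes)

    def test_channel_mismatch_named_error(self):
        cfg = tiny_config()
        model = PointSegNet(cfg, seed=0)
        with pytest.raises(ValueError, match="6 feature channels"):
            model(np.zeros((1, 512, 3)), np.zeros((1, 512, 4), dtype=np.float32))

    def test_end_to_end_permutation_equivariance(self):
        cfg = _mini_config()
        rng = np.random.default_rng(2)
        model = PointSegNet(cfg, seed=0)
        model.set_training(False)
        pos = rng.normal(size=(1, 64, 3))
        feats = rng.normal(size=(1, 64, 6)).astype(np.float32)
        out1 = model(pos, feats).data
        perm = rng.permutation(64)
        out2 = model(pos[:, perm], feats[:, perm]).data
        assert np.allclose(out1[:, perm], out2, atol=1e-4)

    def test_outputs_finite_over_seeds(self):
        cfg = _mini_config()
        model = PointSegNet(cfg, seed=0)
        model.set_training(False)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            out = model(
                rng.uniform(-1, 1, (1, 64, 3)),
                rng.uniform(-1, 1, (1, 64, 6)).astype(np.float32),
            ).data
            assert np.all(np.isfinite(out))

    def test_translation_absorbed_by_normalization(self):
        from stemleaf3d.preprocess import LabeledPointCloud, center_normalize

        cfg = _mini_config()
        model = PointSegNet(cfg, seed=0)
        model.set_training(False)
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(64, 3))
        normals = rng.normal(size=(64, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)

        def scores(p):
            cloud, _ = center_normalize(
                LabeledPointCloud(positions=p, normals=normals)
            )
            feats = np.concatenate([cloud.positions, cloud.normals], axis=1)
            return model(cloud.positions[None], feats[None].astype(np.float32)).data

        assert np.allclose(scores(pos), scores(pos + 17.3), atol=1e-5)

    def test_gradient_flows_to_every_named_module(self):
        cfg = _mini_config()
        model = PointSegNet(cfg, seed=0)
        rng = np.random.default_rng(4)
        from stemleaf3d.training import poly_focal_loss
        from stemleaf3d.autodiff import AdamW

        pos = rng.normal(size=(2, 64, 3))
        feats = rng.normal(size=(2, 64, 6)).astype(np.float32)
        labs = rng.integers(0, 2, (2, 64))
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        opt = AdamW(model.parameters(), lr=1e-2)
        loss = poly_focal_loss(model(pos, feats), labs)
        opt.zero_grad()
        loss.backward()
        opt.step()
        after = model.state_arrays()
        modules = ["stem", "stages.0", "stages.1", "stages.2", "stages.3",
                   "decoders.0", "decoders.1", "decoders.2", "decoders.3", "head"]
        for mod in modules:
            changed = any(
                k.startswith(mod) and not np.array_equal(before[k], after[k])
                for k in after
                if "running" not in k
            )
            assert changed, f"no parameter changed in {mod}"
        for s in range(4):
            key = f"stages.{s}.gate"
            assert not np.array_equal(before[key], after[key]), "fusion gate frozen"


class TestBudgets:
    def test_reference_parameter_count(self):
        assert count_parameters(reference_config()) == pytest.approx(1.33e6, rel=0.01)

    def test_rsa_ablation_parameter_count(self):
        cfg = reference_config()
        ab = dict(cfg.ablation)
        ab["rsa"] = False
        assert count_parameters(
            dataclasses.replace(cfg, ablation=ab)
        ) == pytest.approx(1.068e6, rel=0.03)

    def test_parameter_count_ordering_of_ablation_variants(self):
        cfg = reference_config()

        def variant(**off):
            ab = dict(cfg.ablation)
            ab.update(off)
            return count_parameters(dataclasses.replace(cfg, ablation=ab))

        full = count_parameters(cfg)
        seq = [
            full,
            variant(cam_se=False),
            variant(eafp=False),
            variant(resmlp=False),
            variant(rsa=False),
            variant(rsa=False, eafp=False),
        ]
        assert all(a > b for a, b in zip(seq, seq[1:]))

    def test_doubling_widths_roughly_quadruples_parameters(self):
        cfg = reference_config()
        doubled = dataclasses.replace(
            cfg,
            stem_width=2 * cfg.stem_width,
            stage_widths=tuple(2 * w for w in cfg.stage_widths),
            decoder_widths=tuple(2 * w for w in cfg.decoder_widths),
            head_width=2 * cfg.head_width,
        )
        ratio = count_parameters(doubled) / count_parameters(cfg)
        assert 3.4 < ratio < 4.1

    def test_reference_flop_count(self):
        assert count_flops(reference_config()) == pytest.approx(4.73e9, rel=0.05)

    def test_flops_scale_linearly_in_points(self):
        cfg = reference_config()
        r = count_flops(cfg, 4096) / count_flops(cfg, 2048)
        assert r == pytest.approx(2.0, rel=0.02)

    def test_resmlp_ablation_reduces_flops(self):
        cfg = reference_config()
        ab = dict(cfg.ablation)
        ab["resmlp"] = False
        assert count_flops(dataclasses.replace(cfg, ablation=ab)) < count_flops(cfg)


def test_checkpoint_roundtrip(tmp_path):
    from stemleaf3d.network import load_checkpoint, save_checkpoint

    cfg = _mini_config()
    model = PointSegNet(cfg, seed=3)
    model.set_training(False)
    rng = np.random.default_rng(0)
    pos = rng.normal(size=(1, 64, 3))
    feats = rng.normal(size=(1, 64, 6)).astype(np.float32)
    ref = model(pos, feats).data
    save_checkpoint(model, tmp_path / "w.npz")
    loaded = load_checkpoint(tmp_path / "w.npz")
    loaded.set_training(False)
    assert np.allclose(loaded(pos, feats).data, ref, atol=1e-7)
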