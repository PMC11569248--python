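"""Backbone contracts, branch shapes and model geometry."""

import numpy as np
import pytest

from epitype.errors import ConfigError, ShapeError
from epitype.model import (
    CelltypeFeatures,
    EpitypeModel,
    ModelConfig,
    celltyping_branch,
    combined_forward,
    dna_branch,
    load_model,
    make_matched_backbone,
    make_toy_backbone,
    save_model,
)
from epitype.nn import Tensor
from epitype.regions import DataConfig
from epitype.seq import one_hot, reverse_complement


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def zero_features(mcfg):
    return CelltypeFeatures(np.zeros(mcfg.local_len), np.zeros(mcfg.global_len))


class TestBackboneContract:
    def test_deterministic_and_frozen(self, tiny_mcfg):
        bb = make_toy_backbone(tiny_mcfg, seed=3)
        rng = np.random.default_rng(0)
        oh = one_hot(random_seq(rng, tiny_mcfg.data.input_len))
        a, b = bb(oh), bb(oh)
        assert np.array_equal(a, b)  # bitwise
        assert all(not p.trainable for p in bb.parameters())
        assert a.shape == (tiny_mcfg.n_bins, bb.channels)

    def test_same_seed_same_weights(self, tiny_mcfg):
        h1 = make_toy_backbone(tiny_mcfg, seed=3).state_hash()
        h2 = make_toy_backbone(tiny_mcfg, seed=3).state_hash()
        h3 = make_toy_backbone(tiny_mcfg, seed=4).state_hash()
        assert h1 == h2 != h3

    def test_flip_outside_receptive_field_leaves_centre_unchanged(self, tiny_model):
        cfg = tiny_model.cfg
        rng = np.random.default_rng(1)
        seq = random_seq(rng, cfg.data.input_len)
        bb = tiny_model.backbone
        mid = bb.latent_positions // 2
        lo, hi = bb.latent_span(mid, mid)
        ref = bb.forward_full(Tensor(one_hot(seq).T[None])).data[0, :, mid]
        for pos in (lo - 1, hi + 1):
            alt = [b for b in "ACGT" if b != seq[pos]][0]
            mod = seq[:pos] + alt + seq[pos + 1 :]
            out = bb.forward_full(Tensor(one_hot(mod).T[None])).data[0, :, mid]
            assert np.array_equal(out, ref)

    def test_declared_receptive_field_matches_exhaustive_flips(self, toy_mcfg):
        """On the 4,096-bp toy geometry, flip every base bracketing the
        declared dependency boundary of the centre latent position and
        check the measured extent equals the declared one exactly."""
        bb = make_toy_backbone(toy_mcfg, seed=0)
        rng = np.random.default_rng(2)
        seq = random_seq(rng, toy_mcfg.data.input_len)
        mid = bb.latent_positions // 2
        lo, hi = bb.latent_span(mid, mid)
        assert hi - lo + 1 == bb.receptive_field
        ref = bb.forward_full(Tensor(one_hot(seq).T[None])).data[0, :, mid]
        affected = []
        probe = list(range(lo - 6, lo + 7)) + list(range(hi - 6, hi + 7))
        probe += list(range(lo + 7, hi - 6, 97))  # interior sample
        for pos in probe:
            alt = [b for b in "ACGT" if b != seq[pos]][0]
            mod = seq[:pos] + alt + seq[pos + 1 :]
            out = bb.forward_full(Tensor(one_hot(mod).T[None])).data[0, :, mid]
            if not np.array_equal(out, ref):
                affected.append(pos)
        assert min(affected) == lo
        assert max(affected) == hi

    def test_non_power_of_two_bin_rejected(self, tiny_dcfg):
        import dataclasses

        bad = dataclasses.replace(tiny_dcfg, bin=96, window_len=960,
                                  input_len=1920, local_atac_len=2112,
                                  shift_max=96)
        with pytest.raises(ConfigError):
            make_toy_backbone(
                ModelConfig(data=bad, n_marks=2, n_marker_genes=2), 0
            )


class TestMatchedBackbone:
    def test_detects_planted_motif(self, tiny_mcfg):
        motifs = ("ACGTACGT", "TTGACCAA")
        bb = make_matched_backbone(tiny_mcfg, motifs, seed=0)
        rng = np.random.default_rng(3)
        L = tiny_mcfg.data.input_len
        base = random_seq(rng, L)
        pos = L // 2
        planted = base[: pos - 4] + motifs[0] + base[pos + 4 :]
        lat_base = bb.forward_full(Tensor(one_hot(base).T[None])).data[0]
        lat_plant = bb.forward_full(Tensor(one_hot(planted).T[None])).data[0]
        bin_idx = pos // tiny_mcfg.data.bin
        assert lat_plant[0, bin_idx] == pytest.approx(0.5)  # channel 0 fires
        # reverse complement fires the paired channel
        rc = base[: pos - 4] + reverse_complement(motifs[0]) + base[pos + 4 :]
        lat_rc = bb.forward_full(Tensor(one_hot(rc).T[None])).data[0]
        assert lat_rc[1, bin_idx] == pytest.approx(0.5)

    def test_broken_motif_does_not_fire(self, tiny_mcfg):
        motifs = ("ACGTACGT",)
        bb = make_matched_backbone(tiny_mcfg, motifs, seed=0)
        rng = np.random.default_rng(4)
        L = tiny_mcfg.data.input_len
        base = random_seq(rng, L)
        pos = L // 2
        broken = "ACGAACGT"  # central base mutated
        planted = base[: pos - 4] + broken + base[pos + 4 :]
        lat = bb.forward_full(Tensor(one_hot(planted).T[None])).data[0]
        assert lat[0, pos // tiny_mcfg.data.bin] <= 0.0


class TestDnaBranch:
    def test_simplex_and_positivity(self, tiny_model):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=(tiny_model.backbone.channels,
                                  tiny_model.cfg.latent_positions))
        avg, dist = dna_branch(latent.T, tiny_model)
        assert np.all(avg > 0)
        np.testing.assert_allclose(dist.sum(axis=-1), 1.0, atol=1e-6)

    def test_full_scale_output_shape(self):
        cfg = ModelConfig(data=DataConfig.paper_profile(), n_marks=6,
                          n_marker_genes=1216, backbone_channels=16,
                          trunk_channels=8, hidden_dim=16)
        model = EpitypeModel(cfg)
        latent = np.zeros((cfg.latent_positions, 16))
        avg, dist = model.dna_branch(Tensor(latent.T[None]))
        crop = (cfg.latent_positions - cfg.n_bins) // 2
        assert avg.data[0, crop : crop + cfg.n_bins].shape == (896, 6)
        assert dist.data.shape[-1] == cfg.data.n_dist_bins

    def test_shape_mismatch_rejected(self, tiny_model):
        with pytest.raises(ShapeError):
            tiny_model.dna_branch(Tensor(np.zeros((1, 3, 5))))


class TestCelltypingBranch:
    def test_output_shape_and_finite_on_zero_input(self, tiny_model):
        delta = celltyping_branch(zero_features(tiny_model.cfg), tiny_model)
        assert delta.shape == (tiny_model.cfg.n_bins, tiny_model.cfg.n_marks)
        assert np.all(np.isfinite(delta))

    def test_full_scale_feature_lengths_accepted(self):
        cfg = ModelConfig(data=DataConfig.paper_profile(), n_marks=6,
                          n_marker_genes=1216, backbone_channels=8,
                          trunk_channels=8, local_embed_dim=2,
                          global_embed_dim=2, hidden_dim=8)
        assert cfg.local_len == 1562
        assert cfg.global_len == 14_592
        model = EpitypeModel(cfg)
        feats = CelltypeFeatures(np.zeros(1562), np.zeros(14_592))
        delta = celltyping_branch(feats, model)
        assert delta.shape == (896, 6)

    def test_length_mismatch_rejected(self, tiny_model):
        feats = CelltypeFeatures(np.zeros(3), np.zeros(tiny_model.cfg.global_len))
        with pytest.raises(ShapeError):
            celltyping_branch(feats, tiny_model)


class TestCombinedForward:
    def test_nonnegative_and_deterministic(self, tiny_model):
        rng = np.random.default_rng(5)
        oh = one_hot(random_seq(rng, tiny_model.cfg.data.input_len))
        feats = CelltypeFeatures(
            rng.normal(size=tiny_model.cfg.local_len),
            rng.normal(size=tiny_model.cfg.global_len),
        )
        a = combined_forward(tiny_model, oh, feats, "neglog10p")
        b = combined_forward(tiny_model, oh, feats, "neglog10p")
        assert np.all(a.values >= 0)
        assert np.array_equal(a.values, b.values)
        arc = combined_forward(tiny_model, oh, feats, "arcsinh")
        np.testing.assert_allclose(np.sinh(arc.values), a.values, atol=1e-12)

    def test_output_shape(self, tiny_model):
        rng = np.random.default_rng(6)
        oh = one_hot(random_seq(rng, tiny_model.cfg.data.input_len))
        out = combined_forward(tiny_model, oh, zero_features(tiny_model.cfg))
        assert out.values.shape == (tiny_model.cfg.n_bins, tiny_model.cfg.n_marks)

    def test_full_scale_combined_shape(self):
        cfg = ModelConfig(data=DataConfig.paper_profile(), n_marks=6,
                          n_marker_genes=1216, backbone_channels=8,
                          trunk_channels=8, local_embed_dim=2,
                          global_embed_dim=2, hidden_dim=8,
                          combined_channels=8)
        model = EpitypeModel(cfg)
        out = model.forward(
            Tensor(np.zeros((1, 4, cfg.data.input_len))),
            Tensor(np.zeros((1, cfg.local_len))),
            Tensor(np.zeros((1, cfg.global_len))),
            latent=Tensor(np.zeros((1, 8, cfg.latent_positions))),
        )
        assert out["combined"].data.shape == (1, 896, 6)

    def test_geometry_checked_for_three_configs(self):
        geometries = [
            dict(window_len=512, input_len=1024, local_atac_len=1280, bin=64,
                 shift_max=64),
            dict(window_len=2048, input_len=4096, local_atac_len=4352, bin=128,
                 shift_max=384),
            dict(window_len=16_384, input_len=32_768, local_atac_len=33_280,
                 bin=128, shift_max=384),
        ]
        for geo in geometries:
            dcfg = DataConfig(**geo)
            mcfg = ModelConfig(data=dcfg, n_marks=2, n_marker_genes=2,
                               backbone_channels=8, trunk_channels=8,
                               hidden_dim=8, combined_channels=8,
                               local_embed_dim=2, global_embed_dim=2)
            model = EpitypeModel(mcfg)
            out = model.forward(
                Tensor(np.zeros((1, 4, dcfg.input_len))),
                Tensor(np.zeros((1, mcfg.local_len))),
                Tensor(np.zeros((1, mcfg.global_len))),
                latent=Tensor(np.zeros((1, 8, mcfg.latent_positions))),
            )
            assert out["combined"].data.shape == (1, dcfg.n_bins, 2)
            assert out["dist"].data.shape[-1] == dcfg.n_dist_bins


class TestSaveLoad:
    def test_roundtrip_preserves_predictions(self, tiny_model, tmp_path):
        rng = np.random.default_rng(8)
        oh = one_hot(random_seq(rng, tiny_model.cfg.data.input_len))
        feats = zero_features(tiny_model.cfg)
        before = combined_forward(tiny_model, oh, feats).values
        save_model(tiny_model, tmp_path / "ckpt")
        again = load_model(tmp_path / "ckpt")
        after = combined_forward(again, oh, feats).values
        np.testing.assert_array_equal(before, after)
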