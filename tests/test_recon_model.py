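"""Autoencoder contract, hybrid loss, SSIM/PSNR and the pretraining loop."""

import numpy as np
import pytest

from neuromae import masking as mk
from neuromae import nn
from neuromae import recon_model as rm
from neuromae._seeds import derive_seed

GRID = (32, 32, 16)


class TestStageShapes:
    def test_paper_scale_formula(self):
        cfg = rm.EncoderConfig(feature_size=24, input_grid=(128, 128, 64),
                               n_downsamples=5)
        shapes = rm.stage_shapes(cfg)
        # stage i: (X/2^i, Y/2^i, Z/2^i, 2^(i-1) C), C maps at stages 0 and 1
        assert shapes[2] == (32, 32, 16, 48)
        assert shapes[5] == (4, 4, 2, 384)
        for i, s in enumerate(shapes):
            expect_ch = 24 if i <= 1 else 24 * 2 ** (i - 1)
            assert s == (128 // 2 ** i, 128 // 2 ** i, 64 // 2 ** i, expect_ch)

    def test_forward_features_match_declared_shapes(self, encoder_cfg):
        model = rm.build_autoencoder(encoder_cfg)
        x = np.random.default_rng(0).random((2, 3) + GRID)
        _, feats = model.forward(x)
        for declared, f in zip(model.stage_shapes(GRID), feats):
            assert f.data.shape == (2, declared[3]) + declared[:3]

    def test_indivisible_grid_rejected_naming_dimension(self):
        cfg = rm.EncoderConfig(feature_size=8, input_grid=(32, 32, 20),
                               n_downsamples=4)
        with pytest.raises(ValueError, match="20"):
            rm.build_autoencoder(cfg)


class TestAutoencoderForward:
    def test_output_in_open_unit_interval_and_same_shape(self, encoder_cfg):
        model = rm.build_autoencoder(encoder_cfg)
        x = np.random.default_rng(1).random((2, 3) + GRID)
        recon, _ = model.forward(x)
        assert recon.data.shape == x.shape
        assert recon.data.min() > 0.0 and recon.data.max() < 1.0


class TestLosses:
    def test_recon_loss_examples(self):
        rng = np.random.default_rng(0)
        a = rng.random((3, 8, 8, 8))
        assert rm.recon_loss(a, a) == 0.0
        assert rm.recon_loss(a, a + 0.1) == pytest.approx(0.1, abs=1e-12)
        b = rng.random((3, 8, 8, 8))
        loop = np.mean([abs(a.ravel()[i] - b.ravel()[i]) for i in range(a.size)])
        assert rm.recon_loss(a, b) == pytest.approx(loop, abs=1e-7)

    def test_contrast_loss_symmetric_and_zero_iff_identical(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((3, 4, 4, 4)), rng.random((3, 4, 4, 4))
        assert rm.contrast_loss(a, b) == rm.contrast_loss(b, a)
        assert rm.contrast_loss(a, a) == 0.0
        assert rm.contrast_loss(a, a + 0.05) == pytest.approx(0.05, abs=1e-12)

    def test_total_loss_formula(self):
        assert rm.total_loss(0.5, 0.0) == 0.5
        assert rm.total_loss(0.2, 0.1) == pytest.approx(0.22, abs=1e-15)
        assert rm.total_loss(0.0, 123.0) == 0.0
        for r, c in np.random.default_rng(2).random((100, 2)):
            assert rm.total_loss(r, c) == r * (1 + c)
            assert rm.total_loss(r, c) >= r

    def test_total_loss_rejects_negative(self):
        with pytest.raises(ValueError):
            rm.total_loss(-0.1, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rm.recon_loss(np.zeros((3, 4, 4, 4)), np.zeros((3, 4, 4, 5)))


class TestReconQualityMetrics:
    def test_ssim_identity(self):
        x = np.random.default_rng(0).random((20, 20, 12))
        assert rm.ssim3d(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_psnr_worked_example(self):
        x = np.random.default_rng(0).random((8, 8, 8))
        assert rm.psnr(x, x + 0.1, max_value=1.0) == pytest.approx(20.0, abs=1e-9)
        assert rm.psnr(x, x) == np.inf

    def test_ssim_matches_reference_implementation(self):
        from skimage.metrics import structural_similarity as sk_ssim

        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.random((18, 18, 14))
            y = np.clip(x + 0.15 * rng.standard_normal(x.shape), 0, 1)
            ref = sk_ssim(x, y, data_range=1.0, gaussian_weights=True,
                          sigma=1.5, use_sample_covariance=False)
            assert rm.ssim3d(x, y, data_range=1.0) == pytest.approx(ref, abs=1e-5)


class TestPretrainStep:
    @pytest.fixture()
    def batch(self):
        return np.random.default_rng(0).random((2, 3) + GRID)

    def test_identical_mask_draws_collapse_contrast_term(self, encoder_cfg,
                                                         mask_scheme, batch):
        model = rm.build_autoencoder(encoder_cfg)
        terms, _ = rm.pretrain_step(model, batch, mask_scheme, seed=3,
                                    mask_seed_pair=(11, 11))
        assert terms.l_contrast == 0.0
        assert terms.l_total == terms.l_recon

    def test_unnormalised_input_rejected(self, encoder_cfg, mask_scheme, batch):
        model = rm.build_autoencoder(encoder_cfg)
        with pytest.raises(ValueError, match="normalised"):
            rm.pretrain_step(model, batch + 5.0, mask_scheme, seed=3)

    def test_terms_finite_nonnegative_and_hybrid_identity(self, encoder_cfg,
                                                          mask_scheme, batch):
        model = rm.build_autoencoder(encoder_cfg)
        terms, total = rm.pretrain_step(model, batch, mask_scheme, seed=4)
        assert terms.l_recon >= 0 and terms.l_contrast >= 0
        assert terms.l_total == pytest.approx(
            terms.l_recon * (1 + terms.l_contrast), rel=1e-6)
        assert np.isfinite(total.item())

    def test_identity_stub_model_gives_masked_value_loss(self, mask_scheme, batch):
        """If the model reproduces its (masked) input exactly, L_recon is
        exactly the mean absolute value of the masked-out voxels."""

        class IdentityStub:
            def forward(self, x):
                return nn.Tensor(x), []

        seeds = (21, 22)
        terms, _ = rm.pretrain_step(IdentityStub(), batch, mask_scheme, seed=0,
                                    mask_seed_pair=seeds)
        expected = []
        for s in seeds:
            masks = rm._batch_channel_masks(GRID, mask_scheme, len(batch), s)
            diff = np.where(masks, np.abs(batch - mask_scheme.fill_value), 0.0)
            expected.append(diff.mean())
        assert terms.l_recon == pytest.approx(np.mean(expected), rel=1e-5)


class TestTrainPretrain:
    def test_bookkeeping_two_epochs(self, encoder_cfg, mask_scheme,
                                    pretrain_corpus, tmp_path):
        cfg = rm.PretrainConfig(learning_rate=3e-3, epochs=2, eval_interval=5,
                                batch_size=4, seed=0, held_out_test_size=2,
                                mask_scheme=mask_scheme)
        model = rm.build_autoencoder(encoder_cfg)
        res = rm.train_pretrain(model, pretrain_corpus, cfg, out_dir=tmp_path)
        assert len(res.history) == 1  # ceil(2 / 5) evaluation rows
        assert (tmp_path / "pretrain_best.npz").exists()
        state, config, hist = rm.load_checkpoint(res.checkpoint_path)
        assert config["feature_size"] == encoder_cfg.feature_size
        assert len(hist) == 1

    def test_rerun_is_deterministic(self, encoder_cfg, mask_scheme, pretrain_corpus):
        def run():
            cfg = rm.PretrainConfig(learning_rate=3e-3, epochs=2, eval_interval=2,
                                    batch_size=4, seed=7, held_out_test_size=2,
                                    mask_scheme=mask_scheme)
            model = rm.build_autoencoder(encoder_cfg)
            return rm.train_pretrain(model, pretrain_corpus, cfg)

        a, b = run(), run()
        assert abs(a.history["l_total"].iloc[-1] - b.history["l_total"].iloc[-1]) < 1e-6
        assert a.history["ssim"].iloc[-1] == pytest.approx(
            b.history["ssim"].iloc[-1], abs=1e-9)

    def test_training_improves_reconstruction(self, pretrain_result):
        """20 epochs on 8 noise-free phantoms: held-out SSIM beats the
        untrained model and held-out L_recon drops by at least 20 %."""
        final = pretrain_result.history.iloc[-1]
        assert final["ssim"] > pretrain_result.baseline.ssim
        assert final["held_out_l_recon"] <= 0.8 * pretrain_result.baseline_l_recon

    def test_empty_split_rejected(self, encoder_cfg, mask_scheme, pretrain_corpus):
        cfg = rm.PretrainConfig(epochs=1, held_out_test_size=len(pretrain_corpus),
                                mask_scheme=mask_scheme)
        with pytest.raises(ValueError, match="non-empty"):
            rm.train_pretrain(rm.build_autoencoder(encoder_cfg), pretrain_corpus, cfg)
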