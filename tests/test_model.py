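"""Network components, embeddings, losses, SSIM, and patch sampling."""

import numpy as np
import pytest
from scipy import stats
from skimage.metrics import structural_similarity as skimage_ssim

from spinesynth.model import (
    GeneratorConfig,
    LossWeights,
    TASKS,
    TrainConfig,
    build_discriminator,
    build_generator,
    discriminator_loss,
    generator_loss,
    position_embeddings,
    sample_patch,
    ssim3d,
    ssim_loss,
)
from spinesynth.nn import Tensor
from spinesynth.workflows import make_phantom_cohort


class TestPositionEmbeddings:
    def test_full_volume_embedding_runs_zero_to_one(self):
        emb = position_embeddings((5, 9, 17), (0, 0, 0), (5, 9, 17))
        for a in range(3):
            line = np.moveaxis(emb[a], a, 0)[(slice(None), 0, 0)]
            assert line[0] == 0.0 and line[-1] == 1.0
            assert np.allclose(np.diff(line), 1.0 / (emb[a].shape[a] - 1), atol=1e-6)

    def test_crop_offset_linearity(self):
        emb = position_embeddings((101, 101, 101), (10, 0, 0), (4, 4, 4))
        assert emb[0][0, 0, 0] == pytest.approx(0.1)
        assert emb[0][1, 0, 0] == pytest.approx(0.11)

    def test_constant_along_other_axes(self):
        emb = position_embeddings((10, 12, 14), (2, 3, 4), (4, 4, 4))
        assert np.all(emb[0] == emb[0][:, :1, :1])
        assert np.all(emb[1] == emb[1][:1, :, :1])
        assert np.all(emb[2] == emb[2][:1, :1, :])

    def test_disjoint_crops_agree_only_on_overlap(self):
        a = position_embeddings((32, 32, 32), (0, 0, 0), (16, 16, 16))
        b = position_embeddings((32, 32, 32), (8, 8, 8), (16, 16, 16))
        assert np.allclose(a[:, 8:, 8:, 8:], b[:, :8, :8, :8])
        assert not np.allclose(a[:, :8], b[:, :8])

    def test_singleton_axis_gives_zero_channel(self):
        emb = position_embeddings((1, 8, 8), (0, 0, 0), (1, 8, 8))
        assert np.all(emb[0] == 0.0)


@pytest.fixture(scope="module")
def gen():
    return build_generator(
        GeneratorConfig(in_channels=6, base_channels=8, levels=3),
        rng=np.random.default_rng(0),
    )


class TestGenerator:

    def test_output_shape_matches_input(self, gen, rng):
        x = Tensor(rng.normal(size=(1, 6, 8, 16, 16)).astype(np.float32))
        assert gen(x).data.shape == (1, 1, 8, 16, 16)

    def test_indivisible_shape_rejected_with_hint(self, gen, rng):
        x = Tensor(rng.normal(size=(1, 6, 7, 16, 16)).astype(np.float32))
        with pytest.raises(ValueError, match="pad to"):
            gen(x)

    def test_batch_samples_are_independent(self, gen, rng):
        x1 = rng.normal(size=(1, 6, 8, 16, 16)).astype(np.float32)
        x2 = rng.normal(size=(1, 6, 8, 16, 16)).astype(np.float32)
        both = gen(Tensor(np.concatenate([x1, x2]))).data
        solo = gen(Tensor(x1)).data
        assert np.allclose(both[:1], solo, atol=1e-5)

    def test_forward_is_deterministic(self, gen, rng):
        x = Tensor(rng.normal(size=(1, 6, 8, 16, 16)).astype(np.float32))
        assert np.array_equal(gen(x).data, gen(x).data)

    def test_output_bounded_by_tanh(self, gen, rng):
        x = Tensor(rng.normal(size=(1, 6, 8, 16, 16)).astype(np.float32) * 5)
        out = gen(x).data
        assert out.min() >= -1.0 and out.max() <= 1.0


@pytest.fixture(scope="module")
def disc():
    return build_discriminator(
        GeneratorConfig(in_channels=3, base_channels=8, levels=3),
        rng=np.random.default_rng(1),
    )


class TestDiscriminator:

    def test_score_grid_smaller_than_input(self, disc, rng):
        x = Tensor(rng.normal(size=(1, 3, 16, 32, 32)).astype(np.float32))
        y = Tensor(rng.normal(size=(1, 1, 16, 32, 32)).astype(np.float32))
        grid = disc(x, y).data
        assert grid.shape == (1, 1, 2, 4, 4)

    def test_shift_by_full_stride_translates_scores(self, disc, rng):
        # a blob shifted by the total stride (8) moves the score grid by 1;
        # compare only cells whose receptive field stays inside the volume
        x = np.zeros((1, 3, 16, 16, 64), dtype=np.float32)
        y = np.zeros((1, 1, 16, 16, 64), dtype=np.float32)
        x[0, :, 6:10, 6:10, 20:28] = rng.normal(size=(3, 4, 4, 8))
        y[0, :, 6:10, 6:10, 20:28] = rng.normal(size=(1, 4, 4, 8))
        g0 = disc(Tensor(x), Tensor(y)).data
        g1 = disc(Tensor(np.roll(x, 8, axis=4)), Tensor(np.roll(y, 8, axis=4))).data
        assert np.allclose(
            np.roll(g0, 1, axis=4)[..., 3:7], g1[..., 3:7], atol=1e-3
        )

    def test_deterministic(self, disc, rng):
        x = Tensor(rng.normal(size=(1, 3, 16, 16, 16)).astype(np.float32))
        y = Tensor(rng.normal(size=(1, 1, 16, 16, 16)).astype(np.float32))
        assert np.array_equal(disc(x, y).data, disc(x, y).data)


class TestSSIM:
    def test_identical_volumes_give_one(self, rng):
        a = rng.random((16, 16, 16))
        assert ssim3d(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_of_zero_mean_volume_is_negative(self, rng):
        a = rng.normal(size=(16, 16, 16))
        a -= a.mean()
        assert ssim3d(a, -a, data_range=float(a.max() - a.min())) < 0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16, 16))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        ours = ssim3d(a, b, window=7, data_range=1.0)
        ref = skimage_ssim(a, b, win_size=7, data_range=1.0)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_small_volume_falls_back_to_global_window(self, rng):
        a = rng.random((4, 4, 4))
        b = rng.random((4, 4, 4))
        val = ssim3d(a, b)
        assert -1.0 <= val <= 1.0

    def test_loss_version_matches_metric_on_matching_inputs(self, rng):
        a = rng.uniform(-1, 1, size=(12, 12, 12))
        b = rng.uniform(-1, 1, size=(12, 12, 12))
        loss_val = float(ssim_loss(Tensor(a[None, None]), Tensor(b[None, None])).data)
        metric_val = ssim3d((a + 1) / 2, (b + 1) / 2, data_range=1.0)
        assert loss_val == pytest.approx(metric_val, abs=1e-9)


class TestLosses:
    def test_perfect_prediction_and_confident_critic_give_zero(self, rng):
        x = rng.uniform(-1, 1, size=(1, 1, 8, 8, 8))
        loss = generator_loss(x, x, np.ones((1, 1, 2, 2, 2)))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-9)

    def test_adversarial_term_alone_when_critic_rejects(self, rng):
        x = rng.uniform(-1, 1, size=(1, 1, 8, 8, 8))
        loss = generator_loss(x, x, np.zeros((1, 1, 2, 2, 2)))
        assert float(loss.data) == pytest.approx(1.0, abs=1e-9)

    def test_constant_offset_case_matches_hand_computed_ssim(self):
        # x = 0, x_hat = 0.1 everywhere: on the [0,1] scale mu1=0.55, mu2=0.5
        x = np.zeros((1, 1, 8, 8, 8))
        x_hat = np.full_like(x, 0.1)
        c1, c2 = 0.01**2, 0.03**2
        mu1, mu2 = 0.55, 0.5
        ssim_const = ((2 * mu1 * mu2 + c1) * c2) / ((mu1**2 + mu2**2 + c1) * c2)
        expected = 10 * 0.1 + 10 * (1 - ssim_const)
        loss = generator_loss(x_hat, x, np.ones((1, 1, 1, 1, 1)))
        assert float(loss.data) == pytest.approx(expected, rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            generator_loss(np.zeros((1, 1, 8, 8, 8)), np.zeros((1, 1, 8, 8, 4)),
                           np.ones((1, 1, 1, 1, 1)))

    @pytest.mark.parametrize(
        "d_fake,d_real,expected",
        [(0.0, 1.0, 0.0), (1.0, 0.0, 1.0), (0.5, 0.5, 0.25)],
    )
    def test_discriminator_loss_values(self, d_fake, d_real, expected):
        shape = (1, 1, 2, 2, 2)
        loss = discriminator_loss(np.full(shape, d_fake), np.full(shape, d_real))
        assert float(loss.data) == pytest.approx(expected, abs=1e-9)

    def test_loss_components_are_non_negative(self, rng):
        x = rng.uniform(-1, 1, size=(1, 1, 8, 8, 8))
        y = rng.uniform(-1, 1, size=(1, 1, 8, 8, 8))
        d = rng.normal(size=(1, 1, 2, 2, 2))
        assert float(generator_loss(x, y, d).data) >= 0.0
        assert float(discriminator_loss(d, d).data) >= 0.0


@pytest.fixture(scope="module")
def single_subject():
    studies, _ = make_phantom_cohort(1, seed=3)
    return studies["sub-000"]


class TestSamplePatch:

    def _cfg(self, **kw):
        defaults = dict(patch_size=(16, 64, 64), replication_factor=1,
                        resolution_range=None, epochs=1)
        defaults.update(kw)
        return TrainConfig(**defaults)

    def test_same_seed_gives_identical_patches(self, single_subject):
        cfg = self._cfg()
        p1 = sample_patch(single_subject, "t1w", cfg, np.random.default_rng(5))
        p2 = sample_patch(single_subject, "t1w", cfg, np.random.default_rng(5))
        assert np.array_equal(p1.inputs, p2.inputs)
        assert np.array_equal(p1.target, p2.target)

    def test_channel_count_is_modalities_plus_embeddings(self, single_subject):
        cfg = self._cfg()
        patch = sample_patch(single_subject, "t1w", cfg, np.random.default_rng(0))
        assert patch.inputs.shape == (6, 16, 64, 64)  # t2w + fat + water + 3 emb
        assert patch.target.shape == (1, 16, 64, 64)
        patch_stir = sample_patch(single_subject, "stir", cfg, np.random.default_rng(0))
        assert patch_stir.inputs.shape == (5, 16, 64, 64)  # t2w + t1w + 3 emb

    def test_embedding_channels_in_unit_interval(self, single_subject):
        patch = sample_patch(single_subject, "t1w", self._cfg(), np.random.default_rng(1))
        emb = patch.inputs[-3:]
        assert emb.min() >= 0.0 and emb.max() <= 1.0
        img = patch.inputs[:-3]
        assert img.min() >= -1.0 and img.max() <= 1.0

    def test_target_is_never_jittered(self, single_subject):
        cfg = self._cfg(jitter=True)
        rng_state = np.random.default_rng(2)
        patch = sample_patch(single_subject, "t1w", cfg, rng_state)
        off = patch.offset
        sl = tuple(slice(o, o + s) for o, s in zip(off, cfg.patch_size))
        assert np.array_equal(patch.target[0], single_subject["t1w"].data[sl].astype(np.float32))

    def test_offsets_cover_valid_range_uniformly(self, single_subject):
        cfg = self._cfg(jitter=False)
        rng_state = np.random.default_rng(7)
        shape = single_subject["t2w"].shape
        n_bins = shape[1] - 64 + 1
        draws = [sample_patch(single_subject, "t1w", cfg, rng_state).offset[1] for _ in range(1000)]
        counts = np.bincount(draws, minlength=n_bins)
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_missing_modality_rejected(self, single_subject):
        partial = {k: v for k, v in single_subject.items() if k != "dixon_fat"}
        with pytest.raises(ValueError, match="dixon_fat"):
            sample_patch(partial, "t1w", self._cfg(), np.random.default_rng(0))

    def test_volume_smaller_than_patch_is_padded(self, single_subject):
        cfg = self._cfg(patch_size=(24, 80, 80))
        patch = sample_patch(single_subject, "t1w", cfg, np.random.default_rng(0))
        assert patch.inputs.shape == (6, 24, 80, 80)
        assert patch.target.min() == -1.0  # pad value shows up


def test_patch_size_must_be_divisible_by_eight():
    with pytest.raises(ValueError, match="divisible by 8"):
        TrainConfig(patch_size=(15, 64, 64))
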