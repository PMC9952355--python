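"""Phantom generation, augmentation, patch extraction, corpus building."""

import numpy as np
import pytest
from scipy import stats

from r2cascade import (
    NoiseSpec,
    PhantomSpec,
    build_training_corpus,
    extract_patches,
    generate_liver_phantom,
    make_te_schedule,
    simulate_dataset,
)
from r2cascade.phantom import augment_dataset, patch_grid
from r2cascade.signal_model import synthesize_decay


class TestTeSchedule:
    def test_clinical_schedule(self):
        te = make_te_schedule(0.93, 1.34, 12)
        assert np.allclose(te.te_ms, 0.93 + 1.34 * np.arange(12))

    def test_two_echo_schedule(self):
        assert np.allclose(make_te_schedule(1.0, 1.0, 2).te_ms, [1.0, 2.0])

    @pytest.mark.parametrize("args", [(0.93, 1.34, 1), (0, 1.34, 12), (0.93, 0, 12)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            make_te_schedule(*args)


class TestPhantom:
    def test_shapes_and_range(self):
        spec = PhantomSpec(seed=3)
        maps, masks = generate_liver_phantom(spec)
        assert maps.shape == (64, 128)
        par = masks["parenchyma"]
        assert par.any()
        assert maps.r2star[par].min() >= 45.0
        assert maps.r2star[par].max() <= 956.0

    def test_deterministic(self):
        a, _ = generate_liver_phantom(PhantomSpec(seed=5))
        b, _ = generate_liver_phantom(PhantomSpec(seed=5))
        assert np.array_equal(a.r2star, b.r2star)
        assert np.array_equal(a.s0, b.s0)
        c, _ = generate_liver_phantom(PhantomSpec(seed=6))
        assert not np.array_equal(a.r2star, c.r2star)

    def test_mask_partition(self):
        _, masks = generate_liver_phantom(PhantomSpec(seed=1))
        assert not (masks["parenchyma"] & ~masks["liver"]).any()
        assert not (masks["background"] & masks["liver"]).any()
        assert not (masks["parenchyma"] & masks["vessels"]).any()

    def test_parenchyma_r2star_uniform(self):
        """Marginal R2* over parenchyma is ~uniform on the configured range."""
        values = []
        seed = 0
        while len(values) < 10_000:
            maps, masks = generate_liver_phantom(PhantomSpec(seed=seed))
            values.extend(maps.r2star[masks["parenchyma"]].tolist())
            seed += 1
        values = (np.asarray(values[:10_000]) - 45.0) / (956.0 - 45.0)
        d = stats.kstest(values, "uniform").statistic
        assert d < 0.05


class TestSimulatedDataset:
    def test_clean_non_increasing_and_noisy_non_negative(self, small_dataset):
        assert (np.diff(small_dataset.clean.data, axis=2) <= 1e-9).all()
        assert (small_dataset.noisy.data >= 0).all()

    def test_zero_noise_equals_clean(self):
        ds = simulate_dataset(PhantomSpec(seed=2), noise=NoiseSpec(0.0))
        assert np.array_equal(ds.noisy.data, ds.clean.data)

    def test_clean_is_model_synthesis(self, small_dataset):
        resynth = synthesize_decay(small_dataset.truth, small_dataset.clean.te)
        assert np.allclose(small_dataset.clean.data, resynth.data)


class TestAugmentation:
    def test_flip_involution(self, small_dataset):
        once = augment_dataset(small_dataset, ["flip_h"])[0]
        twice = augment_dataset(once, ["flip_h"])[0]
        assert np.array_equal(twice.noisy.data, small_dataset.noisy.data)
        assert np.array_equal(twice.truth.r2star, small_dataset.truth.r2star)

    def test_rot90_shapes(self, small_dataset):
        rot = augment_dataset(small_dataset, ["rot90"])[0]
        assert rot.noisy.shape == (128, 64, 12)
        assert rot.truth.shape == (128, 64)
        assert rot.masks["liver"].shape == (128, 64)

    @pytest.mark.parametrize("op", ["rot90", "rot180", "rot270", "flip_h", "flip_v"])
    def test_model_commutes_with_geometry(self, small_dataset, op):
        aug = augment_dataset(small_dataset, [op])[0]
        assert np.allclose(
            aug.clean.data, synthesize_decay(aug.truth, aug.clean.te).data
        )

    def test_unknown_op_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            augment_dataset(small_dataset, ["rot45"])


class TestPatches:
    def test_count_on_clinical_grid(self, small_dataset):
        ps = extract_patches(small_dataset, size=32, stride=8)
        assert len(ps) == 65  # (floor(32/8)+1) * (floor(96/8)+1) = 5 * 13
        assert ps.noisy.shape == (65, 32, 32, 12)
        assert ps.truth.shape == (65, 32, 32, 2)

    def test_single_patch_when_size_equals_image(self, small_dataset):
        grid = patch_grid(64, 64, 64, 8)
        assert grid == [(0, 0)]

    def test_patch_alignment(self, small_dataset):
        ps = extract_patches(small_dataset, size=32, stride=8)
        _, (r, c), _ = ps.provenance[17]
        assert np.array_equal(
            ps.noisy[17], small_dataset.noisy.data[r : r + 32, c : c + 32]
        )
        assert np.array_equal(
            ps.truth[17, :, :, 1], small_dataset.truth.r2star[r : r + 32, c : c + 32]
        )

    def test_oversized_patch_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            extract_patches(small_dataset, size=256, stride=8)

    def test_overlapping_reassembly_is_exact(self, small_dataset):
        """Averaging overlapping clean patches reconstructs the interior."""
        ps = extract_patches(small_dataset, size=32, stride=8)
        h, w, e = small_dataset.clean.shape
        acc = np.zeros((h, w, e))
        cnt = np.zeros((h, w, 1))
        for patch, (_, (r, c), _) in zip(ps.clean, ps.provenance):
            acc[r : r + 32, c : c + 32] += patch
            cnt[r : r + 32, c : c + 32] += 1
        interior = (cnt[:, :, 0] > 0)
        recon = acc[interior] / cnt[interior]
        assert np.allclose(recon, small_dataset.clean.data[interior], atol=1e-12)


class TestCorpus:
    def test_patch_count_scales_with_subjects(self):
        ps, manifest = build_training_corpus(3, noise_policy=9.0, seed=0)
        assert len(ps) == 3 * 65
        assert manifest["n_patches"] == 195

    def test_manifest_deterministic(self):
        _, m1 = build_training_corpus(2, noise_policy="mixed", seed=4)
        _, m2 = build_training_corpus(2, noise_policy="mixed", seed=4)
        _, m3 = build_training_corpus(2, noise_policy="mixed", seed=5)
        assert m1["hash"] == m2["hash"]
        assert m1["hash"] != m3["hash"]

    def test_mixed_policy_round_robin(self):
        _, manifest = build_training_corpus(
            20, noise_policy="mixed", seed=0, stride=32
        )
        sigmas = manifest["sigmas_per_subject"]
        counts = {s: sigmas.count(s) for s in set(sigmas)}
        assert len(counts) == 10
        assert all(v == 2 for v in counts.values())

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            build_training_corpus(2, noise_policy="bogus", seed=0)
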