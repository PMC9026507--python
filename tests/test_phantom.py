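"""Phantom simulator: determinism, contrast, registration, bookkeeping."""

import numpy as np
import pytest

import cyclesynth as cs
from cyclesynth.phantom import (BACKGROUND, CONTRAST1_TABLE, FAT, FLUID, GM,
                                WM, PhantomConfig, split_subjects,
                                subsample_manifest)


@pytest.fixture(scope="module")
def clean_cfg():
    """Noise- and bias-free rendering so class means are exact."""
    return PhantomConfig(size=(64, 64), noise_sigma=0.0, bias_amplitude=0.0)


class TestGeneratePhantom:
    def test_seeded_determinism(self):
        cfg = PhantomConfig(size=(64, 64))
        a = cs.generate_phantom(cfg, 123)
        b = cs.generate_phantom(cfg, 123)
        np.testing.assert_array_equal(a.label_map, b.label_map)
        np.testing.assert_array_equal(a.contrast1, b.contrast1)
        np.testing.assert_array_equal(a.contrast2, b.contrast2)
        c = cs.generate_phantom(cfg, 124)
        assert not np.array_equal(a.contrast1, c.contrast1)

    def test_shapes_range_dtype(self):
        cfg = PhantomConfig(size=(48, 80))
        rec = cs.generate_phantom(cfg, 5)
        for img in (rec.contrast1, rec.contrast2):
            assert img.shape == (48, 80)
            assert img.dtype == np.float32
            assert img.min() >= -1.0 and img.max() <= 1.0

    def test_all_tissue_classes_present(self):
        cfg = PhantomConfig(size=(64, 64))
        for seed in range(20):
            labels = cs.generate_phantom(cfg, seed).label_map
            for cls in (BACKGROUND, FAT, WM, GM, FLUID):
                assert np.any(labels == cls), f"class {cls} missing, seed {seed}"

    def test_contrast1_intensity_ordering(self, clean_cfg):
        """Without noise/bias, class means follow the contrast-1 (T1-like)
        table: fat > WM > GM > fluid."""
        rec = cs.generate_phantom(clean_cfg, 11)
        means = [rec.contrast1[rec.label_map == c].mean()
                 for c in (FAT, WM, GM, FLUID)]
        assert means[0] > means[1] > means[2] > means[3]
        # exact table values on the [-1, 1] scale
        np.testing.assert_allclose(means[0], 0.95 * 2 - 1, atol=1e-6)

    def test_contrast2_intensity_ordering(self, clean_cfg):
        rec = cs.generate_phantom(clean_cfg, 11)
        fluid = rec.contrast2[rec.label_map == FLUID].mean()
        gm = rec.contrast2[rec.label_map == GM].mean()
        wm = rec.contrast2[rec.label_map == WM].mean()
        assert fluid > gm > wm
        np.testing.assert_allclose(fluid, 0.95 * 2 - 1, atol=1e-6)

    def test_contrasts_registered_by_construction(self, clean_cfg):
        """The two renderings share the label map: thresholding each contrast
        at its background level recovers the same head support."""
        rec = cs.generate_phantom(clean_cfg, 3)
        head = rec.label_map != BACKGROUND
        np.testing.assert_array_equal(rec.contrast1 > -0.9, head)
        np.testing.assert_array_equal(rec.contrast2 > -0.9, head)

    def test_contrasts_differ(self):
        rec = cs.generate_phantom(PhantomConfig(size=(64, 64)), 2)
        assert np.abs(rec.contrast1 - rec.contrast2).mean() > 0.05

    def test_histograms_give_distinct_domains(self, clean_cfg):
        """Fluid is dark in contrast 1 and bright in contrast 2."""
        rec = cs.generate_phantom(clean_cfg, 9)
        fluid = rec.label_map == FLUID
        assert rec.contrast1[fluid].mean() < 0.0 < rec.contrast2[fluid].mean()

    def test_bias_field_bounded(self):
        """With bias but no noise, per-class intensities stay within
        amplitude x table value of the nominal mean."""
        cfg = PhantomConfig(size=(64, 64), noise_sigma=0.0, bias_amplitude=0.1)
        rec = cs.generate_phantom(cfg, 7)
        wm = rec.contrast1[rec.label_map == WM]
        nominal = 0.75 * 2 - 1
        assert np.all(np.abs(wm - nominal) <= 0.1 * 0.75 * 2 + 1e-6)

    def test_invalid_table_rejected(self):
        bad = dict(CONTRAST1_TABLE)
        bad[FLUID] = 0.99  # breaks fat > ... > fluid
        with pytest.raises(ValueError, match="contrast-1"):
            PhantomConfig(intensity_contrast1=bad)


class TestSplits:
    def test_full_study_scale_bookkeeping(self):
        """1517 subjects x 10 slices per contrast: 30,340 slices total and a
        floor-based 70/10/20 subject split of (1063, 151, 303)."""
        man = cs.generate_dataset(1517, 10, PhantomConfig(size=(16, 16)),
                                  master_seed=0)
        assert man.total_slices == 30_340
        assert man.split_counts() == {"train": 1063, "val": 151, "test": 303}
        assert len(man.train_a) == len(man.train_b) == 1063 * 10

    def test_ten_subject_split(self):
        train, val, test = split_subjects([f"s{i}" for i in range(10)], 0)
        assert (len(train), len(val), len(test)) == (7, 1, 2)
        assert set(train) | set(val) | set(test) == {f"s{i}" for i in range(10)}

    def test_split_deterministic_and_disjoint(self):
        ids = [f"s{i}" for i in range(37)]
        a = split_subjects(ids, 5)
        b = split_subjects(ids, 5)
        assert a == b
        train, val, test = a
        assert not (set(train) & set(val)) and not (set(val) & set(test))
        assert (len(train), len(val), len(test)) == (27, 3, 7)

    def test_subject_level_split_no_leakage(self):
        """All slices of one subject share a split tag."""
        man = cs.generate_dataset(12, 3, PhantomConfig(size=(16, 16)), 1)
        by_subject = {}
        for e in man.entries:
            by_subject.setdefault(e.subject_id, set()).add(e.split)
        assert all(len(s) == 1 for s in by_subject.values())

    def test_too_few_subjects_for_split(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_subjects(["a"] * 9, 0)
        man = cs.generate_dataset(4, 2, PhantomConfig(size=(16, 16)), 0)
        assert man.split_counts() == {"train": 4}


class TestManifest:
    def test_lazy_render_matches_direct_generation(self, tiny_manifest):
        rec = tiny_manifest.render(0)
        direct = cs.generate_phantom(tiny_manifest.config,
                                     tiny_manifest.entries[0].seed)
        np.testing.assert_array_equal(rec.contrast1, direct.contrast1)

    def test_slice_seeds_unique_and_31bit(self):
        man = cs.generate_dataset(50, 4, PhantomConfig(size=(16, 16)), 3)
        seeds = [e.seed for e in man.entries]
        assert len(set(seeds)) == len(seeds)
        assert all(0 <= s < 2**31 for s in seeds)

    def test_dict_roundtrip(self, tiny_manifest, tmp_path):
        path = tmp_path / "man.json"
        tiny_manifest.save(path)
        loaded = cs.DatasetManifest.load(path)
        assert loaded.to_dict() == tiny_manifest.to_dict()
        np.testing.assert_array_equal(loaded.render(0).contrast1,
                                      tiny_manifest.render(0).contrast1)

    def test_training_images_follow_domain_lists(self, tiny_manifest):
        imgs_a = tiny_manifest.training_images("a")
        imgs_b = tiny_manifest.training_images("b")
        assert len(imgs_a) == len(tiny_manifest.train_a)
        rec = tiny_manifest.render(tiny_manifest.train_b[0])
        np.testing.assert_array_equal(imgs_b[0], rec.contrast2)

    def test_paired_slices_are_registered(self, tiny_manifest):
        pairs = tiny_manifest.paired_slices("train")
        assert len(pairs) == sum(e.split == "train"
                                 for e in tiny_manifest.entries)
        c1, c2 = pairs[0]
        assert c1.shape == c2.shape
        assert not np.array_equal(c1, c2)


class TestSubsample:
    def test_balanced_and_deterministic(self):
        man = cs.generate_dataset(30, 4, PhantomConfig(size=(16, 16)), 2)
        sub = subsample_manifest(man, 40, seed=1)
        assert len(sub.train_a) == len(sub.train_b) == 20
        assert set(sub.train_a) <= set(man.train_a)
        again = subsample_manifest(man, 40, seed=1)
        assert again.train_a == sub.train_a and again.train_b == sub.train_b
        other = subsample_manifest(man, 40, seed=2)
        assert other.train_a != sub.train_a

    def test_val_test_untouched(self):
        man = cs.generate_dataset(30, 4, PhantomConfig(size=(16, 16)), 2)
        sub = subsample_manifest(man, 20, seed=0)
        assert sub.split_counts() == man.split_counts()
        assert len(sub.entries) == len(man.entries)

    def test_invalid_requests(self):
        man = cs.generate_dataset(30, 4, PhantomConfig(size=(16, 16)), 2)
        with pytest.raises(ValueError, match="even"):
            subsample_manifest(man, 41)
        with pytest.raises(ValueError, match="available"):
            subsample_manifest(man, 10 ** 6)
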