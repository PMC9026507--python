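"""Schedule, buffer, augmentation, checkpointing, and training smoke tests."""

import numpy as np
import pytest

import cyclesynth as cs
from cyclesynth.experiments import train_model
from cyclesynth.trainer import ImageBuffer


class TestSchedule:
    def test_reference_protocol_values(self):
        cfg = cs.TrainConfig()  # 200 epochs, decay after 100
        assert cs.lr_at_epoch(50, cfg) == pytest.approx(2e-4)
        assert cs.lr_at_epoch(100, cfg) == pytest.approx(2e-4)
        assert cs.lr_at_epoch(150, cfg) == pytest.approx(1e-4)
        assert cs.lr_at_epoch(200, cfg) == 0.0

    def test_continuous_and_nonincreasing(self):
        cfg = cs.TrainConfig()
        values = [cs.lr_at_epoch(e, cfg) for e in range(1, 201)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        steps = np.abs(np.diff(values))
        assert steps.max() <= cfg.lr_initial / 100 + 1e-12  # no jumps

    def test_out_of_range_epoch(self):
        cfg = cs.TrainConfig()
        for epoch in (0, 201):
            with pytest.raises(ValueError, match="epoch"):
                cs.lr_at_epoch(epoch, cfg)

    def test_short_run_stays_at_initial_rate(self):
        cfg = cs.TrainConfig(epochs=12)
        assert cs.lr_at_epoch(12, cfg) == cfg.lr_initial


class TestImageBuffer:
    def _images(self, n, rng):
        return [rng.standard_normal((4, 4)) for _ in range(n)]

    def test_fill_phase_returns_inputs(self, rng):
        buf = ImageBuffer(50, rng)
        for img in self._images(50, rng):
            out = buf.query(img)
            np.testing.assert_array_equal(out, img)
        assert len(buf) == 50

    def test_capacity_pinned_after_fill(self, rng):
        buf = ImageBuffer(50, rng)
        for img in self._images(120, rng):
            buf.query(img)
        assert len(buf) == 50

    def test_historical_return_frequency(self):
        """Post-fill, a query returns a stored image half the time."""
        rng = np.random.default_rng(2024)
        buf = ImageBuffer(50, rng)
        for i in range(50):
            buf.query(np.full((2, 2), float(i)))
        historical = 0
        for i in range(50, 10_050):
            new = np.full((2, 2), float(i))
            out = buf.query(new)
            if out[0, 0] != float(i):
                historical += 1
        assert abs(historical / 10_000 - 0.5) <= 0.02

    def test_no_starvation(self):
        """Every originally stored image is eventually evicted."""
        rng = np.random.default_rng(7)
        buf = ImageBuffer(10, rng)
        for i in range(10):
            buf.query(np.full((1,), float(i)))
        for i in range(10, 2000):
            buf.query(np.full((1,), float(i)))
        stored = {img[0] for img in buf.stored}
        assert stored.isdisjoint(set(map(float, range(10))))


class TestAugment:
    def test_crop_size_and_range(self, rng):
        img = rng.uniform(-1, 1, (256, 256))
        out = cs.augment(img, 128, rng)
        assert out.shape == (128, 128)

    def test_crop_equal_to_image_is_flips_only(self, rng):
        img = rng.uniform(-1, 1, (64, 64))
        out = cs.augment(img, 64, rng)
        variants = [img, img[:, ::-1], img[::-1, :], img[::-1, ::-1]]
        assert any(np.array_equal(out, v) for v in variants)

    def test_seeded_reproducibility(self, rng):
        img = rng.uniform(-1, 1, (100, 100))
        a = cs.augment(img, 48, np.random.default_rng(3))
        b = cs.augment(img, 48, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_too_small_image(self, rng):
        with pytest.raises(ValueError, match="smaller than crop"):
            cs.augment(rng.uniform(-1, 1, (32, 32)), 64, rng)


@pytest.fixture(scope="module")
def toy_training(tiny_manifest, tiny_gen_config):
    cfg = cs.TrainConfig(epochs=2, crop=32, seed=42)
    return train_model(tiny_manifest, "switchable", tiny_gen_config, cfg), cfg


class TestTrainingLoop:
    def test_log_bookkeeping(self, toy_training, tiny_manifest):
        result, cfg = toy_training
        steps_per_epoch = min(len(tiny_manifest.train_a),
                              len(tiny_manifest.train_b))
        assert len(result.log) == cfg.epochs * steps_per_epoch
        assert {r.epoch for r in result.log} == set(range(1, cfg.epochs + 1))
        for r in result.log:
            assert r.total == pytest.approx(
                r.adv_g + 10 * r.cyc + 5 * r.id, rel=1e-5)

    def test_seeded_determinism(self, tiny_manifest, tiny_gen_config):
        cfg = cs.TrainConfig(epochs=1, crop=32, seed=9)
        r1 = train_model(tiny_manifest, "switchable", tiny_gen_config, cfg)
        r2 = train_model(tiny_manifest, "switchable", tiny_gen_config, cfg)
        assert [r.total for r in r1.log] == [r.total for r in r2.log]

    def test_loss_decreases(self, tiny_manifest, tiny_gen_config):
        cfg = cs.TrainConfig(epochs=4, crop=32, seed=1)
        res = train_model(tiny_manifest, "switchable", tiny_gen_config, cfg)
        first = np.median([r.total for r in res.log if r.epoch == 1])
        last = np.median([r.total for r in res.log if r.epoch == cfg.epochs])
        assert last < first

    def test_empty_domain_rejected(self, tiny_manifest, tiny_gen_config):
        import copy

        man = copy.copy(tiny_manifest)
        man = cs.DatasetManifest(config=man.config, entries=man.entries,
                                 train_a=[], train_b=list(man.train_b))
        man.train_a = []
        model = cs.build_model("switchable", tiny_gen_config, 0)
        d_a = cs.build_discriminator(1, base_channels=8)
        d_b = cs.build_discriminator(2, base_channels=8)
        with pytest.raises(ValueError, match="at least one"):
            cs.train(man, model, d_a, d_b, cs.TrainConfig(epochs=1, crop=32))

    def test_csv_log_roundtrip(self, toy_training, tmp_path):
        result, _ = toy_training
        path = tmp_path / "loss.csv"
        result.write_log_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == list(cs.LossReport.FIELDS)
        assert len(df) == len(result.log)


class TestCheckpoint:
    def test_roundtrip_preserves_forward_outputs(self, toy_training, tmp_path,
                                                 tiny_gen_config, rng):
        result, _ = toy_training
        path = tmp_path / "ckpt.npz"
        cs.save_checkpoint(path, result.model, result.d_a, result.d_b, epoch=2)
        fresh = cs.build_model("switchable", tiny_gen_config, seed=999)
        d_a = cs.build_discriminator(seed=998, base_channels=8)
        d_b = cs.build_discriminator(seed=997, base_channels=8)
        meta = cs.load_checkpoint(path, fresh, d_a, d_b)
        assert meta["epoch"] == 2
        x = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        np.testing.assert_array_equal(result.model.a2b(x), fresh.a2b(x))
        np.testing.assert_array_equal(result.model.b2a(x), fresh.b2a(x))
        np.testing.assert_array_equal(
            cs.discriminate(result.d_a, x), cs.discriminate(d_a, x))

    def test_kind_mismatch_rejected(self, toy_training, tmp_path,
                                    tiny_gen_config):
        result, _ = toy_training
        path = tmp_path / "ckpt.npz"
        cs.save_checkpoint(path, result.model, result.d_a, result.d_b, epoch=1)
        wrong = cs.build_model("cyclegan", tiny_gen_config, 0)
        d_a = cs.build_discriminator(base_channels=8)
        d_b = cs.build_discriminator(base_channels=8)
        with pytest.raises(ValueError, match="model"):
            cs.load_checkpoint(path, wrong, d_a, d_b)
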