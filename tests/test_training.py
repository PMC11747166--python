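"""Loss-function worked examples and small training-loop behaviors."""

from dataclasses import replace

import numpy as np
import pytest

from cbctmotion.autodiff import Tensor
from cbctmotion.grids import DisplacementField, VolumeGrid
from cbctmotion.training import (AugmentationConfig, StageConfig,
                                 TrainingSchedule, loss_augmentation,
                                 loss_image, loss_mbc, loss_projection,
                                 loss_self_consistency, loss_tv, loss_zms,
                                 run_training, sample_augmented_scores)


class TestSimilarityLosses:
    def test_image_identical_offset_and_random(self, rng):
        a = rng.uniform(size=(6, 6, 6))
        assert float(loss_image(Tensor(a), a).data) == 0.0
        c = 0.37
        assert float(loss_image(Tensor(a + c), a).data) \
            == pytest.approx(c ** 2, rel=1e-12)
        b = rng.uniform(size=(6, 6, 6))
        assert float(loss_image(Tensor(a), b).data) \
            == pytest.approx(((a - b) ** 2).mean(), rel=1e-12)

    def test_projection_batch_mean(self, rng):
        drr = rng.uniform(size=(4, 5, 6))
        meas = rng.uniform(size=(4, 5, 6))
        assert float(loss_projection(Tensor(drr), drr).data) == 0.0
        assert float(loss_projection(Tensor(drr), meas).data) \
            == pytest.approx(((drr - meas) ** 2).mean(), rel=1e-12)
        with pytest.raises(ValueError):
            loss_projection(Tensor(drr), meas[:2])


class TestTotalVariation:
    def test_constant_volume_is_zero(self):
        assert float(loss_tv(Tensor(np.full((5, 5, 5), 3.3))).data) \
            == pytest.approx(0.0, abs=1e-9)

    def test_unit_step_plane_matches_hand_count(self):
        # 4^3 volume, step of 1 between x-slices 1 and 2: the forward
        # difference is 1 at the 16 voxels of slice 1, 0 elsewhere
        v = np.zeros((4, 4, 4))
        v[2:, :, :] = 1.0
        expected = 16 * 1.0 / 64
        assert float(loss_tv(Tensor(v)).data) \
            == pytest.approx(expected, rel=1e-6)

    def test_positive_homogeneity(self, rng):
        v = rng.uniform(size=(6, 6, 6))
        l1 = float(loss_tv(Tensor(v)).data)
        l3 = float(loss_tv(Tensor(3.0 * v)).data)
        assert l3 == pytest.approx(3.0 * l1, rel=1e-5)


class TestMBCLoss:
    def _fields(self, arrays):
        return [[Tensor(arrays[i][k]) for k in range(3)] for i in range(3)]

    def test_all_zero_basis_gives_one(self):
        z = [[np.zeros((4, 4, 4))] * 3 for _ in range(3)]
        assert float(loss_mbc(self._fields(z)).data) == pytest.approx(1.0)

    def test_orthonormal_basis_gives_zero(self, rng):
        # orthonormal under the mean inner product: scaled Fourier-like
        # modes on 8 samples per field
        n = 8
        t = np.arange(n)
        modes = [np.sqrt(2) * np.cos(2 * np.pi * (i + 1) * t / n)
                 for i in range(3)]
        arrays = [[modes[i].reshape(2, 2, 2) for _ in range(3)]
                  for i in range(3)]
        assert float(loss_mbc(self._fields(arrays)).data) \
            == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_unit_component_gives_eight_ninths(self):
        e = np.sqrt(2) * np.cos(2 * np.pi * np.arange(8) / 8).reshape(2, 2, 2)
        arrays = [[np.zeros((2, 2, 2))] * 3 for _ in range(3)]
        arrays[0] = [e, np.zeros_like(e), np.zeros_like(e)]
        arrays[1] = [e, np.zeros_like(e), np.zeros_like(e)]
        assert float(loss_mbc(self._fields(arrays)).data) \
            == pytest.approx(8.0 / 9.0, rel=1e-12)


class TestZeroMeanScoreLoss:
    def test_zero_mean_scores(self, rng):
        s = rng.normal(size=(10, 3, 3))
        s -= s.mean(axis=0, keepdims=True)
        val = loss_zms(Tensor(s), np.zeros((3, 3)), 10)
        assert float(val.data) == pytest.approx(0.0, abs=1e-24)

    def test_constant_channel_closed_form(self):
        s = np.zeros((5, 3, 3))
        s[:, 1, 2] = 4.0
        val = loss_zms(Tensor(s), np.zeros((3, 3)), 5)
        assert float(val.data) == pytest.approx(16.0 / 9.0, rel=1e-12)

    def test_even_in_sign(self, rng):
        s = rng.normal(size=(6, 3, 3))
        a = float(loss_zms(Tensor(s), np.zeros((3, 3)), 6).data)
        b = float(loss_zms(Tensor(-s), np.zeros((3, 3)), 6).data)
        assert a == pytest.approx(b, rel=1e-12)

    def test_out_of_batch_cache_enters_the_mean(self):
        batch = np.ones((2, 3, 3))
        cached_sum = -2.0 * np.ones((3, 3))     # cancels the batch exactly
        val = loss_zms(Tensor(batch), cached_sum, 4)
        assert float(val.data) == pytest.approx(0.0, abs=1e-24)


class TestSelfConsistency:
    def test_zero_dvf_is_zero(self, smooth_blob):
        grid = smooth_blob
        ref = Tensor(grid.values)
        dvf = Tensor(np.zeros(grid.shape + (3,)))
        assert float(loss_self_consistency(ref, ref, dvf, grid).data) == 0.0

    def test_interior_translation_is_nearly_zero(self, smooth_blob):
        from cbctmotion.motion import warp_tensor
        grid = smooth_blob
        ref = Tensor(grid.values)
        vec = np.zeros(grid.shape + (3,))
        vec[..., 2] = 4.0                        # compact blob: no boundary
        dvf = Tensor(vec)
        dynamic = warp_tensor(ref, dvf, grid)
        val = float(loss_self_consistency(ref, dynamic, dvf, grid).data)
        assert val < 1e-6       # tiny residual from the blob's clipped tail

    def test_fixed_point_inverse_beats_naive_negation(self, smooth_blob):
        from cbctmotion.motion import warp_tensor
        grid = smooth_blob
        pts = grid.voxel_centers().reshape(grid.shape + (3,))
        vec = np.zeros(grid.shape + (3,))
        vec[..., 2] = 6.0 * np.exp(-(pts[..., 0] ** 2) / 300.0)
        ref = Tensor(grid.values)
        dvf_t = Tensor(vec)
        dynamic = warp_tensor(ref, dvf_t, grid)
        good = float(loss_self_consistency(ref, dynamic, dvf_t, grid).data)
        naive = warp_tensor(dynamic, Tensor(-vec), grid)
        bad = float(((naive - ref) ** 2).mean().data)
        assert good < bad


class TestAugmentation:
    def test_ranges_and_zero_fixed_point(self, rng):
        cfg = AugmentationConfig()
        w = rng.uniform(0.5, 2.0, size=(50, 3, 3))
        w_aug = sample_augmented_scores(w, cfg, rng)
        assert np.all(w_aug >= 0.6 * 0.8 * w - 1e-12)
        assert np.all(w_aug <= 2.0 * 1.2 * w + 1e-12)
        assert np.all(sample_augmented_scores(np.zeros((3, 3, 3)), cfg, rng)
                      == 0.0)

    def test_r1_shared_within_frame(self, rng):
        cfg = AugmentationConfig(r2_range=(1.0, 1.0))    # isolate r1
        w = np.ones((4, 3, 3))
        w_aug = sample_augmented_scores(w, cfg, rng)
        for b in range(4):
            assert np.allclose(w_aug[b], w_aug[b, 0, 0])

    def test_reproducible_with_seed(self):
        cfg = AugmentationConfig()
        w = np.ones((5, 3, 3))
        a = sample_augmented_scores(w, cfg, np.random.default_rng(42))
        b = sample_augmented_scores(w, cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_loss_examples(self, rng):
        t = rng.normal(size=(4, 3, 3))
        assert float(loss_augmentation(Tensor(t), t).data) == 0.0
        assert float(loss_augmentation(Tensor(t + 0.5), t).data) \
            == pytest.approx(0.25, rel=1e-12)


def test_full_schedule_matches_protocol_table():
    sched = TrainingSchedule.full_scale()
    assert [s.epochs for s in sched.stages] \
        == [400, 700, 1700, 1000, 1000, 1000, 1000]
    assert [s.lr_inr for s in sched.stages] \
        == [4e-4, 4e-5, 1e-5, 1e-3, 4e-4, 1e-4, 0.0]
    assert [s.lr_cnn for s in sched.stages] \
        == [0.0, 0.0, 1e-3, 0.0, 0.0, 1e-4, 1e-4]
    assert [s.lr_basis for s in sched.stages] \
        == [0.0, 0.0, 1e-3, 0.0, 0.0, 1e-4, 0.0]
    assert sched.weights == {"sim": 1.0, "tv": 2e-4, "mbc": 1.0,
                             "zms": 1e-3, "sc": 1e3, "aug": 1e-4}
    assert sched.n_batch == 32
    assert [s.resolution for s in sched.stages] \
        == ["lo", "lo", "lo", "hi", "hi", "hi", "hi"]
    assert [s.augmentation for s in sched.stages] \
        == [None, None, None, None, "angle", "angle", "motion_angle"]


@pytest.fixture(scope="module")
def tiny_setup():
    """Very small acquisition for fast end-to-end training smoke tests."""
    from cbctmotion.phantom import mini_thorax_spec, packaged_scenarios, \
        acquisition_geometry, render_sequence
    spec = mini_thorax_spec((16, 16, 8), (12.4, 12.4, 12.4))
    geom = acquisition_geometry(12, 6.0, (12, 16), 18.6)
    stack, gt = render_sequence(spec, packaged_scenarios()["S1"], geom)
    return spec, geom, stack, gt


def _tiny_schedule(rows):
    return TrainingSchedule([StageConfig(*r) for r in rows], n_batch=4,
                            sc_subsample=1)


def test_zero_lr_component_is_bit_frozen(tiny_setup):
    spec, geom, stack, gt = tiny_setup
    rows = [("I-b", 2, "lo", 1e-4, 0.0, 0.0, ("prj", "tv"), None)]
    model, _ = run_training(stack, geom, _tiny_schedule(rows), spec.grid(),
                            seed=0)
    trainer = model._trainer
    cnn_before = [p.data.copy() for p in trainer.cnn.parameters()]
    basis_before = [p.data.copy() for p in trainer.basis.parameters()]
    model2, _ = run_training(stack, geom, _tiny_schedule(rows), spec.grid(),
                             seed=0, trainer_state=trainer)
    for p, before in zip(trainer.cnn.parameters(), cnn_before):
        np.testing.assert_array_equal(p.data, before)
    for p, before in zip(trainer.basis.parameters(), basis_before):
        np.testing.assert_array_equal(p.data, before)


def test_training_runs_all_stage_kinds_and_logs_finite(tiny_setup):
    spec, geom, stack, gt = tiny_setup
    rows = [
        ("I-a", 1, "lo", 1e-3, 0.0, 0.0, ("im",), None),
        ("I-b", 1, "lo", 1e-4, 0.0, 0.0, ("prj", "tv"), None),
        ("I-c", 1, "lo", 1e-5, 1e-3, 1e-3,
         ("prj", "tv", "mbc", "zms", "sc"), None),
        ("II-a", 1, "hi", 1e-3, 0.0, 0.0, ("im",), None),
        ("II-b", 1, "hi", 1e-4, 0.0, 0.0, ("prj", "tv", "aug"), "angle"),
        ("II-c", 1, "hi", 1e-4, 1e-3, 1e-3,
         ("prj", "tv", "mbc", "zms", "sc", "aug"), "angle"),
        ("II-d", 1, "hi", 0.0, 1e-3, 0.0, ("aug",), "motion_angle"),
    ]
    model, log = run_training(stack, geom, _tiny_schedule(rows), spec.grid(),
                              seed=3)
    steps = [e for e in log if e.get("epoch", -1) >= 0]
    assert {e["stage"] for e in steps} \
        == {"I-a", "I-b", "I-c", "II-a", "II-b", "II-c", "II-d"}
    assert all(np.isfinite(e["total"]) for e in steps)
    assert model.solved_scores.shape == (len(stack), 3, 3)
    # stage II-d ran the motion+angle augmentation loss
    assert any("aug" in e for e in steps if e["stage"] == "II-d")


def test_resume_by_stage_is_bitwise_identical(tiny_setup):
    spec, geom, stack, gt = tiny_setup
    rows = [
        ("I-a", 1, "lo", 1e-3, 0.0, 0.0, ("im",), None),
        ("I-b", 1, "lo", 1e-4, 0.0, 0.0, ("prj", "tv"), None),
    ]
    sched = _tiny_schedule(rows)
    full, _ = run_training(stack, geom, sched, spec.grid(), seed=5)
    part, _ = run_training(stack, geom, sched, spec.grid(), seed=5,
                           stages=slice(0, 1))
    resumed, _ = run_training(stack, geom, sched, spec.grid(), seed=5,
                              stages=slice(1, 2),
                              trainer_state=part._trainer)
    for a, b in zip(full.inr.parameters(), resumed.inr.parameters()):
        np.testing.assert_array_equal(a.data, b.data)
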