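"""Synthetic dynamic phantom: geometry, breathing traces, analytic
deformation and ground-truth consistency."""

from dataclasses import replace

import numpy as np
import pytest

from cbctmotion.grids import DisplacementField, VolumeGrid
from cbctmotion.motion import propagate_mask, warp_volume
from cbctmotion.phantom import (BreathingScenario, PhantomSpec,
                                acquisition_geometry, analytic_dvf,
                                breathing_trace, deformation_envelope,
                                make_phantom, packaged_scenarios,
                                render_sequence, tumor_occupancy)


@pytest.fixture(scope="module")
def coarse_spec():
    """Full-size anatomy sampled on a coarse grid (fast to rasterize)."""
    return replace(PhantomSpec(), grid_shape=(40, 40, 20),
                   voxel_size_mm=(10.0, 10.0, 10.0))


def test_full_scale_defaults_match_protocol():
    spec = PhantomSpec()
    assert spec.grid_shape == (200, 200, 100)
    assert tuple(spec.voxel_size_mm) == (2.0, 2.0, 2.0)
    assert spec.tumor_diameter_mm == 30.0


def test_tumor_mask_voxel_count_at_2mm():
    # analytic volume (4/3) pi 15^3 / 8 mm^3 per voxel = 1767 voxels
    _, mask = make_phantom(PhantomSpec())
    assert abs(mask.sum() - 1767) <= 0.05 * 1767


def test_phantom_deterministic(coarse_spec):
    v1, m1 = make_phantom(coarse_spec)
    v2, m2 = make_phantom(coarse_spec)
    assert np.array_equal(v1.values, v2.values)
    assert np.array_equal(m1, m2)


def test_tumor_outside_lung_rejected(coarse_spec):
    bad = replace(coarse_spec, tumor_center=(0.0, 0.0, 0.0))   # in mediastinum
    with pytest.raises(ValueError, match="tumor"):
        make_phantom(bad)


def test_grid_and_attenuation_validation(coarse_spec):
    with pytest.raises(ValueError):
        make_phantom(replace(coarse_spec, grid_shape=(8, 8, 4)))
    with pytest.raises(ValueError):
        make_phantom(replace(coarse_spec, mu_lung=-0.1))


def test_breathing_trace_dominant_frequency():
    sc = BreathingScenario(period_s=4.0)
    t = np.arange(0, 60, 1 / 11)
    tr = sc.trace(t)
    freqs = np.fft.rfftfreq(len(tr), 1 / 11)
    power = np.abs(np.fft.rfft(tr - tr.mean()))
    assert freqs[np.argmax(power)] == pytest.approx(0.25, abs=0.02)


def test_zero_amplitude_gives_zero_trace_and_static_phantom(coarse_spec):
    sc = BreathingScenario(baseline_amplitude_mm=0.0)
    t = np.linspace(0, 20, 50)
    assert np.all(breathing_trace(sc, t) == 0.0)
    dvf = analytic_dvf(coarse_spec, sc, 1.23)
    assert np.all(dvf.vectors == 0.0)


def test_extended_range_scenario_exceeds_regular_at_every_peak():
    scenarios = packaged_scenarios()
    t = np.arange(0, 60, 0.02)
    a1 = scenarios["S1"].trace(t)
    a7 = scenarios["S7"].trace(t)
    # compare cycle peaks: S7's SI range is extended
    from scipy.signal import argrelmax
    peaks1 = a1[argrelmax(a1, order=20)]
    peaks7 = a7[argrelmax(a7, order=20)]
    assert peaks7.min() > peaks1.max() * 0.99
    assert a7.max() > a1.max()


def test_trace_bounded_by_amplitude_envelope():
    for sc in packaged_scenarios().values():
        t = np.linspace(0, 60, 2000)
        bound = sc.baseline_amplitude_mm * (1 + abs(sc.amp_mod)) \
            + abs(sc.drift_mm_per_min)
        assert np.all(np.abs(sc.trace(t)) <= bound + 1e-9)


def test_unsorted_timestamps_rejected():
    with pytest.raises(ValueError, match="sorted"):
        BreathingScenario().trace(np.array([0.0, 2.0, 1.0]))


def test_analytic_dvf_tumor_value_and_bound(coarse_spec):
    sc = packaged_scenarios()["S1"]
    t = 1.0
    a = float(sc.trace(np.array([t]))[0])
    dvf = analytic_dvf(coarse_spec, sc, t)
    env_tumor = deformation_envelope(
        coarse_spec, pts=np.asarray(coarse_spec.tumor_center)
        [None, None, None, :])[0, 0, 0]
    # SI displacement at the tumor equals the trace-scaled local envelope
    idx = tuple(np.round((np.asarray(coarse_spec.tumor_center)
                          - dvf.origin) / dvf.spacing).astype(int))
    grid_env = deformation_envelope(coarse_spec, coarse_spec.grid())
    assert dvf.vectors[idx + (2,)] == pytest.approx(a * grid_env[idx],
                                                    rel=1e-12)
    assert abs(env_tumor - grid_env[idx]) < 0.1
    assert np.abs(dvf.vectors).max() <= abs(a) * grid_env.max() + 1e-12
    # zero lateral motion, zero outside body
    assert np.all(dvf.vectors[..., 0] == 0.0)
    body = (coarse_spec.grid().voxel_centers()
            .reshape(coarse_spec.grid_shape + (3,)))
    outside = ((body[..., 0] / coarse_spec.body_semiaxes[0]) ** 2
               + (body[..., 1] / coarse_spec.body_semiaxes[1]) ** 2) >= 1.0
    assert np.all(dvf.vectors[outside] == 0.0)


def test_mass_plausibility_under_deformation(coarse_spec):
    sc = packaged_scenarios()["S1"]
    neutral, _ = make_phantom(coarse_spec)
    dvf = analytic_dvf(coarse_spec, sc, 1.0)     # amplitude <= 10 mm
    moved = warp_volume(neutral, dvf)
    assert abs(moved.values.sum() - neutral.values.sum()) \
        <= 0.02 * neutral.values.sum()


def test_ground_truth_mask_consistency_dsc():
    """Propagating the anti-aliased neutral tumor mask with the analytic
    DVF reproduces the exact frame mask (DSC >= 0.98 at 2 mm voxels)."""
    spec = PhantomSpec()
    grid = spec.grid()
    sc = packaged_scenarios()["S1"]
    occ = tumor_occupancy(spec, grid)
    pts = grid.voxel_centers().reshape(grid.shape + (3,))
    from cbctmotion.phantom import _frame_tumor_mask
    a = 7.5
    env = deformation_envelope(spec, grid)
    vec = a * env[..., None] * np.array([0.0, sc.ap_fraction, 1.0])
    dvf = DisplacementField(vec, grid.spacing, grid.origin)
    warped, _ = propagate_mask(occ, dvf)
    exact = _frame_tumor_mask(spec, sc, a, pts)
    inter = (warped & exact).sum()
    assert 2.0 * inter / (warped.sum() + exact.sum()) >= 0.98


def test_render_sequence_ground_truth_and_determinism(coarse_spec):
    sc = packaged_scenarios()["S2"]
    geom = acquisition_geometry(n_projections=5, duration_s=2.5,
                                detector_shape=(12, 16),
                                pixel_pitch_mm=28.0)
    stack1, gt1 = render_sequence(coarse_spec, sc, geom)
    stack2, gt2 = render_sequence(coarse_spec, sc, geom)
    assert np.array_equal(stack1.frames, stack2.frames)
    assert np.array_equal(gt1.coms_mm, gt2.coms_mm)
    assert len(gt1) == len(stack1) == 5
    # COM of the exact mask stays within half a voxel of the analytic COM
    for k in range(5):
        np.testing.assert_allclose(gt1.mask_com(k), gt1.coms_mm[k],
                                   atol=float(np.max(gt1.neutral.spacing))
                                   / 2.0)


def test_static_scenario_equal_angles_identical(coarse_spec):
    sc = BreathingScenario(baseline_amplitude_mm=0.0)
    angles = np.array([30.0, 30.0, 30.0])
    from cbctmotion.geometry import ScanGeometry
    geom = ScanGeometry(1000.0, 1500.0, (12, 16), 28.0, angles_deg=angles,
                        timestamps_s=np.array([0.0, 1.0, 2.0]))
    stack, _ = render_sequence(coarse_spec, sc, geom)
    np.testing.assert_array_equal(stack.frames[0], stack.frames[1])
    np.testing.assert_array_equal(stack.frames[0], stack.frames[2])


def test_full_scale_protocol_and_test_offset():
    geom = acquisition_geometry()
    assert geom.n_frames == 660
    assert geom.detector_shape == (192, 256)
    assert geom.pixel_pitch_mm == 1.55
    assert geom.timestamps_s[-1] == pytest.approx(60.0 * 659 / 660)
    span = geom.angles_deg[-1] - geom.angles_deg[0]
    assert span == pytest.approx(360.0 * 659 / 660)
    test_geom = acquisition_geometry(angle_offset_deg=90.27)
    np.testing.assert_allclose(test_geom.angles_deg - geom.angles_deg,
                               90.27)


def test_angle_timestamp_mismatch_rejected(coarse_spec):
    from cbctmotion.geometry import ScanGeometry
    geom = ScanGeometry(1000.0, 1500.0, (12, 16), 28.0,
                        angles_deg=np.array([0.0, 1.0]),
                        timestamps_s=np.array([0.0, 1.0, 2.0]))
    with pytest.raises(ValueError):
        render_sequence(coarse_spec, packaged_scenarios()["S1"], geom)
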