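"""Dynamic thorax-like digital phantom with analytic breathing deformation.

The phantom is a composition of geometric primitives (elliptical body,
two ellipsoidal lungs closed inferiorly by diaphragm domes, a spinal
column, and a spherical lung tumor) with tissue-realistic attenuation
coefficients (mm^-1 at ~100 kVp).  Breathing is modeled analytically: a
scalar trace a(t) scales a smooth spatial envelope that peaks at the
diaphragm apex and decays to zero at the body surface, displacing tissue
along superior-inferior (SI) and anterior-posterior (AP) axes:

    d(x, t) = a(t) * E(x) * (0, f_AP, 1)         [mm, pull convention]

Because the deformation is in closed form, every frame of a simulated scan
carries exact ground truth: the dense DVF, the tumor mask, and the tumor
center of mass.  Seven packaged breathing scenarios vary amplitude,
frequency, waveform shape, drift and regularity; scenario 7 has an
extended SI range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ProjectionStack, ScanGeometry, forward_project
from .grids import DisplacementField, VolumeGrid
from .motion import mask_com, warp_volume


@dataclass
class PhantomSpec:
    """Geometric description of the static (end-exhale) phantom, mm units."""

    grid_shape: tuple = (200, 200, 100)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    # attenuation (mm^-1)
    mu_body: float = 0.020
    mu_lung: float = 0.0045
    mu_spine: float = 0.035
    mu_tumor: float = 0.024
    # primitives (mm, world frame centered at isocenter)
    body_semiaxes: tuple = (150.0, 110.0)          # axial ellipse (x, y)
    lung_centers: tuple = ((-65.0, -10.0, 15.0), (65.0, -10.0, 15.0))
    lung_semiaxes: tuple = (52.0, 72.0, 70.0)
    spine_center_y: float = 78.0
    spine_radius: float = 14.0
    diaphragm_apex_z: float = -35.0                # dome apex (SI)
    diaphragm_depth: float = 45.0                  # dome sag toward lung edge
    tumor_center: tuple = (65.0, -10.0, -12.0)
    tumor_diameter_mm: float = 30.0
    # deformation envelope
    envelope_z_halfwidth: float = 110.0            # raised-cosine SI half width

    def scaled(self, factor: float) -> "PhantomSpec":
        """Geometrically self-similar phantom at `factor` times the size."""
        f = float(factor)
        return replace(
            self,
            grid_shape=self.grid_shape,
            body_semiaxes=tuple(a * f for a in self.body_semiaxes),
            lung_centers=tuple(tuple(c * f for c in lc)
                               for lc in self.lung_centers),
            lung_semiaxes=tuple(a * f for a in self.lung_semiaxes),
            spine_center_y=self.spine_center_y * f,
            spine_radius=self.spine_radius * f,
            diaphragm_apex_z=self.diaphragm_apex_z * f,
            diaphragm_depth=self.diaphragm_depth * f,
            tumor_center=tuple(c * f for c in self.tumor_center),
            envelope_z_halfwidth=self.envelope_z_halfwidth * f,
        )

    def validate(self):
        if any(s < m for s, m in zip(self.grid_shape, (16, 16, 8))):
            raise ValueError("grid_shape must be at least (16, 16, 8)")
        for mu in (self.mu_body, self.mu_lung, self.mu_spine, self.mu_tumor):
            if mu < 0:
                raise ValueError("attenuation values must be >= 0")
        if not self._tumor_inside_lung():
            raise ValueError("tumor sphere is not strictly inside a lung")

    def _tumor_inside_lung(self) -> bool:
        c = np.asarray(self.tumor_center)
        r = self.tumor_diameter_mm / 2.0
        # sample the tumor surface and require every point inside one lung
        # ellipsoid and above its diaphragm dome
        n = 200
        idx = np.arange(n)
        phi = np.arccos(1 - 2 * (idx + 0.5) / n)
        theta = np.pi * (1 + 5 ** 0.5) * idx
        pts = c + r * np.stack([np.sin(phi) * np.cos(theta),
                                np.sin(phi) * np.sin(theta),
                                np.cos(phi)], axis=-1)
        sa = np.asarray(self.lung_semiaxes)
        for lc in self.lung_centers:
            lc = np.asarray(lc)
            inside = (((pts - lc) / sa) ** 2).sum(axis=1) < 1.0
            above = pts[:, 2] > self._dome_z(pts[:, 0], pts[:, 1], lc)
            if np.all(inside & above):
                return True
        return False

    def _dome_z(self, x, y, lung_center):
        rho2 = (((x - lung_center[0]) / self.lung_semiaxes[0]) ** 2
                + ((y - lung_center[1]) / self.lung_semiaxes[1]) ** 2)
        return self.diaphragm_apex_z - self.diaphragm_depth * np.minimum(rho2, 1.0)

    def grid(self) -> VolumeGrid:
        return VolumeGrid.centered(self.grid_shape, self.voxel_size_mm)


@dataclass
class BreathingScenario:
    """Parametric breathing trace a(t) >= 0 (mm of peak-scaled displacement).

    a(t) = A(t) * sin^{2n}(phi(t)) + drift(t)  with
    A(t) = baseline_amplitude * (1 + amp_mod * sin(2 pi t / amp_mod_period)),
    phi'(t) = (pi / period) * (1 + freq_mod * sin(2 pi t / freq_mod_period)),
    drift(t) = drift_mm_per_min * t / 60.

    a = 0 is the end-exhale reference state; larger a moves the diaphragm
    (and tumor) inferiorly by a * E(x).
    """

    scenario_id: str = "S1"
    baseline_amplitude_mm: float = 10.0
    ap_fraction: float = 0.4
    period_s: float = 4.0
    pattern_exponent: int = 2                      # sin^(2n) waveform
    amp_mod: float = 0.0
    amp_mod_period_s: float = 12.0
    freq_mod: float = 0.0
    freq_mod_period_s: float = 15.0
    drift_mm_per_min: float = 0.0

    def trace(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        if np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be sorted")
        if self.freq_mod == 0.0:
            phi = np.pi * t / self.period_s
        else:
            # phase = pi/T * (t - (fm * Tfm / 2 pi) * (cos(2 pi t/Tfm) - 1))
            tfm = self.freq_mod_period_s
            phi = (np.pi / self.period_s) * (
                t - self.freq_mod * tfm / (2 * np.pi)
                * (np.cos(2 * np.pi * t / tfm) - 1.0))
        amp = self.baseline_amplitude_mm * (
            1.0 + self.amp_mod * np.sin(2 * np.pi * t / self.amp_mod_period_s))
        a = amp * np.sin(phi) ** (2 * self.pattern_exponent)
        return a + self.drift_mm_per_min * t / 60.0


def mini_thorax_spec(grid_shape=(64, 64, 32),
                     voxel_size_mm=(3.1, 3.1, 3.1)) -> PhantomSpec:
    """Reduced-size thorax with full-amplitude breathing.

    Desk-scale studies must keep the breathing excursion several voxels and
    detector pixels wide (as in a clinical scan) while the voxel budget
    stays small; shrinking the anatomy rather than coarsening the sampling
    preserves that ratio.  The tumor diameter (30 mm) and motion amplitudes
    are unchanged.
    """
    return replace(
        PhantomSpec(),
        grid_shape=tuple(grid_shape),
        voxel_size_mm=tuple(voxel_size_mm),
        body_semiaxes=(90.0, 70.0),
        lung_centers=((-40.0, -8.0, 8.0), (40.0, -8.0, 8.0)),
        lung_semiaxes=(34.0, 42.0, 40.0),
        spine_center_y=48.0,
        spine_radius=10.0,
        diaphragm_apex_z=-20.0,
        diaphragm_depth=25.0,
        tumor_center=(40.0, -8.0, -2.0),
        envelope_z_halfwidth=75.0,
    )


def packaged_scenarios() -> dict[str, BreathingScenario]:
    """Seven scenarios: regular, amplitude-varying, frequency-varying,
    pattern-varying, slow, irregular, extended-range."""
    return {
        "S1": BreathingScenario("S1"),
        "S2": BreathingScenario("S2", amp_mod=0.30, amp_mod_period_s=12.0),
        "S3": BreathingScenario("S3", freq_mod=0.25, freq_mod_period_s=15.0),
        "S4": BreathingScenario("S4", pattern_exponent=1, amp_mod=0.15),
        "S5": BreathingScenario("S5", period_s=6.0),
        "S6": BreathingScenario("S6", amp_mod=0.25, amp_mod_period_s=9.0,
                                freq_mod=0.20, freq_mod_period_s=13.0,
                                drift_mm_per_min=-1.5),
        "S7": BreathingScenario("S7", baseline_amplitude_mm=15.0),
    }


def breathing_trace(scenario: BreathingScenario,
                    timestamps_s: np.ndarray) -> np.ndarray:
    return scenario.trace(timestamps_s)


# ---------------------------------------------------------------------------
# static phantom & envelope

def make_phantom(spec: PhantomSpec):
    """Rasterize the neutral phantom.  Returns (VolumeGrid, tumor_mask)."""
    spec.validate()
    grid = spec.grid()
    pts = grid.voxel_centers().reshape(spec.grid_shape + (3,))
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]

    vol = np.zeros(spec.grid_shape)
    body = (x / spec.body_semiaxes[0]) ** 2 + (y / spec.body_semiaxes[1]) ** 2 <= 1.0
    vol[body] = spec.mu_body

    sa = np.asarray(spec.lung_semiaxes)
    for lc in spec.lung_centers:
        lc = np.asarray(lc)
        lung = (((x - lc[0]) / sa[0]) ** 2 + ((y - lc[1]) / sa[1]) ** 2
                + ((z - lc[2]) / sa[2]) ** 2) <= 1.0
        lung &= z > spec._dome_z(x, y, lc)        # diaphragm closes the base
        vol[lung & body] = spec.mu_lung

    spine = (x ** 2 + (y - spec.spine_center_y) ** 2) <= spec.spine_radius ** 2
    vol[spine & body] = spec.mu_spine

    c = np.asarray(spec.tumor_center)
    tumor = ((pts - c) ** 2).sum(axis=-1) <= (spec.tumor_diameter_mm / 2.0) ** 2
    vol[tumor] = spec.mu_tumor
    return grid.like(vol), tumor


def tumor_occupancy(spec: PhantomSpec, grid: VolumeGrid | None = None,
                    supersample: int = 3) -> np.ndarray:
    """Fractional (anti-aliased) tumor occupancy per voxel in [0, 1].

    Propagating the occupancy rather than the binary mask keeps sub-voxel
    surface information through interpolation; thresholding at 0.5 after
    warping then reproduces the analytic frame mask to DSC >= 0.98."""
    grid = grid or spec.grid()
    pts = grid.voxel_centers().reshape(grid.shape + (3,))
    c = np.asarray(spec.tumor_center)
    r = spec.tumor_diameter_mm / 2.0
    ss = supersample
    offsets = (np.stack(np.meshgrid(*[np.arange(ss)] * 3, indexing="ij"),
                        axis=-1).reshape(-1, 3) - (ss - 1) / 2.0) / ss
    offsets = offsets * np.asarray(grid.spacing)
    occ = np.zeros(grid.shape)
    for o in offsets:
        occ += ((pts + o - c) ** 2).sum(axis=-1) <= r * r
    return occ / len(offsets)


def deformation_envelope(spec: PhantomSpec, grid: VolumeGrid | None = None,
                         pts: np.ndarray | None = None) -> np.ndarray:
    """Smooth (C^1) scalar envelope E(x) in [0, 1]: raised cosine in SI
    centered at the diaphragm apex, tapered to zero at the body surface."""
    if pts is None:
        grid = grid or spec.grid()
        pts = grid.voxel_centers().reshape(grid.shape + (3,))
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    rho2 = ((x / spec.body_semiaxes[0]) ** 2
            + (y / spec.body_semiaxes[1]) ** 2)
    exy = np.where(rho2 < 1.0,
                   np.cos(np.pi * np.minimum(rho2, 1.0) / 2.0) ** 2, 0.0)
    zfrac = np.minimum(np.abs(z - spec.diaphragm_apex_z)
                       / spec.envelope_z_halfwidth, 1.0)
    ez = np.cos(np.pi * zfrac / 2.0) ** 2
    return exy * ez


def analytic_dvf(spec: PhantomSpec, scenario: BreathingScenario,
                 t: float, grid: VolumeGrid | None = None,
                 envelope: np.ndarray | None = None) -> DisplacementField:
    """Closed-form DVF at time t on the phantom grid (pull convention)."""
    grid = grid or spec.grid()
    if envelope is None:
        envelope = deformation_envelope(spec, grid)
    a = float(scenario.trace(np.atleast_1d(t))[0])
    direction = np.array([0.0, scenario.ap_fraction, 1.0])
    vec = a * envelope[..., None] * direction
    return DisplacementField(vec, grid.spacing.copy(), grid.origin.copy())


# ---------------------------------------------------------------------------
# ground truth bookkeeping

@dataclass
class GroundTruthSequence:
    """Exact per-frame ground truth of a simulated dynamic acquisition.

    The analytic DVF is rank-1 per direction (trace x envelope), so the
    sequence stores the shared envelope plus per-frame scalars and
    reconstructs dense DVFs / deformed volumes on demand.
    """

    spec: PhantomSpec
    scenario: BreathingScenario
    neutral: VolumeGrid
    neutral_mask: np.ndarray
    neutral_occupancy: np.ndarray
    envelope: np.ndarray
    trace_mm: np.ndarray          # a(t_k)
    timestamps_s: np.ndarray
    masks: np.ndarray             # (n, nx, ny, nz) bool
    coms_mm: np.ndarray           # (n, 3) analytic tumor center of mass

    def __len__(self):
        return len(self.trace_mm)

    def dvf(self, k: int) -> DisplacementField:
        direction = np.array([0.0, self.scenario.ap_fraction, 1.0])
        vec = self.trace_mm[k] * self.envelope[..., None] * direction
        return DisplacementField(vec, self.neutral.spacing.copy(),
                                 self.neutral.origin.copy())

    def volume(self, k: int) -> VolumeGrid:
        return warp_volume(self.neutral, self.dvf(k))

    def mask_com(self, k: int) -> np.ndarray:
        return mask_com(self.masks[k], self.neutral.spacing,
                        self.neutral.origin)


def _analytic_tumor_com(spec: PhantomSpec, scenario: BreathingScenario,
                        a: float) -> np.ndarray:
    """Solve x* + d(x*) = tumor_center by fixed-point iteration (the pull
    convention moves material points to where their displaced preimage is)."""
    c0 = np.asarray(spec.tumor_center, dtype=np.float64)
    direction = np.array([0.0, scenario.ap_fraction, 1.0])
    x = c0.copy()
    for _ in range(25):
        e = deformation_envelope(spec, pts=x[None, None, None, :])[0, 0, 0]
        x_new = c0 - a * e * direction
        if np.max(np.abs(x_new - x)) < 1e-10:
            x = x_new
            break
        x = x_new
    return x


def _frame_tumor_mask(spec: PhantomSpec, scenario: BreathingScenario,
                      a: float, pts: np.ndarray) -> np.ndarray:
    """Exact frame mask: voxel centers x with |x + d(x)| inside the tumor."""
    c0 = np.asarray(spec.tumor_center)
    direction = np.array([0.0, scenario.ap_fraction, 1.0])
    env = deformation_envelope(spec, pts=pts)
    disp = a * env[..., None] * direction
    return (((pts + disp) - c0) ** 2).sum(axis=-1) \
        <= (spec.tumor_diameter_mm / 2.0) ** 2


def render_sequence(spec: PhantomSpec, scenario: BreathingScenario,
                    geometry: ScanGeometry, noise_i0: float | None = None,
                    seed: int = 0, step_mm: float | None = None):
    """Simulate a dynamic cone-beam acquisition with exact ground truth.

    Each frame warps the neutral phantom with the analytic DVF at the frame
    timestamp and projects it at the frame's gantry angle.  Optional
    Poisson-like noise (photon count `noise_i0` at zero attenuation) is off
    by default.  Returns (ProjectionStack, GroundTruthSequence).
    """
    if geometry.angles_deg is None or geometry.timestamps_s is None:
        raise ValueError("geometry must carry per-frame angles and timestamps")
    if len(geometry.angles_deg) != len(geometry.timestamps_s):
        raise ValueError("angle / timestamp count mismatch")
    neutral, tumor_mask = make_phantom(spec)
    grid = neutral
    env = deformation_envelope(spec, grid)
    pts = grid.voxel_centers().reshape(grid.shape + (3,))
    ts = geometry.timestamps_s
    trace = scenario.trace(ts)
    direction = np.array([0.0, scenario.ap_fraction, 1.0])

    frames = np.empty((len(ts),) + tuple(geometry.detector_shape))
    masks = np.empty((len(ts),) + grid.shape, dtype=bool)
    coms = np.empty((len(ts), 3))
    for k, (a, ang) in enumerate(zip(trace, geometry.angles_deg)):
        vec = a * env[..., None] * direction
        moving = warp_volume(neutral, DisplacementField(
            vec, grid.spacing.copy(), grid.origin.copy()))
        frames[k] = forward_project(moving, geometry, ang, step_mm=step_mm)
        masks[k] = _frame_tumor_mask(spec, scenario, a, pts)
        coms[k] = _analytic_tumor_com(spec, scenario, a)
    if noise_i0 is not None:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(noise_i0 * np.exp(-frames))
        frames = -np.log(np.maximum(counts, 1) / noise_i0)
    stack = ProjectionStack(frames, geometry.angles_deg, ts, geometry)
    gt = GroundTruthSequence(spec, scenario, neutral, tumor_mask,
                             tumor_occupancy(spec, grid), env,
                             trace, ts, masks, coms)
    return stack, gt


def acquisition_geometry(n_projections: int = 660, duration_s: float = 60.0,
                         detector_shape=(192, 256), pixel_pitch_mm: float = 1.55,
                         sad_mm: float = 1000.0, sdd_mm: float = 1500.0,
                         angle_offset_deg: float = 0.0) -> ScanGeometry:
    """Full-fan 360-degree acquisition; frame k at time k/fps, angles uniform
    over 360 degrees in acquisition order.  Defaults follow the full-scale
    protocol (660 projections over 60 s, 256x192 detector at 1.55 mm pitch).
    An `angle_offset_deg` of e.g. 90.27 generates an intra-treatment test
    scan that shares no (motion state, angle) pair with the training scan."""
    angles = angle_offset_deg + np.arange(n_projections) * 360.0 / n_projections
    ts = np.arange(n_projections) * duration_s / n_projections
    return ScanGeometry(sad_mm, sdd_mm, detector_shape, pixel_pitch_mm,
                        angles_deg=angles, timestamps_s=ts)
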