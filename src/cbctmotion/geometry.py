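"""Cone-beam scan geometry, forward projection (DRR) and FDK reconstruction.

The forward projector computes per-pixel line integrals by fixed-step ray
sampling with trilinear interpolation.  It is linear in the voxel values and
exposes a differentiable path (`project_tensor`) used during training.  The
FDK reconstruction (cosine weighting, row-wise ramp filtering with a Hann
apodization, distance-weighted backprojection) provides the warm-start
volume for the reference-anatomy fit.

Geometry convention: the source rotates in the axial x-y plane about the SI
axis z; angles are in degrees, counter-clockwise viewed from superior.  At
angle 0 the source sits at (0, -SAD, 0).  Detector rows (v) are parallel to
the SI axis, as required for Amsterdam-Shroud trace extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .autodiff import Tensor, grid_sample3
from .grids import VolumeGrid

ANGLE_CONVENTION = "degrees, CCW viewed from superior; source at (0,-SAD,0) at 0 deg"


@dataclass
class ScanGeometry:
    """Full-fan circular cone-beam geometry."""

    sad_mm: float                 # source -> isocenter
    sdd_mm: float                 # source -> detector
    detector_shape: tuple         # (rows v, cols u)
    pixel_pitch_mm: float
    angles_deg: np.ndarray = field(default=None)
    timestamps_s: np.ndarray = field(default=None)

    def __post_init__(self):
        if not (self.sdd_mm > self.sad_mm > 0):
            raise ValueError("degenerate geometry: require sdd > sad > 0")
        self.detector_shape = (int(self.detector_shape[0]),
                               int(self.detector_shape[1]))
        if self.angles_deg is not None:
            self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.timestamps_s is not None:
            self.timestamps_s = np.asarray(self.timestamps_s, dtype=np.float64)

    @property
    def n_frames(self):
        return 0 if self.angles_deg is None else len(self.angles_deg)

    def frame_axes(self, angle_deg: float):
        """Source position and (ray-axis, detector-u, detector-v) unit vectors."""
        th = np.deg2rad(angle_deg)
        d = np.array([np.sin(th), np.cos(th), 0.0])      # source -> isocenter
        u = np.array([np.cos(th), -np.sin(th), 0.0])
        v = np.array([0.0, 0.0, 1.0])
        source = -self.sad_mm * d
        return source, d, u, v

    def detector_pixel_positions(self, angle_deg: float) -> np.ndarray:
        """World positions of all detector pixel centers, shape (nv, nu, 3)."""
        source, d, u, v = self.frame_axes(angle_deg)
        nv, nu = self.detector_shape
        center = source + self.sdd_mm * d
        uoff = (np.arange(nu) - (nu - 1) / 2.0) * self.pixel_pitch_mm
        voff = (np.arange(nv) - (nv - 1) / 2.0) * self.pixel_pitch_mm
        return (center[None, None, :]
                + voff[:, None, None] * v[None, None, :]
                + uoff[None, :, None] * u[None, None, :])

    def project_points(self, pts: np.ndarray, angle_deg: float) -> np.ndarray:
        """Perspective projection of world points onto the detector (u,v in mm)."""
        pts = np.atleast_2d(pts)
        _, d, u, v = self.frame_axes(angle_deg)
        depth = self.sad_mm + pts @ d
        return np.stack([self.sdd_mm * (pts @ u) / depth,
                         self.sdd_mm * (pts @ v) / depth], axis=-1)

    def as_attrs(self) -> dict:
        return {"sad_mm": self.sad_mm, "sdd_mm": self.sdd_mm,
                "det_rows": self.detector_shape[0],
                "det_cols": self.detector_shape[1],
                "pitch_mm": self.pixel_pitch_mm,
                "angle_convention": ANGLE_CONVENTION}


@dataclass
class ProjectionStack:
    """Measured or simulated line-integral images (dimensionless)."""

    frames: np.ndarray            # (n, nv, nu)
    angles_deg: np.ndarray
    timestamps_s: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=np.float64)
        n = len(self.frames)
        if len(self.angles_deg) != n or len(self.timestamps_s) != n:
            raise ValueError("frames/angles/timestamps length mismatch")

    def __len__(self):
        return len(self.frames)

    def save_h5(self, path, extra_attrs: dict | None = None):
        with h5py.File(str(path), "w") as f:
            f.create_dataset("projections", data=self.frames)
            f.create_dataset("angles_deg", data=self.angles_deg)
            f.create_dataset("timestamps_s", data=self.timestamps_s)
            for k, v in self.geometry.as_attrs().items():
                f.attrs[k] = v
            for k, v in (extra_attrs or {}).items():
                f.attrs[k] = v

    @classmethod
    def load_h5(cls, path) -> "ProjectionStack":
        with h5py.File(str(path), "r") as f:
            frames = f["projections"][:]
            angles = f["angles_deg"][:]
            ts = f["timestamps_s"][:]
            geom = ScanGeometry(float(f.attrs["sad_mm"]), float(f.attrs["sdd_mm"]),
                                (int(f.attrs["det_rows"]), int(f.attrs["det_cols"])),
                                float(f.attrs["pitch_mm"]),
                                angles_deg=angles, timestamps_s=ts)
        return cls(frames, angles, ts, geom)


# ---------------------------------------------------------------------------
# forward projection

def _ray_samples(volume: VolumeGrid, geometry: ScanGeometry, angle_deg: float,
                 step_mm: float | None):
    """Sample coordinates (voxel units) and per-ray segment weights.

    Returns (coords (n_rays*n_s, 3), seg_over_ns (n_rays,), n_s).  Rays are
    clipped to the volume bounding box; rays that miss contribute zero.
    """
    if step_mm is None:
        step_mm = float(np.min(volume.spacing)) / 2.0
    source, _, _, _ = geometry.frame_axes(angle_deg)
    pix = geometry.detector_pixel_positions(angle_deg).reshape(-1, 3)
    dirs = pix - source
    lengths = np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = dirs / lengths

    lo = volume.origin
    hi = volume.origin + volume.extent_mm
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t0 = (lo[None, :] - source[None, :]) * inv
        t1 = (hi[None, :] - source[None, :]) * inv
    tn = np.nanmax(np.minimum(t0, t1), axis=1)
    tf = np.nanmin(np.maximum(t0, t1), axis=1)
    seg = np.maximum(tf - tn, 0.0)
    max_seg = seg.max() if seg.size else 0.0
    n_s = max(int(np.ceil(max_seg / step_mm)), 1)
    s = (np.arange(n_s) + 0.5) / n_s
    t = tn[:, None] + seg[:, None] * s[None, :]
    pts = source[None, None, :] + t[:, :, None] * dirs[:, None, :]
    coords = (pts - volume.origin) / volume.spacing
    return coords.reshape(-1, 3), seg / n_s, n_s


def forward_project(volume: VolumeGrid, geometry: ScanGeometry,
                    angle_deg: float, step_mm: float | None = None) -> np.ndarray:
    """DRR of a volume at one gantry angle; returns (nv, nu) line integrals."""
    src_out = np.linalg.norm(geometry.frame_axes(angle_deg)[0]) \
        > np.max(np.abs(volume.origin) + volume.extent_mm)
    if not src_out:
        raise ValueError("source lies inside the volume bounding sphere")
    t = project_tensor(Tensor(volume.values), volume, geometry, angle_deg,
                       step_mm=step_mm)
    return t.data


def project_tensor(vol: Tensor, grid: VolumeGrid, geometry: ScanGeometry,
                   angle_deg: float, step_mm: float | None = None,
                   cache: dict | None = None) -> Tensor:
    """Differentiable DRR: line integrals as a Tensor (nv, nu).

    `cache` (keyed by angle) may hold precomputed ray samples to avoid
    recomputing coordinates for repeated angles during training.
    """
    key = (round(float(angle_deg), 6), step_mm, grid.shape,
           tuple(grid.spacing))
    if cache is not None and key in cache:
        coords, w, n_s = cache[key]
    else:
        coords, w, n_s = _ray_samples(grid, geometry, angle_deg, step_mm)
        if cache is not None:
            cache[key] = (coords, w, n_s)
    nv, nu = geometry.detector_shape
    vals = grid_sample3(vol, coords)                     # (rays*n_s,)
    sums = vals.reshape(nv * nu, n_s).sum(axis=1)
    return (sums * Tensor(w)).reshape(nv, nu)


def forward_project_stack(volumes, geometry: ScanGeometry,
                          step_mm: float | None = None) -> ProjectionStack:
    """Project one volume (broadcast) or a per-frame sequence of volumes."""
    n = geometry.n_frames
    if n == 0:
        raise ValueError("geometry carries no frame angles")
    if isinstance(volumes, VolumeGrid):
        volumes = [volumes] * n
    if len(volumes) != n:
        raise ValueError("frame count mismatch between volumes and angles")
    frames = np.stack([forward_project(v, geometry, a, step_mm=step_mm)
                       for v, a in zip(volumes, geometry.angles_deg)])
    ts = geometry.timestamps_s
    if ts is None:
        ts = np.arange(n, dtype=np.float64)
    return ProjectionStack(frames, geometry.angles_deg, ts, geometry)


# ---------------------------------------------------------------------------
# FDK reconstruction

def _ramp_filter(n_pad: int, du: float, apodization: str = "hann") -> np.ndarray:
    """Frequency response of the band-limited ramp filter.

    Built from the spatial-domain Ram-Lak kernel (rather than sampling |f|
    directly) to avoid the well-known DC-bias artifact, then apodized with a
    Hann window in the frequency domain.
    """
    n = np.concatenate([np.arange(n_pad // 2 + 1), np.arange(-n_pad // 2 + 1, 0)])
    h = np.zeros(n_pad)
    h[0] = 1.0 / (4.0 * du ** 2)
    odd = np.abs(n) % 2 == 1
    h[odd] = -1.0 / (np.pi * n[odd] * du) ** 2
    H = np.real(np.fft.fft(h))
    if apodization == "hann":
        freqs = np.fft.fftfreq(n_pad, d=du)
        f_nyq = 1.0 / (2.0 * du)
        H = H * 0.5 * (1.0 + np.cos(np.pi * freqs / f_nyq))
    return H


def fdk_reconstruct(stack: ProjectionStack, geometry: ScanGeometry,
                    out_grid: VolumeGrid, apodization: str = "hann",
                    clamp_negative: bool = True) -> VolumeGrid:
    """Feldkamp-Davis-Kress filtered backprojection onto `out_grid`.

    Full-fan, full 360-degree scans assumed (no short-scan weighting).
    Angular coverage below 200 degrees triggers a warning-level note but the
    reconstruction still runs.
    """
    if len(stack) == 0:
        raise ValueError("empty projection stack")
    angles = np.asarray(stack.angles_deg, dtype=np.float64)
    span = np.ptp(angles)
    if span < 200.0 and len(angles) > 1:
        import warnings
        warnings.warn(f"angular span {span:.1f} deg < 200 deg; "
                      "FDK quality will degrade", stacklevel=2)

    sad, sdd = geometry.sad_mm, geometry.sdd_mm
    nv, nu = geometry.detector_shape
    mag = sad / sdd
    du = geometry.pixel_pitch_mm * mag                   # virtual detector at iso
    ubar = (np.arange(nu) - (nu - 1) / 2.0) * du
    vbar = (np.arange(nv) - (nv - 1) / 2.0) * du
    cosw = sad / np.sqrt(sad ** 2 + ubar[None, :] ** 2 + vbar[:, None] ** 2)

    n_pad = 1 << int(np.ceil(np.log2(2 * nu)))
    ramp = _ramp_filter(n_pad, du, apodization)

    # per-view angular weight: half of the local angular spacing (radians)
    th = np.deg2rad(angles)
    d_th = np.full(len(angles), np.deg2rad(span / max(len(angles) - 1, 1)))

    shape = out_grid.shape
    ax = [out_grid.origin[i] + out_grid.spacing[i] * np.arange(shape[i])
          for i in range(3)]
    X, Y = np.meshgrid(ax[0], ax[1], indexing="ij")     # (nx, ny)
    Z = ax[2]

    recon = np.zeros(shape, dtype=np.float64)
    for i, t in enumerate(th):
        g = stack.frames[i] * cosw
        G = np.fft.fft(g, n=n_pad, axis=1)
        filt = np.real(np.fft.ifft(G * ramp[None, :], axis=1))[:, :nu] * du

        sin_t, cos_t = np.sin(t), np.cos(t)
        U = sad + X * sin_t + Y * cos_t                  # (nx, ny)
        ub = sad * (X * cos_t - Y * sin_t) / U
        iu = (ub - ubar[0]) / du
        w2 = sad ** 2 / U ** 2
        iu0 = np.clip(np.floor(iu).astype(np.int64), 0, nu - 2)
        fu = np.clip(iu - iu0, 0.0, 1.0)
        for kz, z in enumerate(Z):
            vb = sad * z / U
            ivf = (vb - vbar[0]) / du
            iv0 = np.clip(np.floor(ivf).astype(np.int64), 0, nv - 2)
            fv = np.clip(ivf - iv0, 0.0, 1.0)
            s = (filt[iv0, iu0] * (1 - fv) * (1 - fu)
                 + filt[iv0, iu0 + 1] * (1 - fv) * fu
                 + filt[iv0 + 1, iu0] * fv * (1 - fu)
                 + filt[iv0 + 1, iu0 + 1] * fv * fu)
            recon[:, :, kz] += 0.5 * d_th[i] * w2 * s
    if clamp_negative:
        np.maximum(recon, 0.0, out=recon)
    return out_grid.like(recon)
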