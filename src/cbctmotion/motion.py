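"""Low-rank spatiotemporal motion model.

A deformation vector field (DVF) is decomposed into three spatial motion
basis components (MBCs) per Cartesian direction,

    d_k(x, p) = sum_i  w[i,k](p) * e[i,k](x),      i = 1..3, k = x,y,z,

where each ``e[i,k]`` is a cubic B-spline free-form deformation field whose
control coefficients are learnable, and the nine scalars ``w[i,k](p)`` are
per-projection scores predicted by the motion encoder.  The three levels
use control grids of 6^3, 12^3 and 24^3 (doubled per level) spanning the
volume extent, so each level captures a different spatial scale.

Displacements are in mm in the world frame throughout; conversion to voxel
offsets happens only inside the warping routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, bspline_apply, grid_sample3
from .grids import DisplacementField, VolumeGrid

N_LEVELS = 3
COMPONENTS = ("x", "y", "z")


def bspline_weights(u: np.ndarray):
    """Uniform cubic B-spline blending weights for local parameter u in [0,1)."""
    u2, u3 = u * u, u ** 3
    return ((1 - u) ** 3 / 6.0,
            (3 * u3 - 6 * u2 + 4) / 6.0,
            (-3 * u3 + 3 * u2 + 3 * u + 1) / 6.0,
            u3 / 6.0)


def collocation_matrix(points: np.ndarray, lo: float, hi: float,
                       n_ctrl: int) -> np.ndarray:
    """Dense 1-D cubic B-spline collocation matrix (n_points, n_ctrl).

    Control points are uniformly spaced with one-knot padding on each side;
    the interior span [lo, hi] maps to spline parameter [0, n_ctrl - 3].
    """
    pts = np.asarray(points, dtype=np.float64)
    s = (pts - lo) / (hi - lo) * (n_ctrl - 3)
    s = np.clip(s, 0.0, n_ctrl - 3 - 1e-12)
    cell = np.floor(s).astype(np.int64)
    u = s - cell
    w = bspline_weights(u)
    B = np.zeros((len(pts), n_ctrl))
    rows = np.arange(len(pts))
    for m in range(4):
        B[rows, cell + m] = w[m]
    return B


@dataclass
class MBCBasis:
    """Three-level learnable B-spline basis over a fixed volume extent."""

    origin: np.ndarray            # mm, world position of grid corner
    extent: np.ndarray            # mm, interior span per axis
    base_ctrl: int = 6

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.extent = np.asarray(self.extent, dtype=np.float64)
        self.ctrl_shapes = [tuple([self.base_ctrl * 2 ** i] * 3)
                            for i in range(N_LEVELS)]
        self.coef = [[Tensor(np.zeros(self.ctrl_shapes[i]), requires_grad=True)
                      for _ in COMPONENTS] for i in range(N_LEVELS)]
        self._mat_cache: dict = {}

    @classmethod
    def for_volume(cls, volume: VolumeGrid, base_ctrl: int = 6) -> "MBCBasis":
        return cls(volume.origin.copy(), volume.extent_mm.copy(), base_ctrl)

    def init_random(self, rng: np.random.Generator, scale: float = 1.0):
        """Smooth random initialization with roughly unit mean-square fields."""
        for i in range(N_LEVELS):
            for k in range(3):
                self.coef[i][k].data = rng.normal(
                    0.0, scale, size=self.ctrl_shapes[i])

    def parameters(self) -> list[Tensor]:
        return [self.coef[i][k] for i in range(N_LEVELS) for k in range(3)]

    def _mats(self, grid: VolumeGrid, level: int):
        key = (level, grid.shape, tuple(grid.spacing), tuple(grid.origin))
        if key not in self._mat_cache:
            n_ctrl = self.base_ctrl * 2 ** level
            mats = []
            for ax in range(3):
                pts = grid.origin[ax] + grid.spacing[ax] * np.arange(grid.shape[ax])
                mats.append(collocation_matrix(
                    pts, self.origin[ax], self.origin[ax] + self.extent[ax],
                    n_ctrl))
            self._mat_cache[key] = tuple(mats)
        return self._mat_cache[key]

    def eval_basis(self, grid: VolumeGrid, level: int, component: int) -> Tensor:
        """Dense MBC field e[level, component] on `grid` (differentiable)."""
        if not 0 <= level < N_LEVELS:
            raise ValueError("level must be in 0..2")
        return bspline_apply(self._mats(grid, level), self.coef[level][component])

    def eval_all(self, grid: VolumeGrid) -> list[list[Tensor]]:
        return [[self.eval_basis(grid, i, k) for k in range(3)]
                for i in range(N_LEVELS)]

    def evaluate_point(self, pts: np.ndarray, level: int,
                       component: int) -> np.ndarray:
        """Direct (non-differentiable) evaluation at arbitrary world points."""
        pts = np.atleast_2d(pts)
        n_ctrl = self.base_ctrl * 2 ** level
        mats = [collocation_matrix(pts[:, ax], self.origin[ax],
                                   self.origin[ax] + self.extent[ax], n_ctrl)
                for ax in range(3)]
        c = self.coef[level][component].data
        return np.einsum("ni,nj,nk,ijk->n", mats[0], mats[1], mats[2], c,
                         optimize=True)


def compose_dvf(basis: MBCBasis, scores: np.ndarray,
                grid: VolumeGrid) -> DisplacementField:
    """DVF from basis and one (3 levels, 3 components) score matrix."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (3, 3):
        raise ValueError("scores must have shape (3, 3)")
    vec = np.zeros(grid.shape + (3,))
    for k in range(3):
        for i in range(N_LEVELS):
            vec[..., k] += scores[i, k] * basis.eval_basis(grid, i, k).data
    return DisplacementField(vec, grid.spacing.copy(), grid.origin.copy())


def compose_dvf_tensor(fields: list[list[Tensor]], scores: Tensor) -> Tensor:
    """Differentiable DVF (nx, ny, nz, 3) from cached basis fields and a
    (3, 3) score Tensor (slice of the encoder output)."""
    comps = []
    for k in range(3):
        acc = None
        for i in range(N_LEVELS):
            term = scores[i, k].reshape(1, 1, 1) * fields[i][k]
            acc = term if acc is None else acc + term
        comps.append(acc.reshape(acc.shape + (1,)))
    from .autodiff import concat
    return concat(comps, axis=3)


def warp_tensor(ref: Tensor, dvf: Tensor, grid: VolumeGrid) -> Tensor:
    """Differentiable pull-back warp: out(x) = ref(x + d(x)) on the grid."""
    base = grid.voxel_centers()
    base_vox = (base - grid.origin) / grid.spacing
    coords = Tensor(base_vox) + dvf.reshape(-1, 3) / Tensor(grid.spacing)
    out = grid_sample3(ref, None, coords_tensor=coords)
    return out.reshape(grid.shape)


def warp_volume(ref: VolumeGrid, dvf: DisplacementField) -> VolumeGrid:
    """Trilinear pull-back warp of a volume; out-of-bounds samples are 0."""
    if ref.shape != dvf.shape:
        raise ValueError("reference and DVF grids differ")
    out = warp_tensor(Tensor(ref.values), Tensor(dvf.vectors), ref)
    return ref.like(out.data)


def invert_dvf(dvf: DisplacementField, iterations: int = 3) -> DisplacementField:
    """Fixed-point DVF inversion: v_{n+1}(x) = -d(x + v_n(x)), v_0 = 0.

    Three iterations by default; adequate for smooth respiratory-scale
    fields (the self-consistency loss is built on exactly this premise).
    """
    from ._kernels import trilinear_gather
    base = dvf.origin + dvf.spacing * np.stack(
        np.meshgrid(*[np.arange(s) for s in dvf.shape], indexing="ij"),
        axis=-1)
    base = base.reshape(-1, 3)
    vflat = np.ascontiguousarray(dvf.vectors.reshape(dvf.shape + (3,)))
    inv = np.zeros_like(base)
    for _ in range(iterations):
        coords = (base + inv - dvf.origin) / dvf.spacing
        sampled = trilinear_gather(vflat, np.ascontiguousarray(coords))
        inv = -sampled
    return DisplacementField(inv.reshape(dvf.vectors.shape),
                             dvf.spacing.copy(), dvf.origin.copy())


def invert_dvf_tensor(dvf: Tensor, grid: VolumeGrid,
                      iterations: int = 3) -> Tensor:
    """Differentiable fixed-point inversion (gradients flow through all
    interior lookups of d; no stop-gradient)."""
    base = grid.voxel_centers()
    base_vox = Tensor((base - grid.origin) / grid.spacing)
    spacing = Tensor(grid.spacing)
    dvf_flat = dvf.reshape(-1, 3)
    inv = None
    for _ in range(iterations):
        if inv is None:
            coords = base_vox
        else:
            coords = base_vox + inv / spacing
        sampled = grid_sample3(dvf, None,
                               coords_tensor=coords) if inv is not None \
            else dvf_flat
        inv = -sampled
    return inv.reshape(grid.shape + (3,))


def propagate_mask(mask: np.ndarray, dvf: DisplacementField,
                   threshold: float = 0.5):
    """Warp a binary mask (linear interpolation, then threshold).

    Returns (mask, empty_flag); an empty propagated mask is flagged rather
    than raised so streaming callers can hold the last valid position.
    """
    grid = VolumeGrid(mask.astype(np.float64), dvf.spacing, dvf.origin)
    warped = warp_volume(grid, dvf).values >= threshold
    return warped, not warped.any()


def mask_com(mask: np.ndarray, spacing, origin) -> np.ndarray:
    """Center of mass (mm) of a binary mask: exact fractional centroid."""
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("empty mask has no center of mass")
    return np.asarray(origin) + idx.mean(axis=0) * np.asarray(spacing)
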