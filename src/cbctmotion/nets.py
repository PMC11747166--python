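"""Learnable function approximators: the reference-volume INR and the
convolutional motion encoder.

* :class:`ReferenceINR` — a multi-resolution hash-grid encoder feeding a
  three-layer MLP (widths 32, 32, 1) whose hidden layer uses a periodic
  (sine) activation; maps an mm-coordinate inside the volume bounding box
  to a linear attenuation value.
* :class:`MotionEncoderCNN` — six 3x3 convolution layers (channels 2, 4,
  8, 16, 32, 32, stride 2, each with batch norm + ReLU), adaptive average
  pooling to 4x4 and a single linear layer with nine outputs, reshaped to
  the (level, component) score matrix of the motion model.  The pooling
  makes the head independent of the detector resolution.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (Tensor, adaptive_avg_pool2d, batchnorm2d, concat,
                       conv2d, gather_rows, grid_sample3)
from .grids import VolumeGrid

_HASH_PRIMES = np.array([1, 2654435761, 805459861], dtype=np.uint64)


class HashEncoder:
    """Multi-resolution learnable hash-grid encoding of [0,1]^3 coordinates.

    Levels whose dense grid fits in the table are indexed directly; finer
    levels use the standard spatial-hash with XOR-folded primes.
    """

    def __init__(self, n_levels: int = 8, features: int = 2,
                 log2_table: int = 17, base_resolution: int = 8,
                 growth: float = 1.5, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_levels = n_levels
        self.features = features
        self.table_size = 1 << log2_table
        self.resolutions = [int(np.ceil(base_resolution * growth ** i))
                            for i in range(n_levels)]
        self.tables = [Tensor(rng.uniform(-1e-4, 1e-4,
                                          size=(self.table_size, features)),
                              requires_grad=True)
                       for _ in range(n_levels)]
        self._corner_cache: dict = {}

    @property
    def out_dim(self):
        return self.n_levels * self.features

    def parameters(self):
        return list(self.tables)

    def _indices(self, corners: np.ndarray, res: int) -> np.ndarray:
        if (res + 1) ** 3 <= self.table_size:
            return ((corners[..., 0] * (res + 1) + corners[..., 1])
                    * (res + 1) + corners[..., 2])
        h = (corners[..., 0].astype(np.uint64) * _HASH_PRIMES[0]
             ^ corners[..., 1].astype(np.uint64) * _HASH_PRIMES[1]
             ^ corners[..., 2].astype(np.uint64) * _HASH_PRIMES[2])
        return (h % np.uint64(self.table_size)).astype(np.int64)

    def _corners(self, coords01: np.ndarray):
        """Per-level corner indices and trilinear weights, (n,8) each."""
        per_level = []
        for res in self.resolutions:
            pos = np.clip(coords01, 0.0, 1.0) * res
            base = np.floor(pos).astype(np.int64)
            base = np.minimum(base, res - 1)
            frac = pos - base
            n = len(coords01)
            idx = np.empty((n, 8), dtype=np.int64)
            w = np.empty((n, 8))
            c = 0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        corner = base + np.array([dx, dy, dz])
                        idx[:, c] = self._indices(corner, res)
                        w[:, c] = ((frac[:, 0] if dx else 1 - frac[:, 0])
                                   * (frac[:, 1] if dy else 1 - frac[:, 1])
                                   * (frac[:, 2] if dz else 1 - frac[:, 2]))
                        c += 1
            per_level.append((idx, w))
        return per_level

    def encode(self, coords01: np.ndarray, cache_key=None) -> Tensor:
        """coords01: (n, 3) in [0,1]^3 -> features (n, L*F).

        Corner indices/weights depend only on the coordinates; for repeated
        grids (every training step renders the same voxel centers) they are
        cached under `cache_key`.
        """
        from ._kernels import hash_gather, hash_scatter
        if cache_key is not None and cache_key in self._corner_cache:
            per_level = self._corner_cache[cache_key]
        else:
            per_level = self._corners(coords01)
            if cache_key is not None:
                self._corner_cache[cache_key] = per_level
        feats = []
        for lvl, (idx, w) in enumerate(per_level):
            table = self.tables[lvl]
            out = Tensor(hash_gather(table.data, idx, w),
                         table.requires_grad, (table,))

            def bw(g, table=table, idx=idx, w=w):
                table._accum(hash_scatter(np.ascontiguousarray(g), idx, w,
                                          table.data.shape[0]))
            out._backward = bw
            feats.append(out)
        return concat(feats, axis=1)


class ReferenceINR:
    """Hash-encoded SIREN implicit representation of the reference CBCT."""

    def __init__(self, bbox_lo, bbox_hi, omega0: float = 30.0,
                 hidden: int = 32, seed: int = 0, **hash_kwargs):
        rng = np.random.default_rng(seed)
        self.bbox_lo = np.asarray(bbox_lo, dtype=np.float64)
        self.bbox_hi = np.asarray(bbox_hi, dtype=np.float64)
        self.omega0 = omega0
        self.encoder = HashEncoder(rng=rng, **hash_kwargs)
        d_in = self.encoder.out_dim
        # input layer (linear), sine hidden layer (SIREN init), linear output
        self.w1 = Tensor(rng.uniform(-1, 1, (d_in, hidden)) * np.sqrt(6 / d_in),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = Tensor(rng.uniform(-1, 1, (hidden, hidden))
                         * np.sqrt(6 / hidden) / omega0, requires_grad=True)
        self.b2 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w3 = Tensor(rng.uniform(-1, 1, (hidden, 1)) * np.sqrt(6 / hidden),
                         requires_grad=True)
        self.b3 = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self):
        return self.encoder.parameters() + [self.w1, self.b1, self.w2,
                                            self.b2, self.w3, self.b3]

    def forward(self, coords_mm: np.ndarray, cache_key=None) -> Tensor:
        """Attenuation at world coordinates (n, 3); clamped to the box."""
        span = self.bbox_hi - self.bbox_lo
        c01 = (np.asarray(coords_mm) - self.bbox_lo) / span
        if np.any(c01 < -1e-9) or np.any(c01 > 1 + 1e-9):
            import warnings
            warnings.warn("coordinates outside the training bounding box "
                          "are clamped", stacklevel=2)
        feats = self.encoder.encode(np.clip(c01, 0.0, 1.0), cache_key=cache_key)
        h = feats @ self.w1 + self.b1
        h = ((h @ self.w2 + self.b2) * self.omega0).sin()
        out = h @ self.w3 + self.b3
        return out.reshape(-1)

    def render(self, grid: VolumeGrid) -> Tensor:
        """Evaluate all voxel centers of `grid` (differentiable)."""
        key = (grid.shape, tuple(grid.spacing), tuple(grid.origin))
        return self.forward(grid.voxel_centers(), cache_key=key) \
            .reshape(grid.shape)

    def render_volume(self, grid: VolumeGrid) -> VolumeGrid:
        """Non-differentiable convenience wrapper returning a VolumeGrid."""
        return grid.like(self.render(grid).data)


_CNN_CHANNELS = (2, 4, 8, 16, 32, 32)


class MotionEncoderCNN:
    """Projection -> nine motion-basis scores (3 levels x 3 components)."""

    def __init__(self, seed: int = 0, output_scale: float = 10.0):
        rng = np.random.default_rng(seed)
        self.output_scale = output_scale   # mm-scale of respiratory scores
        self.convs = []
        c_in = 1
        for c_out in _CNN_CHANNELS:
            fan = c_in * 9
            w = Tensor(rng.normal(0, np.sqrt(2.0 / fan), (c_out, c_in, 3, 3)),
                       requires_grad=True)
            b = Tensor(np.zeros(c_out), requires_grad=True)
            gamma = Tensor(np.ones(c_out), requires_grad=True)
            beta = Tensor(np.zeros(c_out), requires_grad=True)
            self.convs.append({"w": w, "b": b, "gamma": gamma, "beta": beta,
                               "run_mean": np.zeros(c_out),
                               "run_var": np.ones(c_out)})
            c_in = c_out
        d_flat = _CNN_CHANNELS[-1] * 16
        self.w_head = Tensor(rng.normal(0, np.sqrt(1.0 / d_flat), (d_flat, 9)),
                             requires_grad=True)
        self.b_head = Tensor(np.zeros(9), requires_grad=True)
        self.training = True
        self.bn_momentum = 0.1

    def train(self):
        self.training = True

    def eval(self):
        self.training = False

    def parameters(self):
        ps = []
        for c in self.convs:
            ps += [c["w"], c["b"], c["gamma"], c["beta"]]
        return ps + [self.w_head, self.b_head]

    def forward(self, projections: np.ndarray | Tensor) -> Tensor:
        """projections: (batch, H, W) normalized line integrals ->
        scores Tensor (batch, 3, 3) indexed (level, component)."""
        x = projections if isinstance(projections, Tensor) \
            else Tensor(projections)
        if np.isnan(x.data).any():
            raise ValueError("NaN in input projection")
        x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        for c in self.convs:
            x = conv2d(x, c["w"], c["b"], stride=2, pad=1)
            x = batchnorm2d(x, c["gamma"], c["beta"], c["run_mean"],
                            c["run_var"], training=self.training,
                            momentum=self.bn_momentum)
            x = x.relu()
        x = adaptive_avg_pool2d(x, (4, 4))
        x = x.reshape(x.shape[0], -1)
        out = (x @ self.w_head + self.b_head) * self.output_scale
        return out.reshape(x.shape[0], 3, 3)

    def recalibrate_bn(self, projections: np.ndarray):
        """Replace batch-norm running statistics with the population
        statistics of `projections` (one full-batch training-mode pass).
        Keeps eval-mode inference consistent with the batch statistics the
        network saw during training, which matters for short schedules."""
        was_training, was_momentum = self.training, self.bn_momentum
        self.training, self.bn_momentum = True, 1.0
        try:
            self.forward(np.asarray(projections))
        finally:
            self.training, self.bn_momentum = was_training, was_momentum

    def encode(self, projection: np.ndarray) -> np.ndarray:
        """Deterministic single-projection inference (eval mode)."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(np.asarray(projection)[None]).data[0]
        finally:
            self.training = was_training
        return out
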