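"""Numba-compiled inner loops for trilinear sampling and its adjoints.

These are the only performance-critical kernels in the package: the DRR
projector, the volume warper and the displacement-field inverter all reduce
to gathering (and scatter-adding) trilinearly interpolated values at large
batches of fractional grid coordinates.  Loops are sequential, hence
bit-deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=False)
def trilinear_gather(vol: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """vol: (X, Y, Z, C); coords: (n, 3) voxel units. Out-of-grid -> 0."""
    X, Y, Z, C = vol.shape
    n = coords.shape[0]
    out = np.zeros((n, C), dtype=vol.dtype)
    for i in range(n):
        x, y, z = coords[i, 0], coords[i, 1], coords[i, 2]
        x0 = int(np.floor(x)); y0 = int(np.floor(y)); z0 = int(np.floor(z))
        fx = x - x0; fy = y - y0; fz = z - z0
        for dx in range(2):
            xi = x0 + dx
            if xi < 0 or xi >= X:
                continue
            wx = fx if dx == 1 else 1.0 - fx
            for dy in range(2):
                yi = y0 + dy
                if yi < 0 or yi >= Y:
                    continue
                wy = fy if dy == 1 else 1.0 - fy
                for dz in range(2):
                    zi = z0 + dz
                    if zi < 0 or zi >= Z:
                        continue
                    w = wx * wy * (fz if dz == 1 else 1.0 - fz)
                    for c in range(C):
                        out[i, c] += w * vol[xi, yi, zi, c]
    return out


@njit(cache=False, fastmath=False)
def trilinear_scatter(grad_out: np.ndarray, coords: np.ndarray,
                      X: int, Y: int, Z: int) -> np.ndarray:
    """Adjoint of the gather w.r.t. the volume: scatter-add of weights."""
    n, C = grad_out.shape
    acc = np.zeros((X, Y, Z, C), dtype=grad_out.dtype)
    for i in range(n):
        x, y, z = coords[i, 0], coords[i, 1], coords[i, 2]
        x0 = int(np.floor(x)); y0 = int(np.floor(y)); z0 = int(np.floor(z))
        fx = x - x0; fy = y - y0; fz = z - z0
        for dx in range(2):
            xi = x0 + dx
            if xi < 0 or xi >= X:
                continue
            wx = fx if dx == 1 else 1.0 - fx
            for dy in range(2):
                yi = y0 + dy
                if yi < 0 or yi >= Y:
                    continue
                wy = fy if dy == 1 else 1.0 - fy
                for dz in range(2):
                    zi = z0 + dz
                    if zi < 0 or zi >= Z:
                        continue
                    w = wx * wy * (fz if dz == 1 else 1.0 - fz)
                    for c in range(C):
                        acc[xi, yi, zi, c] += w * grad_out[i, c]
    return acc


@njit(cache=False, fastmath=False)
def trilinear_coord_grad(vol: np.ndarray, coords: np.ndarray,
                         grad_out: np.ndarray) -> np.ndarray:
    """Gradient of the gather w.r.t. the coordinates (n, 3)."""
    X, Y, Z, C = vol.shape
    n = coords.shape[0]
    gc = np.zeros((n, 3), dtype=vol.dtype)
    for i in range(n):
        x, y, z = coords[i, 0], coords[i, 1], coords[i, 2]
        x0 = int(np.floor(x)); y0 = int(np.floor(y)); z0 = int(np.floor(z))
        fx = x - x0; fy = y - y0; fz = z - z0
        for dx in range(2):
            xi = x0 + dx
            if xi < 0 or xi >= X:
                continue
            wx = fx if dx == 1 else 1.0 - fx
            sx = 1.0 if dx == 1 else -1.0
            for dy in range(2):
                yi = y0 + dy
                if yi < 0 or yi >= Y:
                    continue
                wy = fy if dy == 1 else 1.0 - fy
                sy = 1.0 if dy == 1 else -1.0
                for dz in range(2):
                    zi = z0 + dz
                    if zi < 0 or zi >= Z:
                        continue
                    wz = fz if dz == 1 else 1.0 - fz
                    sz = 1.0 if dz == 1 else -1.0
                    dot = 0.0
                    for c in range(C):
                        dot += grad_out[i, c] * vol[xi, yi, zi, c]
                    gc[i, 0] += dot * sx * wy * wz
                    gc[i, 1] += dot * wx * sy * wz
                    gc[i, 2] += dot * wx * wy * sz
    return gc


@njit(cache=False, fastmath=False)
def hash_gather(table: np.ndarray, idx: np.ndarray,
                w: np.ndarray) -> np.ndarray:
    """Weighted 8-corner feature gather: table (T,F), idx/w (n,8) -> (n,F)."""
    n = idx.shape[0]
    F = table.shape[1]
    out = np.zeros((n, F), dtype=table.dtype)
    for i in range(n):
        for c in range(8):
            j = idx[i, c]
            wv = w[i, c]
            for f in range(F):
                out[i, f] += wv * table[j, f]
    return out


@njit(cache=False, fastmath=False)
def hash_scatter(grad: np.ndarray, idx: np.ndarray, w: np.ndarray,
                 T: int) -> np.ndarray:
    """Adjoint of hash_gather w.r.t. the table."""
    n, F = grad.shape
    acc = np.zeros((T, F), dtype=grad.dtype)
    for i in range(n):
        for c in range(8):
            j = idx[i, c]
            wv = w[i, c]
            for f in range(F):
                acc[j, f] += wv * grad[i, f]
    return acc
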