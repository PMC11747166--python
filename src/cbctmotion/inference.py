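"""Online stage: single projection in, motion scores / DVF / volume out.

The motion encoder is angle-agnostic: the gantry angle of an incoming
projection is metadata only (used to project the 3-D target position onto
the detector), never an input to the network.  Per-frame work is one CNN
pass, a B-spline composition and one volume warp; the rendered reference
volume is cached once.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .geometry import ProjectionStack
from .grids import VolumeGrid
from .motion import compose_dvf, mask_com, propagate_mask, warp_volume
from .training import TrainedModel


@dataclass
class TrackedTarget:
    """Per-frame tumor localization results."""

    reference_mask: np.ndarray
    masks: np.ndarray             # (n, nx, ny, nz) bool
    coms_mm: np.ndarray           # (n, 3)
    detector_uv_mm: np.ndarray    # (n, 2) projected COM, detector coords
    empty_flags: np.ndarray       # frames where propagation emptied the mask
    wall_times_s: np.ndarray      # per-frame latency (reported, not asserted)


def estimate_frame(model: TrainedModel, projection: np.ndarray,
                   angle_deg: float):
    """Estimate (scores, DVF, volume) from one projection.

    The projection must come from the training geometry; it is normalized
    with the stored training statistics.
    """
    if projection.shape != tuple(model.geometry.detector_shape):
        raise ValueError("projection shape differs from training geometry")
    scores = model.cnn.encode(model.normalize(projection))
    dvf = compose_dvf(model.basis, scores, model.grid_hi)
    volume = warp_volume(model.reference_volume(), dvf)
    return scores, dvf, volume


def localize_target(model: TrainedModel, mask: np.ndarray,
                    stream: ProjectionStack) -> TrackedTarget:
    """Propagate a reference-grid target mask through a projection stream.

    `mask` may be binary or a fractional occupancy in [0, 1]; propagation
    warps the float mask and thresholds at 0.5.  If a propagated mask comes
    out empty the previous valid center of mass is held and the frame is
    flagged.
    """
    mask = np.asarray(mask, dtype=np.float64)
    if mask.shape != model.grid_hi.shape:
        raise ValueError("mask must live on the reference grid")
    n = len(stream)
    masks = np.zeros((n,) + mask.shape, dtype=bool)
    coms = np.zeros((n, 3))
    uv = np.zeros((n, 2))
    flags = np.zeros(n, dtype=bool)
    times = np.zeros(n)
    last_com = mask_com(mask >= 0.5, model.grid_hi.spacing,
                        model.grid_hi.origin)
    for k in range(n):
        t0 = time.perf_counter()
        scores = model.cnn.encode(model.normalize(stream.frames[k]))
        dvf = compose_dvf(model.basis, scores, model.grid_hi)
        warped, empty = propagate_mask(mask, dvf)
        if empty:
            flags[k] = True
            coms[k] = last_com
        else:
            masks[k] = warped
            coms[k] = mask_com(warped, model.grid_hi.spacing,
                               model.grid_hi.origin)
            last_com = coms[k]
        times[k] = time.perf_counter() - t0
        uv[k] = model.geometry.project_points(coms[k],
                                              stream.angles_deg[k])[0]
    return TrackedTarget(mask >= 0.5, masks, coms, uv, flags, times)
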