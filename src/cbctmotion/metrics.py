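"""Evaluation metrics: relative error, SSIM, center-of-mass error, Dice,
Amsterdam-Shroud trace extraction and Pearson correlation.

The Amsterdam-Shroud (AS) method extracts a 1-D respiratory surrogate
directly in the projection domain: vertical (superior-inferior) intensity
gradients of each projection are integrated laterally over a region of
interest, the resulting (SI row x frame) image is contrast enhanced, and a
sub-pixel edge position is tracked per frame.  It needs no ground truth and
is therefore the comparison protocol when only measured projections exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .grids import VolumeGrid
from .motion import mask_com


def relative_error(estimated, ground_truth) -> float:
    """Frame-averaged normalized L2 error.

    Accepts single volumes/arrays or sequences of them; each frame
    contributes ||I - I_gt||_2 / ||I_gt||_2.
    """
    def _values(v):
        return v.values if isinstance(v, VolumeGrid) else np.asarray(v)

    if isinstance(estimated, (VolumeGrid, np.ndarray)):
        estimated, ground_truth = [estimated], [ground_truth]
    res = []
    for est, gt in zip(estimated, ground_truth, strict=True):
        est, gt = _values(est), _values(gt)
        denom = np.linalg.norm(gt)
        if denom == 0:
            raise ZeroDivisionError("ground truth volume has zero norm")
        res.append(np.linalg.norm(est - gt) / denom)
    return float(np.mean(res))


def ssim3d(a, b, data_range: float | None = None) -> float:
    """SSIM with an 11^3 Gaussian window (sigma 1.5); dynamic range taken
    from the second (ground-truth) argument unless given."""
    av = a.values if isinstance(a, VolumeGrid) else np.asarray(a)
    bv = b.values if isinstance(b, VolumeGrid) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError("volume shape mismatch")
    if data_range is None:
        data_range = float(bv.max() - bv.min())
        if data_range == 0:
            return 1.0 if np.allclose(av, bv) else 0.0
    win = min(11, min(av.shape) - (1 - min(av.shape) % 2))  # odd, <= extent
    return float(structural_similarity(
        av, bv, data_range=data_range, gaussian_weights=True, sigma=1.5,
        win_size=win, use_sample_covariance=False, K1=0.01, K2=0.03))


def come(mask_a: np.ndarray, mask_b: np.ndarray, spacing) -> float:
    """Euclidean distance (mm) between binary-mask centroids."""
    spacing = np.asarray(spacing, dtype=np.float64)
    ca = mask_com(mask_a, spacing, np.zeros(3))
    cb = mask_com(mask_b, spacing, np.zeros(3))
    return float(np.linalg.norm(ca - cb))


def dsc(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A.B| / (|A| + |B|)."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("mask shape mismatch")
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / total)


def amsterdam_shroud(frames: np.ndarray, pixel_pitch_mm: float,
                     roi_cols: slice | None = None,
                     roi_rows: slice | None = None) -> np.ndarray:
    """Respiratory trace (mm, zero mean) from a projection stack.

    frames: (n, rows v, cols u) with rows parallel to SI.  Per frame the
    vertical derivative image is summed over the ROI columns; the (row x
    frame) AS image is per-column z-scored with negative values clipped
    (contrast enhancement), and the per-frame edge is the parabolic-refined
    argmax converted to mm via the detector pitch.
    """
    frames = np.asarray(frames, dtype=np.float64)
    n, nv, nu = frames.shape
    roi_cols = roi_cols or slice(None)
    roi_rows = roi_rows or slice(None)
    grad = np.diff(frames, axis=1)                 # d/dv
    shroud = grad[:, :, roi_cols].sum(axis=2).T    # (rows-1, n)
    shroud = shroud[roi_rows, :]
    if shroud.size == 0:
        raise ValueError("empty AS region of interest")
    # contrast enhancement: per-frame standardization, positive part
    mu = shroud.mean(axis=0, keepdims=True)
    sd = shroud.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    enh = np.clip((shroud - mu) / sd, 0.0, None)

    rows = np.argmax(enh, axis=0).astype(np.float64)
    for k in range(n):                             # parabolic refinement
        i = int(rows[k])
        if 0 < i < enh.shape[0] - 1:
            y0, y1, y2 = enh[i - 1, k], enh[i, k], enh[i + 1, k]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                rows[k] += 0.5 * (y0 - y2) / denom
    trace = rows * pixel_pitch_mm
    return trace - trace.mean()


def projection_shift_trace(frames: np.ndarray, pixel_pitch_mm: float,
                           detrend_window: int = 25,
                           max_lag: int = 6) -> np.ndarray:
    """Rotation-robust respiratory surrogate from a rotating projection
    stack (arbitrary units, zero median).

    On a rotating gantry the absolute shroud-edge position is dominated by
    view-angle appearance changes.  Between *adjacent* frames, however,
    the view changes little while breathing shifts the anatomy vertically:
    cross-correlating consecutive vertical-gradient profiles yields
    incremental SI shifts whose cumulative sum, high-pass filtered with a
    moving median (window in frames, spanning a few breathing cycles of
    the slow rotation trend), isolates the breathing phase.  Used for
    respiratory gating; amplitudes are not calibrated.
    """
    from scipy.ndimage import median_filter
    frames = np.asarray(frames, dtype=np.float64)
    prof = np.diff(frames, axis=1).sum(axis=2)          # (n, nv-1)
    n, nv = prof.shape
    shifts = np.zeros(n)
    for k in range(1, n):
        a = prof[k - 1] - prof[k - 1].mean()
        b = prof[k] - prof[k].mean()
        cc = np.array([np.dot(a[max(0, -l):nv - max(0, l)],
                              b[max(0, l):nv - max(0, -l)])
                       for l in range(-max_lag, max_lag + 1)])
        i = int(np.argmax(cc))
        lag = float(i - max_lag)
        if 0 < i < len(cc) - 1:
            y0, y1, y2 = cc[i - 1], cc[i], cc[i + 1]
            den = y0 - 2 * y1 + y2
            if den != 0:
                lag += 0.5 * (y0 - y2) / den
        shifts[k] = lag
    cum = np.cumsum(shifts) * pixel_pitch_mm
    trend = median_filter(cum, size=detrend_window, mode="nearest")
    out = cum - trend
    return out - np.median(out)


def pearson(trace_a: np.ndarray, trace_b: np.ndarray) -> float:
    """Sample Pearson correlation coefficient."""
    a = np.asarray(trace_a, dtype=np.float64)
    b = np.asarray(trace_b, dtype=np.float64)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("traces must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ZeroDivisionError("zero-variance trace")
    return float(stats.pearsonr(a, b)[0])


@dataclass
class MetricReport:
    """Per-frame metrics with mean +/- SD summaries."""

    re_frames: list = field(default_factory=list)
    ssim_frames: list = field(default_factory=list)
    come_mm_frames: list = field(default_factory=list)
    dsc_frames: list = field(default_factory=list)
    as_pearson_r: float | None = None
    as_error_mm: list = field(default_factory=list)

    @staticmethod
    def _summary(vals):
        if not vals:
            return None
        return {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}

    def summary(self) -> dict:
        out = {}
        for name, vals in [("re", self.re_frames), ("ssim", self.ssim_frames),
                           ("come_mm", self.come_mm_frames),
                           ("dsc", self.dsc_frames),
                           ("as_error_mm", self.as_error_mm)]:
            s = self._summary(vals)
            if s is not None:
                out[name] = s
        if self.as_pearson_r is not None:
            out["as_pearson_r"] = self.as_pearson_r
        return out


def as_localization_error(trace_ref: np.ndarray,
                          trace_est: np.ndarray) -> np.ndarray:
    """Per-frame |difference| of two AS traces after joint zero-mean
    alignment (the projection-domain localization protocol)."""
    a = np.asarray(trace_ref) - np.mean(trace_ref)
    b = np.asarray(trace_est) - np.mean(trace_est)
    return np.abs(a - b)
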