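"""Joint reconstruction / motion-encoder training.

The training solves two coupled tasks from a single pre-treatment cone-beam
scan: (1) reconstruct a reference volume plus a low-rank motion model such
that DRRs of the warped reference match the measured projections, and
(2) train the CNN motion encoder to regress the motion scores from single
projections, generalizing over gantry angle and motion amplitude through
on-the-fly augmentation.

The progressive schedule has seven stages at two spatial resolutions:

=====  ======  ==========  ========================================  =========
stage  epochs  resolution  active losses                             augment
=====  ======  ==========  ========================================  =========
I-a      400   coarse      image similarity                          --
I-b      700   coarse      projection similarity + TV                --
I-c     1700   coarse      projection + TV + MBC + ZMS + SC          --
II-a    1000   fine        image similarity (vs upsampled I-ref)     --
II-b    1000   fine        projection + TV + augmentation            angle
II-c    1000   fine        projection + TV + MBC + ZMS + SC + aug    angle
II-d    1000   fine        augmentation only (INR & basis frozen)    motion+angle
=====  ======  ==========  ========================================  =========

with loss weights: similarity 1, TV 2e-4, MBC 1, ZMS 1e-3, SC 1e3,
augmentation 1e-4, and batches of 32 projections.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .autodiff import Adam, Tensor, concat
from .geometry import ProjectionStack, ScanGeometry, fdk_reconstruct, \
    project_tensor
from .grids import VolumeGrid
from .motion import MBCBasis, compose_dvf_tensor, invert_dvf_tensor, \
    warp_tensor
from .nets import MotionEncoderCNN, ReferenceINR

LOSS_WEIGHTS = {"sim": 1.0, "tv": 2e-4, "mbc": 1.0, "zms": 1e-3,
                "sc": 1e3, "aug": 1e-4}
N_BATCH = 32

STAGE_TABLE = [
    # name, epochs, res, lr_inr, lr_cnn, lr_basis, losses, augmentation
    ("I-a", 400, "lo", 4e-4, 0.0, 0.0, ("im",), None),
    ("I-b", 700, "lo", 4e-5, 0.0, 0.0, ("prj", "tv"), None),
    ("I-c", 1700, "lo", 1e-5, 1e-3, 1e-3,
     ("prj", "tv", "mbc", "zms", "sc"), None),
    ("II-a", 1000, "hi", 1e-3, 0.0, 0.0, ("im",), None),
    ("II-b", 1000, "hi", 4e-4, 0.0, 0.0, ("prj", "tv", "aug"), "angle"),
    ("II-c", 1000, "hi", 1e-4, 1e-4, 1e-4,
     ("prj", "tv", "mbc", "zms", "sc", "aug"), "angle"),
    ("II-d", 1000, "hi", 0.0, 1e-4, 0.0, ("aug",), "motion_angle"),
]


@dataclass
class StageConfig:
    name: str
    epochs: int
    resolution: str               # "lo" (coarse) or "hi" (fine)
    lr_inr: float
    lr_cnn: float
    lr_basis: float
    losses: tuple
    augmentation: str | None      # None | "angle" | "motion_angle"


@dataclass
class AugmentationConfig:
    """Score resampling ranges: w' = r1(p) * r2(i,k) * w with r1 shared
    across the nine channels of a frame and r2 independent per channel."""
    r1_range: tuple = (0.6, 2.0)
    r2_range: tuple = (0.8, 1.2)


@dataclass
class TrainingSchedule:
    stages: list
    weights: dict = field(default_factory=lambda: dict(LOSS_WEIGHTS))
    n_batch: int = N_BATCH
    sc_subsample: int = N_BATCH   # frames per step entering the SC term
    gated_warmstart: bool = False  # FDK warm start from dwell-phase frames
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)

    @classmethod
    def full_scale(cls) -> "TrainingSchedule":
        return cls([StageConfig(*row) for row in STAGE_TABLE])

    def scaled(self, epoch_factor: float,
               lr_factor: float | None = None) -> "TrainingSchedule":
        """Shorten every stage by `epoch_factor`; learning rates are scaled
        by `lr_factor` (default: `epoch_factor`) so the total Adam parameter
        travel stays comparable to the full schedule."""
        if lr_factor is None:
            lr_factor = epoch_factor
        stages = [replace(s, epochs=max(int(round(s.epochs / epoch_factor)), 1),
                          lr_inr=s.lr_inr * lr_factor,
                          lr_cnn=s.lr_cnn * lr_factor,
                          lr_basis=s.lr_basis * lr_factor)
                  for s in self.stages]
        return TrainingSchedule(stages, dict(self.weights), self.n_batch,
                                self.sc_subsample, self.gated_warmstart,
                                self.augment)


# ---------------------------------------------------------------------------
# loss functions

def loss_image(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error between two volumes on the same grid."""
    if pred.shape != np.shape(target):
        raise ValueError("volume shape mismatch")
    return ((pred - Tensor(np.asarray(target))) ** 2).mean()


def loss_projection(drrs: Tensor, measured: np.ndarray) -> Tensor:
    """Mean squared error between batched DRRs and measured projections."""
    if drrs.shape != np.shape(measured):
        raise ValueError("projection batch shape mismatch")
    return ((drrs - Tensor(np.asarray(measured))) ** 2).mean()


def loss_tv(volume: Tensor, eps: float = 1e-12) -> Tensor:
    """Mean gradient-vector magnitude (forward differences, zero at the far
    boundary)."""
    nx, ny, nz = volume.shape
    zx = Tensor(np.zeros((1, ny, nz)))
    zy = Tensor(np.zeros((nx, 1, nz)))
    zz = Tensor(np.zeros((nx, ny, 1)))
    gx = concat([volume[1:, :, :] - volume[:-1, :, :], zx], axis=0)
    gy = concat([volume[:, 1:, :] - volume[:, :-1, :], zy], axis=1)
    gz = concat([volume[:, :, 1:] - volume[:, :, :-1], zz], axis=2)
    return (gx ** 2 + gy ** 2 + gz ** 2 + eps).sqrt().mean() - np.sqrt(eps)


def loss_mbc(fields: list[list[Tensor]]) -> Tensor:
    """Ortho-normality penalty on the motion basis components.

    Inner products are means over the voxel-grid samples, a grid-size-
    invariant discretization: <e, f> = mean_l e(x_l) f(x_l).
    """
    total = None
    n_levels = len(fields)
    for k in range(3):
        for i in range(n_levels):
            e_i = fields[i][k]
            norm = (e_i * e_i).mean()
            term = (norm - 1.0) ** 2
            for j in range(i + 1, n_levels):
                dot = (e_i * fields[j][k]).mean()
                term = term + dot ** 2
            total = term if total is None else total + term
    return total * (1.0 / (3 * n_levels))


def loss_zms(batch_scores: Tensor, out_of_batch_sum: np.ndarray,
             n_projections: int) -> Tensor:
    """Zero-mean score penalty over the full projection set.

    The mean over all N_p projections combines the current batch's scores
    (with gradients) and the cached scores of out-of-batch frames.
    """
    mean = (batch_scores.sum(axis=0) + Tensor(out_of_batch_sum)) \
        * (1.0 / n_projections)
    return (mean ** 2).mean()


def loss_self_consistency(ref: Tensor, dynamic: Tensor, dvf: Tensor,
                          grid: VolumeGrid, iterations: int = 3) -> Tensor:
    """Deforming the dynamic volume by the inverse DVF must return the
    reference: mean |I(x + d^-1(x)) - I_ref(x)|^2 (one frame)."""
    inv = invert_dvf_tensor(dvf, grid, iterations=iterations)
    returned = warp_tensor(dynamic, inv, grid)
    return ((returned - ref) ** 2).mean()


def sample_augmented_scores(scores: np.ndarray, config: AugmentationConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Random motion-state resampling w' = r1(p) r2(i,k) w (batch, 3, 3)."""
    scores = np.asarray(scores)
    r1 = rng.uniform(*config.r1_range, size=(scores.shape[0], 1, 1))
    r2 = rng.uniform(*config.r2_range, size=scores.shape)
    return r1 * r2 * scores


def loss_augmentation(predicted: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared score error over the batch and nine channels."""
    if predicted.shape != np.shape(target):
        raise ValueError("score batch shape mismatch")
    return ((predicted - Tensor(np.asarray(target))) ** 2).mean()


# ---------------------------------------------------------------------------
# trained-model container

@dataclass
class TrainedModel:
    inr: ReferenceINR
    basis: MBCBasis
    cnn: MotionEncoderCNN
    grid_hi: VolumeGrid
    grid_lo: VolumeGrid
    geometry: ScanGeometry
    norm_lo: float
    norm_hi: float
    solved_scores: np.ndarray     # (N_p, 3, 3)
    seed: int = 0
    reference_cache: np.ndarray | None = None

    def normalize(self, projections: np.ndarray) -> np.ndarray:
        return (np.asarray(projections) - self.norm_lo) \
            / (self.norm_hi - self.norm_lo)

    def reference_volume(self) -> VolumeGrid:
        if self.reference_cache is None:
            self.reference_cache = self.inr.render(self.grid_hi).data
        return self.grid_hi.like(self.reference_cache)


# ---------------------------------------------------------------------------
# trainer

def _upsample_trilinear(values: np.ndarray, src: VolumeGrid,
                        dst: VolumeGrid) -> np.ndarray:
    pts = dst.voxel_centers()
    idx = ((pts - src.origin) / src.spacing).T.reshape(3, *dst.shape)
    return map_coordinates(values, idx, order=1, mode="nearest")


class _Trainer:
    def __init__(self, stack: ProjectionStack, geometry: ScanGeometry,
                 schedule: TrainingSchedule, grid_hi: VolumeGrid,
                 seed: int, step_mm: float | None, log: list,
                 grid_lo: VolumeGrid | None = None,
                 warmstart_volume: np.ndarray | None = None):
        self.stack = stack
        self.geometry = geometry
        self.schedule = schedule
        self.grid_hi = grid_hi
        if grid_lo is None:
            lo_shape = tuple(max(s // 2, 2) for s in grid_hi.shape)
            grid_lo = VolumeGrid.centered(lo_shape, grid_hi.spacing * 2)
        self.grid_lo = grid_lo
        self.seed = seed
        self.step_mm = step_mm
        self.log = log

        self.norm_lo = float(stack.frames.min())
        self.norm_hi = float(stack.frames.max())
        if self.norm_hi <= self.norm_lo:
            self.norm_hi = self.norm_lo + 1.0

        margin = np.maximum(grid_hi.spacing, self.grid_lo.spacing)
        bb_lo = grid_hi.origin - margin
        bb_hi = grid_hi.origin + grid_hi.extent_mm + margin
        self.inr = ReferenceINR(bb_lo, bb_hi,
                                seed=int(np.random.default_rng([seed, 1])
                                         .integers(2 ** 31)))
        self.cnn = MotionEncoderCNN(
            seed=int(np.random.default_rng([seed, 2]).integers(2 ** 31)))
        self.basis = MBCBasis.for_volume(grid_hi)
        self._init_basis(np.random.default_rng([seed, 3]))

        n = len(stack)
        self.solved_scores = np.zeros((n, 3, 3))
        self.normalized = (stack.frames - self.norm_lo) \
            / (self.norm_hi - self.norm_lo)
        self.proj_cache: dict = {}
        self.i_app_lo = None
        self.warmstart_volume = warmstart_volume

    def _init_basis(self, rng):
        """Random smooth coefficients, each field normalized to unit
        mean-square on the fine grid (the MBC loss then maintains it)."""
        self.basis.init_random(rng)
        for i in range(3):
            for k in range(3):
                f = self.basis.eval_basis(self.grid_hi, i, k).data
                rms = np.sqrt((f ** 2).mean())
                if rms > 0:
                    self.basis.coef[i][k].data /= rms

    # -- helpers -----------------------------------------------------------
    def grid(self, stage: StageConfig) -> VolumeGrid:
        return self.grid_lo if stage.resolution == "lo" else self.grid_hi

    def _fdk_warmstart(self):
        if self.warmstart_volume is not None:
            # externally supplied warm-start target (e.g. the simulator's
            # known reference anatomy, as an oracle-reference diagnostic)
            self.i_app_lo = np.asarray(self.warmstart_volume, dtype=float)
            return
        stack = self.stack
        if self.schedule.gated_warmstart:
            # respiratory-gated warm start: extract the breathing surrogate
            # from the projections themselves and reconstruct only frames
            # near the dwell phase, giving a sharper (less motion-blurred)
            # reference for the subsequent joint solve
            from .metrics import projection_shift_trace
            trace = projection_shift_trace(stack.frames,
                                           self.geometry.pixel_pitch_mm)
            band = 0.22 * (trace.max() - trace.min())
            keep = np.abs(trace - np.median(trace)) <= band
            if keep.sum() >= 24:                 # enough angular coverage
                from .geometry import ProjectionStack, ScanGeometry
                geo = ScanGeometry(self.geometry.sad_mm,
                                   self.geometry.sdd_mm,
                                   self.geometry.detector_shape,
                                   self.geometry.pixel_pitch_mm,
                                   angles_deg=stack.angles_deg[keep],
                                   timestamps_s=stack.timestamps_s[keep])
                stack = ProjectionStack(stack.frames[keep],
                                        stack.angles_deg[keep],
                                        stack.timestamps_s[keep], geo)
        rec = fdk_reconstruct(stack, stack.geometry, self.grid_lo).values
        if self.schedule.gated_warmstart:
            # mild smoothing suppresses the view-undersampling streaks of
            # the gated reconstruction (high-frequency) at a small cost in
            # edge sharpness
            from scipy.ndimage import gaussian_filter
            rec = gaussian_filter(rec, sigma=0.8)
        self.i_app_lo = rec

    def _batches(self, n: int, rng) -> list[np.ndarray]:
        order = rng.permutation(n)
        nb = self.schedule.n_batch
        return [order[i:i + nb] for i in range(0, n, nb)]

    def _cnn_scores(self, frame_idx: np.ndarray, training: bool) -> Tensor:
        self.cnn.training = training
        return self.cnn.forward(self.normalized[frame_idx])

    def _dynamic_volume(self, ref: Tensor, fields, score_slice: Tensor,
                        grid: VolumeGrid):
        dvf = compose_dvf_tensor(fields, score_slice)
        return warp_tensor(ref, dvf, grid), dvf

    def _augmented_sample(self, ref_np: np.ndarray, fields_np,
                          scores: np.ndarray, grid: VolumeGrid,
                          angle: float, mode: str,
                          rng) -> tuple[np.ndarray, np.ndarray]:
        """One augmentation pair: (normalized DRR at `angle`, target scores).

        `angle_only` re-projects the solved dynamic volume; `motion_angle`
        first resamples the scores (random motion state), then projects.
        """
        if mode == "motion_angle":
            target = sample_augmented_scores(scores[None], self.schedule.augment,
                                             rng)[0]
        else:
            target = scores
        vec = np.zeros(grid.shape + (3,))
        for k in range(3):
            for i in range(3):
                vec[..., k] += target[i, k] * fields_np[i][k]
        from .motion import warp_volume
        from .grids import DisplacementField
        vol = warp_volume(grid.like(ref_np),
                          DisplacementField(vec, grid.spacing, grid.origin))
        drr = project_tensor(Tensor(vol.values), grid, self.geometry, angle,
                             step_mm=self.step_mm).data
        return (drr - self.norm_lo) / (self.norm_hi - self.norm_lo), target

    # -- stage loop ---------------------------------------------------------
    def run_stage(self, stage: StageConfig, stage_idx: int):
        w = self.schedule.weights
        grid = self.grid(stage)
        n = len(self.stack)
        rng_batch = np.random.default_rng([self.seed, 10 + stage_idx])
        rng_aug = np.random.default_rng([self.seed, 100 + stage_idx])

        if stage.name == "I-a" and self.i_app_lo is None:
            self._fdk_warmstart()
        if stage.name == "II-a":
            lo_ref = self.inr.render(self.grid_lo).data
            self.i_app_hi = _upsample_trilinear(lo_ref, self.grid_lo,
                                                self.grid_hi)

        opt = Adam({"inr": self.inr.parameters(),
                    "cnn": self.cnn.parameters(),
                    "basis": self.basis.parameters()},
                   {"inr": stage.lr_inr, "cnn": stage.lr_cnn,
                    "basis": stage.lr_basis})
        train_cnn = stage.lr_cnn > 0

        frozen = stage.name == "II-d"
        need_render = any(k in stage.losses for k in ("im", "prj", "tv", "sc"))
        need_motion = any(k in stage.losses for k in ("mbc", "zms", "sc")) \
            or ("prj" in stage.losses and stage.name != "I-b")
        if frozen:
            ref_frozen = self.inr.render(grid).data
            fields_frozen = [[self.basis.eval_basis(grid, i, k).data
                              for k in range(3)] for i in range(3)]

        for epoch in range(stage.epochs):
            for batch in self._batches(n, rng_batch):
                losses = {}
                opt.zero_grad()

                # shared upstream graphs, re-entered once per step through
                # leaf "junction" tensors so per-frame graphs can be freed
                # right after their backward pass
                ref = fields = scores = None
                ref_j = fields_j = scores_j = None
                if need_render and not frozen:
                    ref = self.inr.render(grid)
                    ref_j = Tensor(ref.data, requires_grad=True)
                if need_motion and not frozen:
                    fields = self.basis.eval_all(grid)
                    fields_j = [[Tensor(fields[i][k].data, requires_grad=True)
                                 for k in range(3)] for i in range(3)]
                    scores = self._cnn_scores(batch, training=train_cnn)
                    scores_j = Tensor(scores.data, requires_grad=True)

                # small whole-volume losses (graphs kept until step end)
                head_terms = []
                if "im" in stage.losses:
                    target = self.i_app_lo if stage.resolution == "lo" \
                        else self.i_app_hi
                    l_im = loss_image(ref_j, target)
                    head_terms.append(w["sim"] * l_im)
                    losses["im"] = float(l_im.data)
                if "tv" in stage.losses:
                    l_tv = loss_tv(ref_j)
                    head_terms.append(w["tv"] * l_tv)
                    losses["tv"] = float(l_tv.data)
                if "mbc" in stage.losses:
                    l_mbc = loss_mbc(fields_j)
                    head_terms.append(w["mbc"] * l_mbc)
                    losses["mbc"] = float(l_mbc.data)
                if "zms" in stage.losses:
                    oob = self.solved_scores.sum(axis=0) \
                        - self.solved_scores[batch].sum(axis=0)
                    l_zms = loss_zms(scores_j, oob, n)
                    head_terms.append(w["zms"] * l_zms)
                    losses["zms"] = float(l_zms.data)
                if head_terms:
                    head = head_terms[0]
                    for t in head_terms[1:]:
                        head = head + t
                    head.backward()

                # per-frame similarity / self-consistency terms
                if "prj" in stage.losses:
                    n_pix = float(np.prod(self.geometry.detector_shape))
                    acc_prj = 0.0
                    acc_sc = 0.0
                    n_sc = min(self.schedule.sc_subsample, len(batch))
                    for bi, fi in enumerate(batch):
                        angle = self.stack.angles_deg[fi]
                        if stage.name == "I-b":
                            vol_t, dvf = ref_j, None
                        else:
                            vol_t, dvf = self._dynamic_volume(
                                ref_j, fields_j, scores_j[bi], grid)
                        drr = project_tensor(vol_t, grid, self.geometry,
                                             angle, step_mm=self.step_mm)
                        resid = ((drr - Tensor(self.stack.frames[fi])) ** 2) \
                            .sum() * (1.0 / (len(batch) * n_pix))
                        term = w["sim"] * resid
                        acc_prj += float(resid.data)
                        if "sc" in stage.losses and dvf is not None \
                                and bi < n_sc:
                            # unbiased subsample of the batch-mean term
                            l_sc = loss_self_consistency(ref_j, vol_t, dvf,
                                                         grid)
                            term = term + (w["sc"] / n_sc) * l_sc
                            acc_sc += float(l_sc.data) / n_sc
                        term.backward()
                    losses["prj"] = acc_prj
                    if "sc" in stage.losses:
                        losses["sc"] = acc_sc

                # augmentation task (scores from single projections)
                if "aug" in stage.losses and stage.lr_cnn > 0:
                    mode = "motion_angle" if stage.augmentation == \
                        "motion_angle" else "angle"
                    if frozen:
                        ref_np, fields_np = ref_frozen, fields_frozen
                    else:
                        ref_np = ref.data
                        fields_np = [[fields[i][k].data for k in range(3)]
                                     for i in range(3)]
                    drr_aug = np.empty((len(batch),)
                                       + tuple(self.geometry.detector_shape))
                    tgt = np.empty((len(batch), 3, 3))
                    for bi, fi in enumerate(batch):
                        angle = rng_aug.uniform(0.0, 360.0)
                        drr_aug[bi], tgt[bi] = self._augmented_sample(
                            ref_np, fields_np, self.solved_scores[fi],
                            grid, angle, mode, rng_aug)
                    self.cnn.training = train_cnn
                    pred = self.cnn.forward(drr_aug)
                    l_aug = loss_augmentation(pred, tgt)
                    (w["aug"] * l_aug).backward()
                    losses["aug"] = float(l_aug.data)

                # close the junctions: push accumulated gradients through
                # the shared render / basis / encoder graphs exactly once
                if ref_j is not None and ref_j.grad is not None:
                    ref.backward(ref_j.grad)
                if fields_j is not None:
                    for i in range(3):
                        for k in range(3):
                            if fields_j[i][k].grad is not None:
                                fields[i][k].backward(fields_j[i][k].grad)
                if scores_j is not None and scores_j.grad is not None:
                    scores.backward(scores_j.grad)

                total = sum(losses.get(k, 0.0) * w.get(
                    {"im": "sim", "prj": "sim"}.get(k, k), 1.0)
                    for k in losses)
                if not np.isfinite(total):
                    raise FloatingPointError(
                        f"non-finite loss in stage {stage.name} epoch {epoch}"
                        f": {losses}")
                opt.step()

                if need_motion and not frozen:
                    self.solved_scores[batch] = scores.data
                self.log.append({"stage": stage.name, "epoch": epoch,
                                 "total": total, **losses})

        if train_cnn:
            # later stages (and online inference) read the encoder in eval
            # mode; pin its batch-norm statistics to the training scan so
            # eval scores match the just-solved training-mode scores
            self.cnn.recalibrate_bn(self.normalized)
            self.cnn.eval()
            self.solved_scores = self.cnn.forward(self.normalized).data


def run_training(stack: ProjectionStack, geometry: ScanGeometry,
                 schedule: TrainingSchedule, grid_hi: VolumeGrid,
                 seed: int = 0, step_mm: float | None = None,
                 stages: slice | None = None,
                 trainer_state: "_Trainer | None" = None,
                 grid_lo: VolumeGrid | None = None,
                 warmstart_volume: np.ndarray | None = None):
    """Execute the progressive schedule; returns (TrainedModel, log).

    `stages` may restrict execution to a sub-range for resumable training;
    pass the previous `trainer_state` (attached to the returned model as
    ``_trainer``) to continue.
    """
    log: list = []
    if trainer_state is None:
        trainer = _Trainer(stack, geometry, schedule, grid_hi, seed,
                           step_mm, log, grid_lo=grid_lo,
                           warmstart_volume=warmstart_volume)
    else:
        trainer = trainer_state
        trainer.log = log
    todo = schedule.stages if stages is None else schedule.stages[stages]
    offset = 0 if stages is None else (stages.start or 0)
    for si, stage in enumerate(todo):
        t0 = time.time()
        trainer.run_stage(stage, offset + si)
        log.append({"stage": stage.name, "epoch": -1,
                    "wall_s": time.time() - t0})
    if todo and todo[-1] is schedule.stages[-1]:
        # final stage done: pin batch-norm statistics to the population
        # statistics of the training scan for deterministic inference
        trainer.cnn.recalibrate_bn(trainer.normalized)
    model = TrainedModel(trainer.inr, trainer.basis, trainer.cnn,
                         trainer.grid_hi, trainer.grid_lo, geometry,
                         trainer.norm_lo, trainer.norm_hi,
                         trainer.solved_scores.copy(), seed)
    model._trainer = trainer
    return model, log
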