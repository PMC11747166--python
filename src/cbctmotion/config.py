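"""Run configuration: YAML schema, validation, and config hashing.

Every artifact written by the CLI carries the SHA-256 hash of its resolved
configuration plus the master seed, so outputs can always be traced back to
the exact run conditions.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml

from .phantom import BreathingScenario, PhantomSpec, packaged_scenarios
from .studies import StudyConfig
from .training import TrainingSchedule

_ALLOWED_KEYS = {"profile", "scenario", "seed", "output_dir", "phantom",
                 "geometry", "schedule", "noise_i0"}
_PHANTOM_KEYS = set(PhantomSpec.__dataclass_fields__)
_GEOMETRY_KEYS = {"n_projections", "duration_s", "detector_shape",
                  "pixel_pitch_mm", "sad_mm", "sdd_mm", "angle_offset_deg"}
_SCHEDULE_KEYS = {"epochs", "lr_inr", "lr_cnn", "lr_basis"}


@dataclass
class RunConfig:
    """Validated configuration for simulate / train / infer / evaluate."""

    profile: str = "scaled"               # "scaled" or "full"
    scenario: str = "S1"
    seed: int = 0
    output_dir: str = "runs"
    phantom: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)   # per-stage overrides
    noise_i0: float | None = None

    def __post_init__(self):
        if self.profile not in ("scaled", "full"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.scenario not in packaged_scenarios():
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for key in self.phantom:
            if key not in _PHANTOM_KEYS:
                raise ValueError(f"unknown phantom key {key!r}")
        for key in self.geometry:
            if key not in _GEOMETRY_KEYS:
                raise ValueError(f"unknown geometry key {key!r}")
        for name, overrides in self.schedule.items():
            for key in overrides:
                if key not in _SCHEDULE_KEYS:
                    raise ValueError(f"unknown schedule key {key!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # -- resolved objects ---------------------------------------------------
    def study_config(self) -> StudyConfig:
        base = StudyConfig(scenario_id=self.scenario)
        geo = dict(self.geometry)
        kw = {}
        for name in ("n_projections", "duration_s", "detector_shape",
                     "pixel_pitch_mm"):
            if name in geo:
                kw[name] = geo[name]
        if kw.get("detector_shape") is not None:
            kw["detector_shape"] = tuple(kw["detector_shape"])
        return replace(base, **kw)

    def phantom_spec(self) -> PhantomSpec:
        if self.profile == "full":
            base = PhantomSpec()
        else:
            base = self.study_config().phantom_spec()
        over = dict(self.phantom)
        for key in ("grid_shape", "voxel_size_mm", "tumor_center",
                    "body_semiaxes", "lung_semiaxes"):
            if key in over:
                over[key] = tuple(over[key])
        return replace(base, **over)

    def scenario_obj(self) -> BreathingScenario:
        return packaged_scenarios()[self.scenario]

    def acquisition(self, offset_deg: float = 0.0):
        from .phantom import acquisition_geometry
        if self.profile == "full":
            defaults = dict(n_projections=660, duration_s=60.0,
                            detector_shape=(192, 256), pixel_pitch_mm=1.55,
                            sad_mm=1000.0, sdd_mm=1500.0)
        else:
            sc = self.study_config()
            defaults = dict(n_projections=sc.n_projections,
                            duration_s=sc.duration_s,
                            detector_shape=sc.detector_shape,
                            pixel_pitch_mm=sc.pixel_pitch_mm,
                            sad_mm=1000.0, sdd_mm=1500.0)
        defaults.update(self.geometry)
        if "angle_offset_deg" not in defaults:
            defaults["angle_offset_deg"] = offset_deg
        defaults["detector_shape"] = tuple(defaults["detector_shape"])
        return acquisition_geometry(**defaults)

    def training_schedule(self) -> TrainingSchedule:
        if self.profile == "full":
            sched = TrainingSchedule.full_scale()
        else:
            sched = self.study_config().schedule()
        if self.schedule:
            stages = []
            for s in sched.stages:
                over = self.schedule.get(s.name, {})
                stages.append(replace(s, **over))
            sched = TrainingSchedule(stages, dict(sched.weights),
                                     n_batch=sched.n_batch,
                                     sc_subsample=sched.sc_subsample,
                                     gated_warmstart=sched.gated_warmstart,
                                     augment=sched.augment)
        return sched
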