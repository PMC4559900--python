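"""Run configuration: one serializable object aggregating every tunable.

The config round-trips through YAML unchanged and is echoed into each run's
manifest, so a run is reproducible from its manifest alone.  A single
global seed is expanded into per-module seeds through a documented counter
scheme (``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed
counter per module).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml


#: fixed per-module counters for seed expansion
SEED_COUNTERS = {"synth": 0, "dca": 1, "pose": 2, "simulate": 3}


def module_seed(seed: int, module: str) -> int:
    """Derive a per-module 31-bit seed from the global seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(SEED_COUNTERS[module],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PathsConfig:
    alignment: str | None = None
    alignment_format: str = "fasta"
    structure: str | None = None
    chains: list[str] | None = None
    mapping_table: str | None = None


@dataclass
class DcaConfig:
    theta: float = 0.8
    lam: float | None = None          # None -> Meff
    min_separation: int = 2


@dataclass
class FilterConfig:
    sasa_threshold: float = 0.5
    n_top: int = 100
    monomer_cutoff: float = 8.0
    dilation: float = 0.0
    sasa_probe: float = 1.4
    sasa_points: int = 960


@dataclass
class SbmConfig:
    k_b: float = 200.0
    k_a: float = 40.0
    k_d_base: float = 1.0
    dihedral_factor: float = 100.0
    sigma_ex: float = 4.0
    epsilon: float = 1.0
    contact_cutoff: float = 8.0
    min_loop_sep: int = 4
    intra_A: float = 1.0
    intra_w: float = 0.5


@dataclass
class ScheduleConfig:
    r0: list[float] = field(default_factory=lambda: [50.0, 38.0, 28.0, 20.0, 14.0, 10.0, 8.0])
    A: list[float] = field(default_factory=lambda: [1.0, 1.0, 1.0, 1.0, 2.0, 3.0, 4.0])
    w: list[float] = field(default_factory=lambda: [10.0, 8.0, 6.0, 5.0, 4.0, 3.0, 1.5])
    max_steps: int = 100000
    window: int = 50
    tol: float = 0.02


@dataclass
class SimulateConfig:
    dt: float = 0.005
    gamma: float = 0.1
    temperature: float = 0.3
    record_stride: int = 50
    separation: float = 50.0
    rotate_axis: str = "centroid"
    rotate_angle_deg: float = 180.0


@dataclass
class EvaluateConfig:
    interface_cutoff: float = 10.0
    contact_cutoff: float = 8.0


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    dca: DcaConfig = field(default_factory=DcaConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    sbm: SbmConfig = field(default_factory=SbmConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.dca.theta <= 1):
            raise ValueError("dca.theta must lie in (0, 1]")
        if not (0 <= self.filter.sasa_threshold <= 1):
            raise ValueError("filter.sasa_threshold must lie in [0, 1]")
        if len(self.schedule.r0) != 7 or len(self.schedule.A) != 7 \
                or len(self.schedule.w) != 7:
            raise ValueError("schedule must define exactly 7 stages")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            paths=PathsConfig(**d.get("paths", {})),
            dca=DcaConfig(**d.get("dca", {})),
            filter=FilterConfig(**d.get("filter", {})),
            sbm=SbmConfig(**d.get("sbm", {})),
            schedule=ScheduleConfig(**d.get("schedule", {})),
            simulate=SimulateConfig(**d.get("simulate", {})),
            evaluate=EvaluateConfig(**d.get("evaluate", {})),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def build_schedule(self):
        from coevdock.sbm import Stage, StageSchedule
        return StageSchedule([
            Stage(r0=r, A=a, w=w, max_steps=self.schedule.max_steps,
                  window=self.schedule.window, tol=self.schedule.tol)
            for r, a, w in zip(self.schedule.r0, self.schedule.A, self.schedule.w)])

    def build_sbm_params(self):
        from coevdock.sbm import SBMParams
        return SBMParams(**asdict(self.sbm))
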