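"""Run configuration: one YAML document with per-stage sections.

Every analysis constant (baseline window w, rhythm band, integrator time
constant, bin width, ratio window, gas protocol) is a configurable default
here, never hard-coded in the pipeline.  ``RunConfig.validate`` checks the
parameters against the stage preconditions before any computation starts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class SynthgenConfig:
    movie: dict = field(default_factory=dict)  # MovieSpec overrides
    nerve: dict = field(default_factory=dict)  # NerveTraceSpec overrides
    breath: dict = field(default_factory=dict)  # BreathTraceSpec overrides
    n_animals: int = 6


@dataclass
class ImagingConfig:
    w: int = 100
    band: tuple[float, float] = (0.1, 0.4)
    mode: str = "full_series"
    cta_window: tuple[int, int] = (25, 25)
    min_area: int = 5
    max_area: int = 200
    start_quantile: float = 0.995
    step: float = 0.95


@dataclass
class EphysConfig:
    tau_ms: float = 50.0
    k_threshold: float = 3.0
    min_duration_ms: float = 50.0
    refractory_ms: float = 300.0
    response_window_s: float = 2.0


@dataclass
class PlethConfig:
    protocol: str = "neonatal"  # or "adult"
    bin_s: float = 20.0
    window_s: float = 100.0
    k_gap: float = 2.0


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "chemoreflex_out"
    stages: tuple[str, ...] = ("synthgen", "imaging", "ephys", "pleth")
    log_level: str = "INFO"
    synthgen: SynthgenConfig = field(default_factory=SynthgenConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    ephys: EphysConfig = field(default_factory=EphysConfig)
    pleth: PlethConfig = field(default_factory=PlethConfig)

    def validate(self) -> None:
        if self.imaging.w < 1:
            raise ValueError("imaging.w must be >= 1")
        n_frames = self.synthgen.movie.get("n_frames", 1800)
        if "synthgen" in self.stages and n_frames <= self.imaging.w:
            raise ValueError("movie n_frames must exceed the baseline window w")
        lo, hi = self.imaging.band
        if not 0 < lo < hi:
            raise ValueError("imaging.band must satisfy 0 < low < high")
        if self.ephys.tau_ms <= 0:
            raise ValueError("ephys.tau_ms must be positive")
        if self.pleth.bin_s <= 0 or self.pleth.window_s <= 0:
            raise ValueError("pleth bin and window must be positive")
        if self.pleth.protocol not in ("neonatal", "adult"):
            raise ValueError("pleth.protocol must be 'neonatal' or 'adult'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for name, sub in (
            ("synthgen", SynthgenConfig),
            ("imaging", ImagingConfig),
            ("ephys", EphysConfig),
            ("pleth", PlethConfig),
        ):
            if name in d:
                section = dict(d.pop(name))
                for key in ("band", "cta_window"):
                    if key in section and isinstance(section[key], list):
                        section[key] = tuple(section[key])
                kwargs[name] = sub(**section)
        if "stages" in d and isinstance(d["stages"], list):
            d["stages"] = tuple(d["stages"])
        return cls(**d, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(doc)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def demo_config(seed: int = 0, out_dir: str = "chemoreflex_out") -> RunConfig:
    """A small end-to-end demonstration configuration on synthetic data."""
    cfg = RunConfig(seed=seed, out_dir=out_dir)
    cfg.synthgen.movie = {
        "height": 64,
        "width": 64,
        "n_frames": 900,
        "noise_sd": 1.0,
        "n_cells": 8,
    }
    cfg.synthgen.nerve = {
        "duration": 120.0,
        "sample_rate": 1000.0,
        "stim_every_s": 6.0,
        "stim_success_prob": 0.7,
    }
    cfg.synthgen.breath = {"ttot_cv": 0.1, "vt_cv": 0.1, "hypercapnic_effects": (0.805, 1.275)}
    cfg.synthgen.n_animals = 4
    return cfg
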