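"""Pipeline configuration: validated YAML-backed settings for every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainingConfig


@dataclass
class SpectralSettings:
    window: int = 256
    hop: int = 8
    segment: int = 1016
    stride: int = 254

    def validate(self):
        if self.window < 2 or self.hop < 1:
            raise ValueError("spectral.window/hop must be positive")
        if self.segment % self.hop != 0:
            raise ValueError("spectral.segment must be a multiple of hop")
        if self.segment < self.window:
            raise ValueError("spectral.segment must be >= window")

    @property
    def n_frames(self) -> int:
        return self.segment // self.hop + 1

    @property
    def n_rows(self) -> int:
        return self.window // 2


@dataclass
class SynthSettings:
    n_eeg: int = 4
    n_seeg: int = 8
    duration_s: float = 256.0
    rate_hz: float = 64.0
    noise_sd: float = 0.3
    burst_rate: float = 0.5
    attenuation_exponent: float = 2.0

    def validate(self):
        if self.n_eeg < 1 or self.n_seeg < 1:
            raise ValueError("synth.n_eeg/n_seeg must be >= 1")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("synth.duration_s/rate_hz must be positive")


@dataclass
class FilterSettings:
    line_hz: float = 50.0
    target_hz: float = 64.0

    def validate(self):
        if self.line_hz <= 0 or self.target_hz <= 0:
            raise ValueError("filter.line_hz/target_hz must be positive")


@dataclass
class MatchSettings:
    bin_mm: float = 5.0

    def validate(self):
        if self.bin_mm <= 0:
            raise ValueError("match.bin_mm must be positive")


@dataclass
class EvalSettings:
    nperseg: int = 256

    def validate(self):
        if self.nperseg < 8:
            raise ValueError("eval.nperseg must be >= 8")


@dataclass
class PerturbSettings:
    repeats: int = 50

    def validate(self):
        if self.repeats < 2:
            raise ValueError("perturb.repeats must be >= 2")


@dataclass
class PipelineConfig:
    """Validated settings for the full synth-to-perturbation pipeline.

    ``preset='desk'`` switches every shape-dependent size to the reduced
    32x32 configuration (248-sample segments, window 64, hop 8) for
    CPU-scale runs; the defaults are the full 128x128 geometry.
    """

    out_dir: str = "e2sgan_run"
    seed: int = 0
    preset: str = "full"         # 'full' or 'desk'
    synth: SynthSettings = field(default_factory=SynthSettings)
    filter: FilterSettings = field(default_factory=FilterSettings)
    spectral: SpectralSettings = field(default_factory=SpectralSettings)
    match: MatchSettings = field(default_factory=MatchSettings)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    eval: EvalSettings = field(default_factory=EvalSettings)
    perturb: PerturbSettings = field(default_factory=PerturbSettings)

    def __post_init__(self):
        if self.preset not in ("full", "desk"):
            raise ValueError("preset must be 'full' or 'desk'")
        if self.preset == "desk":
            self.spectral = SpectralSettings(window=64, hop=8, segment=248,
                                             stride=62)
            self.model = ModelConfig(size=32, gen_base=16, disc_base=8)
            self.eval = EvalSettings(nperseg=64)
        self.validate()

    def validate(self):
        for section in (self.synth, self.filter, self.spectral, self.match,
                        self.eval, self.perturb):
            section.validate()
        if self.spectral.n_rows != self.model.size \
                or self.spectral.n_frames != self.model.size:
            raise ValueError(
                f"spectral geometry ({self.spectral.n_rows} rows x "
                f"{self.spectral.n_frames} frames) does not match model size "
                f"{self.model.size}")


_SECTIONS = {
    "synth": SynthSettings, "filter": FilterSettings,
    "spectral": SpectralSettings, "match": MatchSettings,
    "model": ModelConfig, "training": TrainingConfig,
    "eval": EvalSettings, "perturb": PerturbSettings,
}


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            try:
                kwargs[key] = cls(**val)
            except TypeError as err:
                raise ValueError(f"invalid field in section {key!r}: {err}") from err
        elif key in ("out_dir", "seed", "preset"):
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config section {key!r}")
    # preset must be applied before explicit sections override it
    preset = kwargs.pop("preset", "full")
    explicit = {k: kwargs.pop(k) for k in list(kwargs)
                if k in _SECTIONS}
    cfg = PipelineConfig(preset=preset, **kwargs)
    for k, v in explicit.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
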