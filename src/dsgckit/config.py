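"""Run configuration: one schema holding every tunable stage parameter.

Configuration travels as JSON (YAML accepted as a convenience dialect) and
is validated up front so a bad field fails with its path before any stage
runs.  Every parameter that a stage exposes — analysis windows, detection
thresholds, model constants, calibration separation, smoothing width, seeds —
appears here with its documented default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ConfigError


@dataclass
class WindowConfig:
    on_start: float = 0.5
    off_start: float = 2.5
    width: float = 1.5
    baseline_width: float = 0.5


@dataclass
class SpikeConfig:
    band_low_hz: float = 80.0
    band_high_hz: float = 2000.0
    threshold: float | None = None  # None -> 5x MAD automatic
    polarity: int = 1
    refractory_s: float = 0.002
    slide_width_s: float = 0.1


@dataclass
class ModelConfig:
    cm_pf: float = 80.0
    g_leak_ns: float = 3.3
    e_leak_mv: float = -55.0
    e_exc_mv: float = 0.0
    e_inh_mv: float = -60.0
    dt_ms: float = 0.1
    hold_exc_mv: float = -60.0
    hold_inh_mv: float = 0.0
    lowpass_cutoff_hz: float = 50.0


@dataclass
class PairedConfig:
    junction_mv: float = -10.0
    qc_r2: float = 0.80
    epoch_s: tuple[float, float] = (0.2, 0.6)
    baseline_s: tuple[float, float] = (0.0, 0.1)


@dataclass
class OkrConfig:
    likelihood_threshold: float = 0.9
    gaussian_sigma_frames: float = 2.0
    saccade_threshold_dps: float = 30.0
    separation_deg: float = 12.0
    saccade_margin_frames: int = 1
    camera: str = "auto"  # auto | A | B
    fps: float = 100.0


@dataclass
class SynthConfig:
    sampling_rate_hz: float = 10_000.0
    sweep_duration_s: float = 4.5
    n_trials: int = 3
    noise_sd_pa: float = 10.0
    scale_deg_per_px: float = 0.5
    eye_duration_s: float = 45.0


@dataclass
class RunConfig:
    windows: WindowConfig = field(default_factory=WindowConfig)
    spikes: SpikeConfig = field(default_factory=SpikeConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    paired: PairedConfig = field(default_factory=PairedConfig)
    okr: OkrConfig = field(default_factory=OkrConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    genotype: str = "wild_type"  # free metadata: wild_type | b2_ko
    cell_type: str = "nDSGC"  # free metadata: nDSGC | vDSGC

    def validate(self) -> "RunConfig":
        checks = [
            ("windows.width", self.windows.width > 0),
            ("windows.baseline_width", self.windows.baseline_width > 0),
            ("spikes.band_low_hz", 0 < self.spikes.band_low_hz < self.spikes.band_high_hz),
            ("spikes.refractory_s", self.spikes.refractory_s >= 0),
            ("spikes.slide_width_s", self.spikes.slide_width_s > 0),
            ("model.cm_pf", self.model.cm_pf > 0),
            ("model.g_leak_ns", self.model.g_leak_ns >= 0),
            ("model.dt_ms", self.model.dt_ms > 0),
            ("paired.qc_r2", 0 <= self.paired.qc_r2 <= 1),
            ("okr.likelihood_threshold", 0 <= self.okr.likelihood_threshold <= 1),
            ("okr.saccade_threshold_dps", self.okr.saccade_threshold_dps > 0),
            ("okr.separation_deg", self.okr.separation_deg > 0),
            ("okr.gaussian_sigma_frames", self.okr.gaussian_sigma_frames >= 0),
            ("okr.saccade_margin_frames", self.okr.saccade_margin_frames >= 0),
            ("okr.camera", self.okr.camera in ("auto", "A", "B")),
            ("okr.fps", self.okr.fps > 0),
            ("synth.sampling_rate_hz", self.synth.sampling_rate_hz > 0),
            ("synth.n_trials", self.synth.n_trials >= 1),
            ("seed", isinstance(self.seed, int) and 0 <= self.seed < 2**31),
        ]
        for path, ok in checks:
            if not ok:
                raise ConfigError(f"invalid configuration field: {path}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        sections = {
            "windows": WindowConfig,
            "spikes": SpikeConfig,
            "model": ModelConfig,
            "paired": PairedConfig,
            "okr": OkrConfig,
            "synth": SynthConfig,
        }
        for key, value in data.items():
            if key in sections:
                known = sections[key]().__dict__
                bad = set(value) - set(known)
                if bad:
                    raise ConfigError(f"unknown configuration field: {key}.{sorted(bad)[0]}")
                known.update(value)
                if key == "paired":  # tuples round-trip through JSON as lists
                    for f2 in ("epoch_s", "baseline_s"):
                        known[f2] = tuple(known[f2])
                setattr(cfg, key, sections[key](**known))
            elif key in ("seed", "genotype", "cell_type"):
                setattr(cfg, key, value)
            else:
                raise ConfigError(f"unknown configuration field: {key}")
        return cfg.validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})
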