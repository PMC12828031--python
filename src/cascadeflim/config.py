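"""Pipeline configuration: a single YAML document with per-stage blocks.

CLI flags override config values (flag > config > default).  The config
round-trips load -> save -> load identically, which the test suite checks.

Schema (all blocks optional unless a command needs them)::

    seed: 1
    out_dir: results/
    pair_table: pairs.json          # fluorophore pair JSON (io module format)
    acquisition:
      period_ns: 12.5               # 80 MHz repetition
      n_bins: 256
      irf_sigma_ns: 0.0
    fitting:
      n_components: 1
      photon_threshold: 300         # below this, 3x3 binning before fitting
      min_counts: 100
    calibration:
      linker_n: 40
      force_model: printed          # or "compliance"
      r_TL_nm: null                 # usually measured from the TL condition
    simulate:
      decay: {components: [[1.0, 4.178]], total_photons: 1.0e6, background_rate: 0.0}
      scene: {pop1: [...], pop2: [...], donor: mTFP1, acceptor: mVenus,
              r_TL_nm: 4.2, image_shape: [48, 48], photons_per_pixel: 1.0e4}
      ensemble: {distances: {"mTurq2-mVenus": 6.41, ...}, total_photons: 1.0e6}
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = [
    "AcquisitionConfig",
    "FittingConfig",
    "CalibrationConfig",
    "PipelineConfig",
]


@dataclass
class AcquisitionConfig:
    period_ns: float = 12.5
    n_bins: int = 256
    irf_sigma_ns: float = 0.0


@dataclass
class FittingConfig:
    n_components: int = 1
    photon_threshold: int = 300
    min_counts: int = 100


@dataclass
class CalibrationConfig:
    linker_n: int = 40
    force_model: str = "printed"
    r_TL_nm: float | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    pair_table: str | None = None
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        for key, sub in (
            ("acquisition", AcquisitionConfig),
            ("fitting", FittingConfig),
            ("calibration", CalibrationConfig),
        ):
            if key in d and isinstance(d[key], dict):
                known = {f.name for f in dataclasses.fields(sub)}
                unknown = set(d[key]) - known
                if unknown:
                    raise ConfigurationError(f"unknown {key} keys: {sorted(unknown)}")
                d[key] = sub(**d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def validate_paths(self, base: Path | None = None) -> None:
        """Check that all referenced paths exist."""
        base = Path(base) if base else Path(".")
        if self.pair_table is not None:
            p = base / self.pair_table
            if not p.exists():
                raise ConfigurationError(f"pair_table path does not exist: {p}")
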