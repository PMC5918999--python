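"""Pipeline configuration: one human-readable YAML file with per-stage sections.

Every parameter has a documented default; CLI flags override config values.
The random seed is always explicit so any run is reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError


@dataclass
class SimulateConfig:
    mode: str = "clustered"
    field_width_nm: float = 25_000.0
    field_height_nm: float = 25_000.0
    molecule_density_um2: float = 100.0
    parent_density_um2: float = 50.0
    displacement_scale_nm: float = 25.0
    mean_blinks: float = 4.0
    precision_sigma_nm: float = 20.0
    frames_total: int = 30_000


@dataclass
class LocalizeConfig:
    threshold_scale: float = 5.0
    background_window: int = 101
    min_separation_px: int = 4
    patch_half_px: int = 4
    min_photons: float = 30.0
    camera_pixel_nm: float = 100.0


@dataclass
class RenderConfig:
    render_pixel_nm: float = 5.0
    smoothing_sigma_nm: float = 10.0


@dataclass
class PaircorrConfig:
    bin_nm: float = 5.0
    dr_nm: float = 5.0
    r_max_nm: float = 500.0


@dataclass
class DensityConfig:
    n_rois: int = 5
    area_min_um2: float = 0.7
    area_max_um2: float = 2.5


@dataclass
class DriftConfig:
    bin_frames: int = 1000
    render_pixel_nm: float = 20.0


@dataclass
class KineticsConfig:
    t_half_h: float = 40.0


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    localize: LocalizeConfig = field(default_factory=LocalizeConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    paircorr: PaircorrConfig = field(default_factory=PaircorrConfig)
    density: DensityConfig = field(default_factory=DensityConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)

    _SECTIONS = {
        "simulate": SimulateConfig,
        "localize": LocalizeConfig,
        "render": RenderConfig,
        "paircorr": PaircorrConfig,
        "density": DensityConfig,
        "drift": DriftConfig,
        "kinetics": KineticsConfig,
    }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping of sections")
        cfg = cls(seed=int(raw.get("seed", 0)))
        for name, klass in cls._SECTIONS.items():
            section = raw.get(name, {})
            if not isinstance(section, dict):
                raise FormatError(f"{path}: section {name!r} must be a mapping")
            known = klass().__dict__
            unknown = set(section) - set(known)
            if unknown:
                raise FormatError(f"{path}: unknown keys in {name!r}: {sorted(unknown)}")
            setattr(cfg, name, klass(**{**known, **section}))
        return cfg

    def to_yaml(self, path) -> None:
        out = {"seed": self.seed}
        for name in self._SECTIONS:
            out[name] = asdict(getattr(self, name))
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
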