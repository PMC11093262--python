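"""Run configuration: strict YAML-backed schema for simulation and analysis.

Unknown keys are rejected (typos must fail loudly for reproducibility);
every default is the package default documented on the underlying dataclass.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .cs import FitConfig
from .hydro import RotorProtocol, SolventModel, Species
from .instrument import InstrumentModel, NoiseOptions

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeciesConfig(_Strict):
    name: str = "species"
    s: float
    ff0: float = 1.2
    vbar: float = 0.73
    c0: float = 1.0
    lambda_max_nm: float = 550.0
    fwhm_nm: float = 60.0
    exc_eff: float = 1.0
    eps_exc: float = 0.0

    def build(self) -> Species:
        return Species.gaussian_emitter(
            self.name, self.s, self.lambda_max_nm, self.fwhm_nm,
            ff0=self.ff0, vbar=self.vbar, c0=self.c0,
            exc_eff=self.exc_eff, eps_exc=self.eps_exc)


class SolventConfig(_Strict):
    density: float = 1.0
    viscosity: float = 1.002
    temperature: float = 293.15

    def build(self) -> SolventModel:
        return SolventModel(**self.model_dump())


class ProtocolConfig(_Strict):
    speed_rpm: float = 40_000.0
    meniscus_cm: float = 6.0
    bottom_cm: float = 7.2
    radial_step_um: float = 50.0
    scan_interval_s: float = 90.0
    n_scans: int = 30
    start_delay_s: float = 0.0

    def build(self) -> RotorProtocol:
        return RotorProtocol(**self.model_dump())


class InstrumentConfig(_Strict):
    laser_nm: float = 520.0
    laser_spot_diameter_um: float = 40.0
    fiber_core_um: float = 200.0
    grating_lmm: int = 150
    read_noise_e: float = 7.0
    adc_gain_e_per_count: float = 1.0
    exposure_ms: float = 100.0
    photon_budget: float = 2000.0
    sensor_pixels: int = 1600

    def build(self) -> InstrumentModel:
        return InstrumentModel(**self.model_dump())


class NoiseConfig(_Strict):
    detector: bool = True
    ti_amplitude: float = 0.0
    ri_amplitude: float = 0.0
    beam_drift_frac: float = 0.0

    def build(self) -> NoiseOptions:
        return NoiseOptions(**self.model_dump())


class FitSection(_Strict):
    s_min: float = 0.5
    s_max: float = 15.0
    n_s: int = 150
    regularization: Literal["second_derivative", "maximum_entropy"] = \
        "second_derivative"
    confidence: float = 0.683
    fit_ti: bool = True
    fit_ri: bool = True
    ff0: float = 1.2
    vbar: float = 0.73
    wavelength_step_nm: float = 1.5
    window_lo_nm: float | None = None
    window_hi_nm: float | None = None
    window_lo_cm: float | None = None   # radial analysis window
    window_hi_cm: float | None = None

    def build(self) -> FitConfig:
        d = self.model_dump()
        d.pop("wavelength_step_nm")
        d.pop("window_lo_nm")
        d.pop("window_hi_nm")
        return FitConfig(**d)

    @property
    def window_nm(self):
        if self.window_lo_nm is None or self.window_hi_nm is None:
            return None
        return (self.window_lo_nm, self.window_hi_nm)


class QcSection(_Strict):
    asymmetry_threshold: float = 0.15
    snr_floor: float = 3.0


class RunConfig(_Strict):
    """Top-level configuration covering all module parameters."""

    species: list[SpeciesConfig] = Field(default_factory=list)
    solvent: SolventConfig = Field(default_factory=SolventConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    instrument: InstrumentConfig = Field(default_factory=InstrumentConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    fit: FitSection = Field(default_factory=FitSection)
    qc: QcSection = Field(default_factory=QcSection)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the validated configuration, for run logs."""
    import hashlib
    blob = cfg.model_dump_json().encode()
    return hashlib.sha256(blob).hexdigest()[:12]
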