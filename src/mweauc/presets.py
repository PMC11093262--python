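"""Canonical synthetic study conditions used by tests, examples and QC.

Each preset fixes every generator parameter of one reference scenario:
the species' hydrodynamics and emission bands, the solvent, the rotor
protocol and the instrument settings.  The scenarios emulate the systems
the instrument was characterized with — a GFP-like fluorescent protein and
glutathione-stabilized gold nanoclusters with size-dependent near-infrared
emission — at signal levels typical of real runs (peak amplitudes of order
10^4 counts).

Runs are sub-sampled in time relative to a full 450-scan experiment: the
scan schedules below span the same rotor-time window with fewer scans,
which keeps analyses fast without changing boundary coverage.
"""

from __future__ import annotations

from .hydro import RotorProtocol, SolventModel, Species
from .instrument import InstrumentModel, NoiseOptions, simulate_sv_dataset
from .cs import FitConfig

__all__ = [
    "gfp_like_run",
    "aunc_two_species_run",
    "aunc_three_species_run",
    "aunc_fit_config",
    "protein_fit_config",
]


def protein_fit_config(**overrides) -> FitConfig:
    """c(s) settings for the protein scenarios (floating-ff0 convention)."""
    kw = dict(s_min=0.8, s_max=12.0, n_s=150, ff0=1.2, vbar=0.73,
              regularization="maximum_entropy")
    kw.update(overrides)
    return FitConfig(**kw)


def aunc_fit_config(**overrides) -> FitConfig:
    """c(s) settings for the nanocluster scenarios.

    Compact-sphere model (ff0 fixed at 1.0) with the best-fit partial
    specific volume for 405 nm excitation, second-derivative regularization,
    and a bottom exclusion wide enough to clear the strong back-diffusion
    layer of these small, fast-diffusing particles.
    """
    kw = dict(s_min=1.0, s_max=10.0, n_s=150, ff0=1.0, vbar=0.547,
              regularization="second_derivative", window_hi_cm=7.0)
    kw.update(overrides)
    return FitConfig(**kw)


def gfp_like_run(seed: int = 1, *, n_scans: int = 20, noise=None,
                 photon_budget: float = 20000.0):
    """Single 4 S fluorescent-protein species, 520 nm excitation.

    Returns (ScanSet, species list, solvent, protocol, instrument).
    """
    sp = Species.gaussian_emitter("gfp", s=4.0, lam_max=511.0, fwhm_nm=40.0,
                                  ff0=1.2, vbar=0.73, c0=1.0)
    solvent = SolventModel(density=1.0)
    protocol = RotorProtocol(speed_rpm=40_000.0, meniscus_cm=6.0,
                             bottom_cm=7.2, n_scans=n_scans,
                             scan_interval_s=24_000.0 / n_scans)
    instrument = InstrumentModel(laser_nm=520.0, exposure_ms=100.0,
                                 photon_budget=photon_budget,
                                 adc_gain_e_per_count=4.0)
    ds = simulate_sv_dataset([sp], solvent, protocol, instrument,
                             noise or NoiseOptions(), seed=seed)
    return ds, [sp], solvent, protocol, instrument


def _aunc_instrument() -> InstrumentModel:
    return InstrumentModel(laser_nm=405.0, exposure_ms=100.0,
                           photon_budget=100_000.0,
                           adc_gain_e_per_count=4.0)


def aunc_two_species_run(seed: int = 2, *, n_scans: int = 60, noise=None):
    """Two gold-nanocluster species (3.4 S / 3.9 S; emission 800 / 705 nm).

    The reference two-ridge scenario: distinct sedimentation coefficients
    with distinct near-infrared emission maxima, equal loadings, compact
    spheres with a shared partial specific volume of 0.547 cm^3/g.
    Returns (ScanSet, species list, solvent, protocol, instrument).
    """
    species = [
        Species.gaussian_emitter("aunc-3.4S", s=3.4, lam_max=800.0,
                                 fwhm_nm=70.0, ff0=1.0, vbar=0.547, c0=1.0),
        Species.gaussian_emitter("aunc-3.9S", s=3.9, lam_max=705.0,
                                 fwhm_nm=70.0, ff0=1.0, vbar=0.547, c0=1.0),
    ]
    solvent = SolventModel(density=1.0)
    protocol = RotorProtocol(speed_rpm=40_000.0, meniscus_cm=6.0,
                             bottom_cm=7.2, n_scans=n_scans,
                             scan_interval_s=27_000.0 / n_scans)
    instrument = _aunc_instrument()
    ds = simulate_sv_dataset(species, solvent, protocol, instrument,
                             noise or NoiseOptions(), seed=seed)
    return ds, species, solvent, protocol, instrument


def aunc_three_species_run(seed: int = 3, *, n_scans: int = 45, noise=None):
    """Three nanocluster species (3.35 / 3.97 / 4.82 S; 700 / 760 / 825 nm).

    The discrete-species scenario used for the global fit across selected
    wavelengths.  Returns (ScanSet, species list, solvent, protocol,
    instrument).
    """
    species = [
        Species.gaussian_emitter("aunc-3.35S", s=3.35, lam_max=700.0,
                                 fwhm_nm=60.0, ff0=1.0, vbar=0.547, c0=1.0),
        Species.gaussian_emitter("aunc-3.97S", s=3.97, lam_max=760.0,
                                 fwhm_nm=60.0, ff0=1.0, vbar=0.547, c0=0.8),
        Species.gaussian_emitter("aunc-4.82S", s=4.82, lam_max=825.0,
                                 fwhm_nm=60.0, ff0=1.0, vbar=0.547, c0=0.6),
    ]
    solvent = SolventModel(density=1.0)
    protocol = RotorProtocol(speed_rpm=40_000.0, meniscus_cm=6.0,
                             bottom_cm=7.2, n_scans=n_scans,
                             scan_interval_s=21_600.0 / n_scans)
    instrument = _aunc_instrument()
    ds = simulate_sv_dataset(species, solvent, protocol, instrument,
                             noise or NoiseOptions(), seed=seed)
    return ds, species, solvent, protocol, instrument
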