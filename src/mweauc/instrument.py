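"""Forward model of the multiwavelength fluorescence-emission AUC detector.

Turns radial concentration fields from :mod:`mweauc.hydro` into realistic
scan data: confocal collection geometry, primary/secondary inner-filter
attenuation, grating dispersion onto an EMCCD sensor, and shot/read noise
with 16-bit digitization.

Coordinate conventions
----------------------
* radius r: cm, increasing outward, sampled at the protocol's step (50 um
  default);
* optical axis z: mm, z = 0 at the cell face nearest the optics, increasing
  into the cell (away from the optics).  The commanded stage position maps
  to the physical cell through an additive vacuum shift (the cell rises by
  ``z_vacuum_shift`` mm once the chamber is evacuated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence
import warnings

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d

from .hydro import (
    RotorProtocol,
    SolventModel,
    Species,
    solve_lamm,
)

__all__ = [
    "GRATINGS",
    "InstrumentModel",
    "Scan",
    "ZScan",
    "ScanSet",
    "CalibrationDisk",
    "NoiseOptions",
    "confocal_geometry",
    "rayleigh_length",
    "excitation_profile",
    "emission_escape",
    "simulate_zscan",
    "disperse_spectrum",
    "detect",
    "simulate_sv_dataset",
    "simulate_calibration_scan",
]

#: grating groove density -> (window start nm, window end nm, FWHM resolution nm)
GRATINGS = {
    150: (400.0, 937.0, 2.0),
    600: (515.0, 643.0, 0.51),
    1800: (525.0, 558.0, 0.14),
}

#: fixed imaging magnification from fibre core to confocal spot in the cell
MAGNIFICATION = 0.675

# printed anchor points: (fibre core um -> confocal depth mm)
_DEPTH_ANCHORS = ((50.0, 0.7), (200.0, 1.5))


def confocal_geometry(fiber_core_um: float,
                      magnification: float = MAGNIFICATION):
    """Collection spot size (um) and confocal depth (mm) for a fibre core.

    The spot scales linearly with the core diameter through the fixed imaging
    magnification; the confocal depth is anchored at the two characterized
    cores (50 um -> 0.7 mm, 200 um -> 1.5 mm) with linear interpolation.
    """
    if fiber_core_um <= 0:
        raise ValueError("fiber core diameter must be positive")
    if fiber_core_um not in (50.0, 200.0, 50, 200):
        warnings.warn(
            f"fiber core {fiber_core_um} um is outside the characterized set "
            "{50, 200}; confocal depth is interpolated", stacklevel=2)
    spot = fiber_core_um * magnification
    (c0, d0), (c1, d1) = _DEPTH_ANCHORS
    depth = d0 + (fiber_core_um - c0) * (d1 - d0) / (c1 - c0)
    return spot, depth


def rayleigh_length(waist_diameter_um: float, wavelength_nm: float) -> float:
    """Rayleigh length z_R = pi (d/2)^2 / lambda of a Gaussian beam, in mm."""
    if waist_diameter_um <= 0 or wavelength_nm <= 0:
        raise ValueError("waist diameter and wavelength must be positive")
    w0_mm = waist_diameter_um * 1e-3 / 2.0
    lam_mm = wavelength_nm * 1e-6
    return np.pi * w0_mm ** 2 / lam_mm


@dataclass
class InstrumentModel:
    """Optics and detector parameters governing the forward model.

    Defaults describe the second-generation instrument: 520 nm excitation,
    200 um collection fibre (135 um confocal spot, 1.5 mm confocal depth),
    150 L/mm grating on a 1600 x 200 px EMCCD at 1 MHz readout.
    """

    laser_nm: float = 520.0
    laser_spot_diameter_um: float = 40.0   # 1/e^2 diameter in the cell
    beam_waist_diameter_um: float = 35.0
    fiber_core_um: float = 200.0
    cell_depth_mm: float = 3.0
    grating_lmm: int = 150
    grating_window_nm: tuple[float, float] | None = None
    sensor_pixels: int = 1600
    sensor_rows: int = 200
    read_noise_e: float = 7.0              # rms; 4 e- at the 100 kHz ADC rate
    adc_gain_e_per_count: float = 1.0      # or 4 for extended dynamic range
    adc_bits: int = 16
    adc_offset_counts: float = 100.0
    exposure_ms: float = 100.0
    longpass_cutoff_nm: float = 0.0
    z_vacuum_shift_mm: float = 2.0
    cell_face_z_mm: float = 9.4            # commanded z of the cell face in air
    photon_budget: float = 2000.0          # photoelectrons per (conc * ms), whole band

    def __post_init__(self):
        if self.grating_lmm not in GRATINGS:
            raise ValueError(f"unknown grating {self.grating_lmm} L/mm; "
                             f"choose from {sorted(GRATINGS)}")
        if self.exposure_ms <= 0 or self.exposure_ms > 500.0:
            raise ValueError("exposure must lie in (0, 500] ms")
        if self.adc_gain_e_per_count <= 0 or self.read_noise_e < 0:
            raise ValueError("invalid detector parameters")

    # derived optics -------------------------------------------------------
    @property
    def collection_spot_um(self) -> float:
        return confocal_geometry(self.fiber_core_um)[0]

    @property
    def confocal_depth_mm(self) -> float:
        return confocal_geometry(self.fiber_core_um)[1]

    @property
    def counts_max(self) -> int:
        return (1 << self.adc_bits) - 1

    # derived dispersion ---------------------------------------------------
    @property
    def window_nm(self) -> tuple[float, float]:
        if self.grating_window_nm is not None:
            return self.grating_window_nm
        lo, hi, _ = GRATINGS[self.grating_lmm]
        return lo, hi

    @property
    def resolution_nm(self) -> float:
        return GRATINGS[self.grating_lmm][2]

    @property
    def nm_per_pixel(self) -> float:
        lo, hi = self.window_nm
        return (hi - lo) / self.sensor_pixels

    def wavelength_grid(self) -> np.ndarray:
        """Pixel-center wavelengths (nm), length ``sensor_pixels``."""
        lo, hi = self.window_nm
        d = self.nm_per_pixel
        return lo + d * (0.5 + np.arange(self.sensor_pixels))

    def small_core_variant(self) -> "InstrumentModel":
        """First-generation optics: 50 um core (34 um spot, 0.7 mm depth)."""
        return replace(self, fiber_core_um=50.0)


@dataclass
class Scan:
    """One radial scan: counts over radius x emission wavelength."""

    time_s: float
    speed_rpm: float
    z_mm: float
    radius_cm: np.ndarray
    wavelength_nm: np.ndarray
    counts: np.ndarray          # (n_radius, n_wavelength), integers in [0, 65535]
    exposure_ms: float = 100.0

    def __post_init__(self):
        self.radius_cm = np.asarray(self.radius_cm, dtype=float)
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.radius_cm) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.counts.shape != (self.radius_cm.size, self.wavelength_nm.size):
            raise ValueError("counts shape must be (n_radius, n_wavelength)")


@dataclass
class ZScan:
    """Signal profile along the optical axis at a fixed radius."""

    z_mm: np.ndarray
    wavelength_nm: np.ndarray
    counts: np.ndarray          # (n_z, n_wavelength)
    radius_cm: float
    speed_rpm: float
    exposure_ms: float = 10.0

    def __post_init__(self):
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        if np.any(np.diff(self.z_mm) <= 0):
            raise ValueError("z grid must be strictly increasing")


@dataclass
class ScanSet:
    """Time-ordered multiwavelength radial scans: the unit of analysis."""

    times_s: np.ndarray         # (n_scans,)
    radius_cm: np.ndarray       # (n_radius,)
    wavelength_nm: np.ndarray   # (n_wavelength,)
    counts: np.ndarray          # (n_scans, n_radius, n_wavelength) uint16
    speed_rpm: float
    exposure_ms: float
    instrument: InstrumentModel | None = None
    ground_truth: dict | None = None
    meniscus_cm: float | None = None
    bottom_cm: float | None = None

    @property
    def n_scans(self) -> int:
        return self.times_s.size

    def signal(self) -> np.ndarray:
        """Offset-subtracted counts as float (n_scans, n_radius, n_wavelength)."""
        off = self.instrument.adc_offset_counts if self.instrument else 0.0
        return self.counts.astype(float) - off

    def slice_wavelength(self, lam_nm: float, bin_nm: float | None = None
                         ) -> np.ndarray:
        """Signal matrix (n_scans, n_radius) at one wavelength.

        With ``bin_nm`` the pixels within lam_nm +/- bin_nm/2 are averaged.
        """
        lam = self.wavelength_nm
        if bin_nm is None:
            j = int(np.argmin(np.abs(lam - lam_nm)))
            return self.signal()[:, :, j]
        mask = np.abs(lam - lam_nm) <= bin_nm / 2.0
        if not mask.any():
            raise ValueError(f"no pixels within {bin_nm} nm of {lam_nm} nm")
        return self.signal()[:, :, mask].mean(axis=2)

    def binned(self, step_nm: float, window: tuple[float, float] | None = None):
        """(bin centers, signal array (n_scans, n_radius, n_bins)) at step_nm."""
        lam = self.wavelength_nm
        lo = window[0] if window else lam[0]
        hi = window[1] if window else lam[-1]
        edges = np.arange(lo, hi + step_nm / 2, step_nm)
        if edges.size < 2:
            raise ValueError("wavelength window too narrow for the bin step")
        centers = 0.5 * (edges[:-1] + edges[1:])
        sig = self.signal()
        idx = np.digitize(lam, edges) - 1
        nb = centers.size
        out = np.zeros(sig.shape[:2] + (nb,))
        counts = np.zeros(nb)
        for j, b in enumerate(idx):
            if 0 <= b < nb:
                out[:, :, b] += sig[:, :, j]
                counts[b] += 1
        good = counts > 0
        out[:, :, good] /= counts[good]
        return centers[good], out[:, :, good]

    def scans(self) -> list[Scan]:
        z = 0.0
        return [
            Scan(time_s=t, speed_rpm=self.speed_rpm, z_mm=z,
                 radius_cm=self.radius_cm, wavelength_nm=self.wavelength_nm,
                 counts=self.counts[k], exposure_ms=self.exposure_ms)
            for k, t in enumerate(self.times_s)
        ]


@dataclass
class CalibrationDisk:
    """Transparent gaps (start, end radii in cm) over a fluorescent backing."""

    gaps_cm: tuple[tuple[float, float], ...] = (
        (5.95, 6.10), (6.25, 6.40), (6.55, 6.70), (6.85, 7.00), (7.10, 7.15),
    )

    def __post_init__(self):
        prev_end = -np.inf
        for a, b in self.gaps_cm:
            if not a < b or a < prev_end:
                raise ValueError("gaps must be ordered and disjoint")
            prev_end = b

    def edges(self) -> np.ndarray:
        """All gap edge radii in scan order."""
        return np.asarray([e for gap in self.gaps_cm for e in gap])


@dataclass
class NoiseOptions:
    """Systematic-signal injections for synthetic datasets.

    ``ti_amplitude`` adds a fixed smooth radial pattern (time-invariant
    noise) and ``ri_amplitude`` adds a random per-scan offset
    (radial-invariant noise), both expressed as fractions of the peak
    expected signal.  ``beam_drift_frac`` ramps the sensitivity linearly
    with radius (a first-generation artefact; off by default).
    ``detector`` toggles shot/read noise and quantization.
    """

    detector: bool = True
    ti_amplitude: float = 0.0
    ri_amplitude: float = 0.0
    beam_drift_frac: float = 0.0


# ---------------------------------------------------------------------------
# Inner-filter optics
# ---------------------------------------------------------------------------

def _column_od(z_mm: np.ndarray, conc: np.ndarray, eps: float) -> np.ndarray:
    """Decadic optical depth accumulated from the cell face to each z."""
    z_mm = np.asarray(z_mm, dtype=float)
    conc = np.broadcast_to(np.asarray(conc, dtype=float), z_mm.shape)
    if eps < 0 or np.any(conc < 0):
        raise ValueError("attenuation coefficient and concentration must be >= 0")
    z_cm = z_mm * 0.1
    od = cumulative_trapezoid(conc, z_cm, initial=0.0)
    return eps * od


def excitation_profile(z_mm, conc, eps_exc: float) -> np.ndarray:
    """Relative excitation intensity I(z) = 10^(-eps_exc * int_0^z c dz').

    z is measured from the cell face nearest the optics (mm); c may be a
    scalar (uniform column) or an array on the z grid.  Monotone
    nonincreasing in z (primary inner-filter effect).
    """
    return 10.0 ** (-_column_od(z_mm, conc, eps_exc))


def emission_escape(z_mm, lam_nm, conc, eps_em) -> np.ndarray:
    """Fraction of light emitted at depth z that escapes toward the optics.

    eps_em may be a scalar or a callable of wavelength (nm).  Equals 1 when
    eps_em = 0 (red-side wavelengths clear of the absorption band).
    """
    eps = eps_em(lam_nm) if callable(eps_em) else float(eps_em)
    return 10.0 ** (-_column_od(z_mm, conc, eps))


# ---------------------------------------------------------------------------
# Dispersion and detection
# ---------------------------------------------------------------------------

def disperse_spectrum(lam_nm, density, instrument: InstrumentModel) -> np.ndarray:
    """Expected photoelectrons per sensor pixel for a point emission mixture.

    ``density`` is a spectral density (photoelectrons per nm) tabulated on
    ``lam_nm``; the total integral is conserved by dispersion up to window
    truncation (a warning is emitted when part of the band falls outside the
    grating window).  The resolution kernel is a Gaussian with the grating's
    printed FWHM.
    """
    lam_nm = np.asarray(lam_nm, dtype=float)
    density = np.asarray(density, dtype=float)
    if lam_nm.ndim != 1 or lam_nm.shape != density.shape:
        raise ValueError("wavelength grid and density must be matching 1-D arrays")
    lo, hi = instrument.window_nm
    total = np.trapezoid(density, lam_nm)
    # integrate the piecewise-linear density over pixel bins via its CDF
    cdf = cumulative_trapezoid(density, lam_nm, initial=0.0)
    edges = np.linspace(lo, hi, instrument.sensor_pixels + 1)
    cdf_at = np.interp(edges, lam_nm, cdf, left=0.0, right=cdf[-1])
    per_pixel = np.diff(cdf_at)
    if total > 0 and per_pixel.sum() < (1.0 - 1e-3) * total:
        warnings.warn(
            "part of the emission spectrum falls outside the grating window "
            f"{lo:.0f}-{hi:.0f} nm and is truncated", stacklevel=2)
    sigma_px = instrument.resolution_nm / 2.354820045 / instrument.nm_per_pixel
    return gaussian_filter1d(per_pixel, sigma_px, mode="constant")


def detect(expected_e, instrument: InstrumentModel,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """ADC counts for expected photoelectron numbers.

    counts = clip(round((Poisson(Ne) + Normal(0, sigma_read)) / gain)
                  + offset, 0, 2^bits - 1)

    With rng=None the noiseless mean response is returned (no rounding).
    Saturation is a value, never an error; dark current is neglected for
    exposures <= 500 ms.
    """
    expected_e = np.asarray(expected_e, dtype=float)
    if np.any(expected_e < 0):
        raise ValueError("expected photoelectron numbers must be >= 0")
    gain = instrument.adc_gain_e_per_count
    off = instrument.adc_offset_counts
    if rng is None:
        return np.clip(expected_e / gain + off, 0, instrument.counts_max)
    e = rng.poisson(expected_e).astype(float)
    e += rng.normal(0.0, instrument.read_noise_e, size=e.shape)
    counts = np.rint(e / gain) + off
    return np.clip(counts, 0, instrument.counts_max).astype(np.uint16)


# ---------------------------------------------------------------------------
# z-scans
# ---------------------------------------------------------------------------

def _collection_weight(z_rel_mm: np.ndarray, depth_mm: float) -> np.ndarray:
    """Flat-top axial collection weight of width ``depth_mm`` (unnormalized)."""
    return (np.abs(z_rel_mm) <= depth_mm / 2.0).astype(float)


def _zscan_expected(conc, species_eps_exc, eps_em_val, instrument, z_cell_mm,
                    z_focal_mm):
    """Expected relative signal at each focal position (internal helper)."""
    exc = excitation_profile(z_cell_mm, conc, species_eps_exc)
    esc = 10.0 ** (-_column_od(z_cell_mm, conc, eps_em_val))
    conc_arr = np.broadcast_to(np.asarray(conc, float), z_cell_mm.shape)
    emitter = exc * conc_arr * esc
    dz = z_cell_mm[1] - z_cell_mm[0]
    out = np.empty(z_focal_mm.size)
    for i, zf in enumerate(z_focal_mm):
        w = _collection_weight(z_cell_mm - zf, instrument.confocal_depth_mm)
        out[i] = (w * emitter).sum() * dz
    return out


def simulate_zscan(
    species: Species | Sequence[Species],
    instrument: InstrumentModel,
    z_grid_mm: np.ndarray,
    *,
    wavelengths_nm: Sequence[float] = (540.0,),
    radius_cm: float = 6.6,
    speed_rpm: float = 5000.0,
    in_vacuum: bool = True,
    exposure_ms: float = 10.0,
    rng: np.random.Generator | None = None,
) -> ZScan:
    """Axial scan through a (stationary) uniformly loaded cell.

    The commanded z grid is translated to cell coordinates using the cell
    face position and, in vacuum, the vacuum shift.  A dilute sample yields
    a symmetric profile peaked at the cell centre; strong excitation
    attenuation (primary inner filter) shifts the peak toward the incident
    face and makes the profile asymmetric.
    """
    z_grid_mm = np.asarray(z_grid_mm, dtype=float)
    if np.any(np.diff(z_grid_mm) <= 0):
        raise ValueError("z grid must be strictly increasing")
    species_list = [species] if isinstance(species, Species) else list(species)
    wavelengths = np.asarray(wavelengths_nm, dtype=float)

    z_face = instrument.cell_face_z_mm + (
        instrument.z_vacuum_shift_mm if in_vacuum else 0.0)
    # fine axial grid through the cell, in cell coordinates (0 = near face)
    z_cell = np.linspace(0.0, instrument.cell_depth_mm, 301)
    z_focal = z_grid_mm - z_face  # focal position in cell coordinates

    counts = np.zeros((z_grid_mm.size, wavelengths.size))
    for sp in species_list:
        if sp.emission_nm is not None:
            em = np.interp(wavelengths, sp.emission_nm, sp.emission_density,
                           left=0.0, right=0.0)
        else:
            em = np.ones(wavelengths.size) / max(wavelengths.size, 1)
        for j, lam in enumerate(wavelengths):
            eps_em_val = float(sp.eps_em_at(np.array([lam]))[0])
            rel = _zscan_expected(sp.c0, sp.eps_exc, eps_em_val, instrument,
                                  z_cell, z_focal)
            counts[:, j] += (instrument.photon_budget * exposure_ms
                             * sp.exc_eff * em[j] * rel)
    out = detect(counts, instrument, rng)
    return ZScan(z_mm=z_grid_mm, wavelength_nm=wavelengths, counts=out,
                 radius_cm=radius_cm, speed_rpm=speed_rpm,
                 exposure_ms=exposure_ms)


# ---------------------------------------------------------------------------
# Radial response and SV datasets
# ---------------------------------------------------------------------------

def radial_response_sigma_cm(instrument: InstrumentModel) -> float:
    """Gaussian sigma (cm) of the radial point-spread function.

    Signal is generated where the excitation beam hits and accepted wherever
    that falls inside the (much wider) collection flat-top, so the effective
    radial weight is the product of the two profiles.  With the
    second-generation geometry (135 um flat-top collection) this is the
    excitation Gaussian essentially unchanged; a collection spot narrower
    than the beam truncates it instead (first-generation behaviour).

    The excitation profile is modelled as a Gaussian whose FWHM equals the
    quoted in-cell spot diameter: this is the only reading under which the
    instrument's spot size and its 10-90% radial resolution (both ~40 um)
    are mutually consistent, since the 10-90% edge width of a Gaussian
    response is 1.09 x FWHM.
    """
    sigma_exc = instrument.laser_spot_diameter_um / 2.354820045  # FWHM -> sigma
    return sigma_exc * 1e-4


def _apply_radial_psf(radii_fine_cm, profile, instrument):
    h = radii_fine_cm[1] - radii_fine_cm[0]
    sigma_px = radial_response_sigma_cm(instrument) / h
    half_coll = 0.5 * instrument.collection_spot_um * 1e-4
    sigma_cm = radial_response_sigma_cm(instrument)
    if half_coll < 3.0 * sigma_cm:
        # collection aperture truncates the excitation Gaussian
        u = np.arange(-int(np.ceil(4 * sigma_px)), int(np.ceil(4 * sigma_px)) + 1)
        w = np.exp(-0.5 * (u / sigma_px) ** 2)
        w *= (np.abs(u * h) <= half_coll)
        w /= w.sum()
        return np.convolve(profile, w, mode="same")
    return gaussian_filter1d(profile, sigma_px, mode="nearest")


def _inner_filter_factor(instrument: InstrumentModel, conc, eps_total):
    """Column-averaged attenuation for a z-uniform concentration.

    The collection window (flat-top of width confocal_depth) is centred on
    the cell centre; over that window the Beer-Lambert factor
    10^(-eps c z) is averaged analytically.
    """
    depth = instrument.confocal_depth_mm
    zc = instrument.cell_depth_mm / 2.0
    z0 = max(0.0, zc - depth / 2.0) * 0.1   # cm
    z1 = min(instrument.cell_depth_mm, zc + depth / 2.0) * 0.1
    k = np.asarray(eps_total * np.asarray(conc) * np.log(10.0))
    span = z1 - z0
    small = np.abs(k) < 1e-12
    kk = np.where(small, 1.0, k)
    avg = (np.exp(-kk * z0) - np.exp(-kk * z1)) / (kk * span)
    return np.where(small, 1.0, avg)


def simulate_sv_dataset(
    species: Sequence[Species],
    solvent: SolventModel,
    protocol: RotorProtocol,
    instrument: InstrumentModel,
    noise: NoiseOptions | None = None,
    seed: int = 0,
    *,
    scan_duration_s: float = 0.0,
) -> ScanSet:
    """Simulate a full sedimentation-velocity multiwavelength dataset.

    Deterministic given ``seed``.  Scan timestamps include the consecutive
    acquisition offset ``scan_duration_s`` accumulated per scan (cells are
    scanned one after another).  Injected systematic noise and the seed are
    recorded in the ``ground_truth`` sidecar.
    """
    noise = noise or NoiseOptions()
    rng = np.random.default_rng(seed)
    radii = protocol.radii()
    times = protocol.scan_times() + scan_duration_s * np.arange(protocol.n_scans)
    lam = instrument.wavelength_grid()
    nt, nr, nl = times.size, radii.size, lam.size

    expected = np.zeros((nt, nr, nl))
    truth_species = []
    for sp in species:
        if sp.emission_nm is None:
            raise ValueError(f"species {sp.name!r} has no emission spectrum")
        sol = solve_lamm(sp, solvent, protocol, times)
        spec_px = disperse_spectrum(sp.emission_nm, sp.emission_density,
                                    instrument)  # unit-area band -> per pixel
        eps_em_px = sp.eps_em_at(lam)
        for k in range(nt):
            fine = _apply_radial_psf(sol.radii, sol.profiles[k], instrument)
            c_r = np.interp(radii, sol.radii, fine)
            base = (instrument.photon_budget * instrument.exposure_ms
                    * sp.exc_eff) * c_r
            if sp.eps_exc > 0 or sp.eps_em is not None:
                att = _inner_filter_factor(
                    instrument, c_r[:, None], sp.eps_exc + eps_em_px[None, :])
                expected[k] += base[:, None] * spec_px[None, :] * att
            else:
                expected[k] += base[:, None] * spec_px[None, :]
        truth_species.append({
            "name": sp.name, "s": sp.s, "ff0": sp.ff0, "vbar": sp.vbar,
            "c0": sp.c0,
            "lambda_max": float(sp.emission_nm[np.argmax(sp.emission_density)]),
        })

    # reference amplitude for the noise injections: the usable-signal peak,
    # excluding the last mm before the bottom where back-diffusion piles up
    usable = radii <= protocol.bottom_cm - 0.1
    peak = expected[:, usable, :].max() if expected[:, usable, :].max() > 0 \
        else 1.0
    ti_profile = np.zeros(nr)
    ri_offsets = np.zeros(nt)
    if noise.ti_amplitude:
        x = (radii - radii[0]) / (radii[-1] - radii[0])
        ti_profile = noise.ti_amplitude * peak * np.sin(2.5 * np.pi * x + 0.7)
        expected += ti_profile[None, :, None]
    if noise.ri_amplitude:
        ri_offsets = noise.ri_amplitude * peak * rng.standard_normal(nt)
        expected += ri_offsets[:, None, None]
    if noise.beam_drift_frac:
        ramp = 1.0 + noise.beam_drift_frac * (radii - radii[0]) / (
            radii[-1] - radii[0])
        expected *= ramp[None, :, None]
    expected = np.clip(expected, 0.0, None)

    counts = detect(expected, instrument, rng if noise.detector else None)
    if not noise.detector:
        counts = np.clip(np.rint(counts), 0, instrument.counts_max)
    counts = counts.astype(np.uint16)

    ground_truth = {
        "seed": seed,
        "species": truth_species,
        "solvent": {"density": solvent.density, "viscosity": solvent.viscosity,
                    "temperature": solvent.temperature},
        "ti_profile": ti_profile,
        "ri_offsets": ri_offsets,
        "expected_peak": float(peak),
    }
    return ScanSet(times_s=times, radius_cm=radii, wavelength_nm=lam,
                   counts=counts, speed_rpm=protocol.speed_rpm,
                   exposure_ms=instrument.exposure_ms, instrument=instrument,
                   ground_truth=ground_truth,
                   meniscus_cm=protocol.meniscus_cm,
                   bottom_cm=protocol.bottom_cm)


def simulate_edge_scan(
    instrument: InstrumentModel,
    *,
    step_cm: float = 6.6,
    radii_cm: np.ndarray | None = None,
    amplitude_e: float = 20000.0,
    rng: np.random.Generator | None = None,
) -> Scan:
    """Radial scan across a sharp fluorophore concentration step.

    The fluorophore fills radii beyond ``step_cm``; the recorded edge is
    blurred by the radial response (excitation spot through the collection
    aperture) and sampled at the scan step.  Noise-free when rng is None.
    """
    if radii_cm is None:
        radii_cm = np.arange(step_cm - 0.35, step_cm + 0.35, 50e-4)
    radii_cm = np.asarray(radii_cm, dtype=float)
    fine = np.arange(radii_cm[0] - 0.05, radii_cm[-1] + 0.05, 2e-4)
    ideal = (fine >= step_cm).astype(float)
    blurred = _apply_radial_psf(fine, ideal, instrument)
    rel = np.interp(radii_cm, fine, blurred)
    expected = amplitude_e * rel[:, None]
    counts = detect(expected, instrument, rng)
    if rng is None:
        counts = np.rint(counts).astype(np.uint16)
    return Scan(time_s=0.0, speed_rpm=0.0, z_mm=0.0, radius_cm=radii_cm,
                wavelength_nm=np.asarray([instrument.laser_nm + 20.0]),
                counts=counts, exposure_ms=instrument.exposure_ms)


def simulate_calibration_scan(
    disk: CalibrationDisk,
    instrument: InstrumentModel,
    *,
    offset_um: float = 0.0,
    step_scale: float = 1.0,
    radii_cm: np.ndarray | None = None,
    amplitude_e: float = 20000.0,
    rng: np.random.Generator | None = None,
) -> Scan:
    """Radial scan over the calibration disk.

    Fluorescence from the backing is high in the transparent gaps and
    blocked under the opaque bars; edges are blurred by the excitation spot.
    ``offset_um`` and ``step_scale`` map commanded radii to physical ones:
    r_phys = step_scale * r_cmd + offset.
    """
    if radii_cm is None:
        radii_cm = np.arange(5.85, 7.25, 50e-4)
    radii_cm = np.asarray(radii_cm, dtype=float)
    r_phys = step_scale * radii_cm + offset_um * 1e-4

    fine = np.arange(r_phys[0] - 0.05, r_phys[-1] + 0.05, 2e-4)
    ideal = np.zeros(fine.size)
    for a, b in disk.gaps_cm:
        ideal += (fine >= a) & (fine < b)
    blurred = _apply_radial_psf(fine, ideal, instrument)
    rel = np.interp(r_phys, fine, blurred)

    lam = np.asarray([520.0])
    expected = amplitude_e * rel[:, None]
    counts = detect(expected, instrument, rng)
    if rng is None:
        counts = np.rint(counts).astype(np.uint16)
    return Scan(time_s=0.0, speed_rpm=0.0, z_mm=0.0, radius_cm=radii_cm,
                wavelength_nm=lam, counts=counts,
                exposure_ms=instrument.exposure_ms)
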