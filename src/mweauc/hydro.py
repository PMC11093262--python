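"""Sedimentation/diffusion physics for sector-shaped AUC cells.

This module provides the hydrodynamic ground truth used everywhere else in
the package: species descriptions, closed-form sedimentation relations
(Svedberg equation, radial dilution, diffusion-free boundary motion) and a
conservative finite-volume solver for the Lamm equation

    dc/dt = (1/r) d/dr [ r ( D dc/dr - s w^2 r^2 c ) ]

with impermeable boundaries at the meniscus and the cell bottom.

Units follow AUC conventions: radii in cm, time in s, sedimentation
coefficients in Svedberg (1 S = 1e-13 s) at the user surface and in seconds
internally, diffusion coefficients in cm^2 s^-1, solvent density in g cm^-3,
viscosity in mPa s, temperature in K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

__all__ = [
    "SVEDBERG",
    "Species",
    "SolventModel",
    "RotorProtocol",
    "LammSolution",
    "water20",
    "standard_analysis_solvent",
    "svedberg_mass",
    "stokes_radius",
    "diffusion_from_s",
    "solve_lamm",
    "faxen_boundary",
    "radial_dilution",
    "GridResolutionError",
]

#: 1 Svedberg in seconds.
SVEDBERG = 1e-13

# CGS constants (erg-based; radii in cm, masses in g).
_KB = 1.380649e-16  # erg / K
_R_GAS = 8.31446261815324e7  # erg / (mol K)
_AVOGADRO = 6.02214076e23


class GridResolutionError(ValueError):
    """Raised when the radial/temporal discretization cannot resolve the run."""


@dataclass
class Species:
    """One sedimenting fluorophore.

    Parameters
    ----------
    name : str
        Label used in reports and ground-truth sidecars.
    s : float
        Sedimentation coefficient in Svedberg.
    ff0 : float
        Frictional ratio f/f0 (>= 1; 1 for a compact sphere).
    vbar : float
        Partial specific volume in cm^3 g^-1.
    c0 : float
        Loading concentration in arbitrary signal-equivalent units.
    emission_nm, emission_density : arrays
        Tabulated relative emission density over wavelength (nm); it is
        renormalized to unit area on construction.
    exc_eff : float
        Relative excitation efficiency at the laser wavelength (0-1).
    eps_exc : float
        Decadic attenuation coefficient at the excitation wavelength, per
        concentration unit per cm (inner-filter strength; 0 = transparent).
    eps_em_nm, eps_em : arrays, optional
        Decadic attenuation at emission wavelengths (secondary inner filter).
    """

    name: str
    s: float
    ff0: float = 1.2
    vbar: float = 0.73
    c0: float = 1.0
    emission_nm: np.ndarray | None = None
    emission_density: np.ndarray | None = None
    exc_eff: float = 1.0
    eps_exc: float = 0.0
    eps_em_nm: np.ndarray | None = None
    eps_em: np.ndarray | None = None

    def __post_init__(self):
        if self.s < 0:
            raise ValueError(f"s must be >= 0, got {self.s}")
        if self.ff0 < 1.0:
            raise ValueError(f"ff0 must be >= 1, got {self.ff0}")
        if not (0.0 < self.vbar < 1.2):
            raise ValueError(f"vbar must lie in (0, 1.2), got {self.vbar}")
        if self.c0 < 0:
            raise ValueError("c0 must be >= 0")
        if self.eps_exc < 0:
            raise ValueError("eps_exc must be >= 0")
        if self.emission_nm is not None:
            lam = np.asarray(self.emission_nm, dtype=float)
            dens = np.asarray(self.emission_density, dtype=float)
            if lam.shape != dens.shape or lam.ndim != 1:
                raise ValueError("emission grid and density must be matching 1-D arrays")
            if np.any(dens < 0):
                raise ValueError("emission density must be nonnegative")
            area = np.trapezoid(dens, lam)
            if area <= 0:
                raise ValueError("emission density must have positive area")
            self.emission_nm = lam
            self.emission_density = dens / area
        if self.eps_em is not None:
            if np.any(np.asarray(self.eps_em) < 0):
                raise ValueError("eps_em must be >= 0")

    def eps_em_at(self, lam_nm: np.ndarray) -> np.ndarray:
        """Decadic emission attenuation coefficient interpolated at lam_nm."""
        lam_nm = np.asarray(lam_nm, dtype=float)
        if self.eps_em is None:
            return np.zeros_like(lam_nm)
        return np.interp(lam_nm, np.asarray(self.eps_em_nm, float),
                         np.asarray(self.eps_em, float))

    @staticmethod
    def gaussian_emitter(name, s, lam_max, fwhm_nm, *, ff0=1.2, vbar=0.73, c0=1.0,
                         grid=None, **kw) -> "Species":
        """Convenience constructor with a Gaussian emission band."""
        sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        if grid is None:
            grid = np.arange(max(300.0, lam_max - 3.5 * sigma),
                             lam_max + 3.5 * sigma, 0.5)
        dens = np.exp(-0.5 * ((grid - lam_max) / sigma) ** 2)
        return Species(name=name, s=s, ff0=ff0, vbar=vbar, c0=c0,
                       emission_nm=grid, emission_density=dens, **kw)


@dataclass(frozen=True)
class SolventModel:
    """Solvent density (g cm^-3), viscosity (mPa s) and temperature (K)."""

    density: float = 0.99823
    viscosity: float = 1.002
    temperature: float = 293.15

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0 or self.temperature <= 0:
            raise ValueError("density, viscosity and temperature must be positive")

    def buoyancy(self, vbar: float) -> float:
        """Buoyancy factor 1 - vbar*rho; warns (does not raise) on flotation."""
        b = 1.0 - vbar * self.density
        if b <= 0:
            warnings.warn(
                f"1 - vbar*rho = {b:.4g} <= 0: species floats in this solvent",
                stacklevel=2,
            )
        return b

    @property
    def viscosity_poise(self) -> float:
        return self.viscosity * 0.01  # 1 mPa s = 0.01 poise


def water20() -> SolventModel:
    """Water at 20 C (rho = 0.99823 g cm^-3, eta = 1.002 mPa s)."""
    return SolventModel()


def standard_analysis_solvent() -> SolventModel:
    """The conventional analysis solvent: rho = 1.0 g/cm^3, eta = 1.002 mPa s."""
    return SolventModel(density=1.0, viscosity=1.002, temperature=293.15)


@dataclass
class RotorProtocol:
    """Rotor speed, cell geometry and scan schedule of one velocity run."""

    speed_rpm: float = 40_000.0
    meniscus_cm: float = 6.0
    bottom_cm: float = 7.2
    radial_step_um: float = 50.0
    scan_interval_s: float = 90.0
    n_scans: int = 30
    start_delay_s: float = 0.0

    def __post_init__(self):
        if self.speed_rpm <= 0:
            raise ValueError("speed_rpm must be positive")
        if not self.meniscus_cm < self.bottom_cm:
            raise ValueError("meniscus must lie below (smaller radius than) bottom")
        if self.radial_step_um <= 0 or self.n_scans < 1:
            raise ValueError("invalid radial step or scan count")

    @property
    def omega(self) -> float:
        """Angular velocity in rad s^-1."""
        return 2.0 * np.pi * self.speed_rpm / 60.0

    @property
    def omega2(self) -> float:
        return self.omega ** 2

    def radii(self) -> np.ndarray:
        """Strictly increasing radial grid at the configured step, in cm."""
        step_cm = self.radial_step_um * 1e-4
        n = int(np.floor((self.bottom_cm - self.meniscus_cm) / step_cm)) + 1
        return self.meniscus_cm + step_cm * np.arange(n)

    def scan_times(self) -> np.ndarray:
        return self.start_delay_s + self.scan_interval_s * (
            1.0 + np.arange(self.n_scans))


# ---------------------------------------------------------------------------
# Closed-form relations
# ---------------------------------------------------------------------------

def svedberg_mass(s, D, vbar, solvent: SolventModel) -> float:
    """Molar mass (kg mol^-1) from the Svedberg relation M = sRT / (D(1-vbar*rho)).

    Parameters: s in Svedberg, D in cm^2 s^-1, vbar in cm^3 g^-1.
    Raises ValueError at neutral buoyancy (1 - vbar*rho = 0).
    """
    if D <= 0:
        raise ValueError("D must be positive")
    b = 1.0 - vbar * solvent.density
    if b == 0:
        raise ValueError("neutral buoyancy: 1 - vbar*rho = 0, mass undefined")
    s_sec = s * SVEDBERG
    m_g_per_mol = s_sec * _R_GAS * solvent.temperature / (D * b)
    return m_g_per_mol / 1000.0


def stokes_radius(s, ff0, vbar, solvent: SolventModel) -> float:
    """Radius (cm) of the compact sphere consistent with (s, ff0, vbar).

    Eliminating M between the Svedberg and Stokes-Einstein relations gives
    R0 = sqrt(9 s eta ff0 vbar / (2 (1 - vbar rho))) for the equivalent
    compact sphere; the hydrodynamic radius is ff0 * R0.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    if ff0 < 1:
        raise ValueError("ff0 must be >= 1")
    b = solvent.buoyancy(vbar)
    if b <= 0:
        raise ValueError("1 - vbar*rho must be positive for sedimentation")
    s_sec = s * SVEDBERG
    eta = solvent.viscosity_poise
    return np.sqrt(9.0 * s_sec * eta * ff0 * vbar / (2.0 * b))


def diffusion_from_s(s, ff0, vbar, solvent: SolventModel) -> float:
    """Diffusion coefficient D(s) (cm^2 s^-1) implied by the c(s) scaling law.

    The distribution model parameterizes each s value by a single frictional
    ratio: the species is the compact sphere of radius R0(s) inflated by ff0,
    so D = kT / (6 pi eta ff0 R0).  This is the standard hydrodynamic scaling
    D propto s^(-1/2) (eta ff0)^(-3/2) ((1-vbar rho)/vbar)^(1/2).
    """
    r0 = stokes_radius(s, ff0, vbar, solvent)
    eta = solvent.viscosity_poise
    return _KB * solvent.temperature / (6.0 * np.pi * eta * ff0 * r0)


def faxen_boundary(s, omega, r_m, t):
    """Diffusion-free boundary position r_m * exp(s omega^2 t) (cm).

    s in Svedberg; omega in rad/s; t in s (scalar or array).
    """
    if r_m <= 0:
        raise ValueError("meniscus radius must be positive")
    s_sec = np.asarray(s, dtype=float) * SVEDBERG
    if np.any(s_sec < 0) or np.any(np.asarray(t) < 0):
        raise ValueError("s and t must be >= 0")
    return r_m * np.exp(s_sec * omega ** 2 * np.asarray(t, dtype=float))


def radial_dilution(s, omega, t):
    """Square-dilution plateau factor exp(-2 s omega^2 t), in (0, 1]."""
    s_sec = np.asarray(s, dtype=float) * SVEDBERG
    return np.exp(-2.0 * s_sec * omega ** 2 * np.asarray(t, dtype=float))


# ---------------------------------------------------------------------------
# Lamm solver
# ---------------------------------------------------------------------------

def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), evaluated without overflow."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    big_pos = x > 500.0
    big_neg = x < -500.0
    mid = ~(small | big_pos | big_neg)
    out[small] = 1.0 - 0.5 * x[small]
    out[big_pos] = 0.0
    out[big_neg] = -x[big_neg]
    out[mid] = x[mid] / np.expm1(x[mid])
    return out


@dataclass
class LammSolution:
    """Radial concentration profiles c(r, t) from the Lamm solver."""

    radii: np.ndarray          # cell-center radii, cm
    times: np.ndarray          # s
    profiles: np.ndarray       # (n_times, n_radii)
    meniscus: float
    bottom: float
    c0: float

    def interp(self, radii_out: np.ndarray) -> np.ndarray:
        """Profiles linearly interpolated onto radii_out, shape (n_t, len(out))."""
        radii_out = np.asarray(radii_out, dtype=float)
        out = np.empty((self.profiles.shape[0], radii_out.size))
        for k in range(self.profiles.shape[0]):
            out[k] = np.interp(radii_out, self.radii, self.profiles[k])
        return out

    def sector_mass(self) -> np.ndarray:
        """Per-scan sector mass integral (c r dr) on the cell-center grid."""
        h = self.radii[1] - self.radii[0]
        return (self.profiles * self.radii * h).sum(axis=1)

    def boundary_midpoint(self, plateau_frac: float = 0.5) -> np.ndarray:
        """Radius where each profile first crosses plateau_frac * plateau level.

        The plateau level is estimated as the median over the outer half of
        the column (excluding the bottom accumulation zone).
        """
        n = self.radii.size
        lo, hi = int(0.55 * n), int(0.9 * n)
        out = np.full(self.times.shape, np.nan)
        for k, prof in enumerate(self.profiles):
            plateau = np.median(prof[lo:hi])
            if plateau <= 0:
                continue
            target = plateau_frac * plateau
            idx = np.nonzero(prof[:hi] >= target)[0]
            if idx.size == 0 or idx[0] == 0:
                out[k] = self.radii[0]
                continue
            i = idx[0]
            r0, r1 = self.radii[i - 1], self.radii[i]
            y0, y1 = prof[i - 1], prof[i]
            out[k] = r0 + (target - y0) / (y1 - y0) * (r1 - r0)
        return out


def solve_lamm(
    species: Species,
    solvent: SolventModel,
    protocol: RotorProtocol,
    times: Sequence[float],
    *,
    n_radial: int | None = None,
    dt_max: float | None = None,
    theta: float = 0.5,
    D: float | None = None,
    include_t0: bool = False,
) -> LammSolution:
    """Solve the Lamm equation for one species with closed boundaries.

    Conservative finite-volume discretization in sector geometry with
    Scharfetter-Gummel (exponential-fitted) face fluxes, which remain
    monotone at arbitrary cell Peclet number, and an implicit theta scheme
    in time (theta=0.5: Crank-Nicolson with two implicit-Euler startup steps).

    Parameters
    ----------
    times : increasing scan times (s).  t=0 carries the uniform loading c0.
    n_radial : number of finite-volume cells (default: 8 um cells, >= 240).
    dt_max : largest internal time step (default: span/400, capped at 60 s).
    D : override the diffusion coefficient (cm^2/s); by default it is
        derived from (s, ff0, vbar) via :func:`diffusion_from_s`.

    Raises
    ------
    GridResolutionError
        If the requested radial grid is too coarse to resolve boundary
        transport in the configured Peclet regime (fewer than 50 cells or
        cells wider than 100 um).
    """
    r_m, r_b = protocol.meniscus_cm, protocol.bottom_cm
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be nonnegative and strictly increasing")

    if n_radial is None:
        n_radial = max(240, int(np.ceil((r_b - r_m) / 8e-4)))
    h = (r_b - r_m) / n_radial
    if n_radial < 50 or h > 0.0100001:
        raise GridResolutionError(
            f"radial grid too coarse ({n_radial} cells of {h*1e4:.0f} um) for the "
            "sedimentation Peclet regime; boundary transport would be dominated "
            "by numerical diffusion. Increase n_radial (cells should be <= 100 um)."
        )

    if D is None:
        if species.s > 0:
            D = diffusion_from_s(species.s, species.ff0, species.vbar, solvent)
        else:
            D = 1e-7
    if D < 0:
        raise ValueError("D must be >= 0")
    D = max(D, 1e-30)  # SG formulation needs D > 0; this is effectively zero

    s_sec = species.s * SVEDBERG
    w2 = protocol.omega2

    faces = r_m + h * np.arange(n_radial + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    vol = centers * h  # sector volume weight per unit angle and path

    # Face drift velocities (outward positive) and SG coefficients.
    vf = s_sec * w2 * faces[1:-1]
    pe = vf * h / D
    b_minus = _bernoulli(-pe)   # multiplies upstream (inner) cell
    b_plus = _bernoulli(pe)     # multiplies downstream (outer) cell

    # Rate matrix A with c' = A c from flux balance (interior faces only).
    n = n_radial
    coef = D / h
    f_in = faces[1:-1]
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    # face j sits between cells j-1 and j, j = 1..n-1
    flux_a = coef * b_minus   # * c_{j-1}
    flux_b = -coef * b_plus   # * c_j
    # cell j-1 loses f_in*J / vol[j-1]; cell j gains f_in*J / vol[j]
    diag[:-1] -= f_in * flux_a / vol[:-1]
    upper[:-1] = -f_in * flux_b / vol[:-1]
    diag[1:] += f_in * flux_b / vol[1:]
    lower[1:] = f_in * flux_a / vol[1:]

    A = sparse.diags([lower[1:], diag, upper[:-1]], offsets=[-1, 0, 1],
                     format="csc")

    span = times[-1]
    if dt_max is None:
        dt_max = min(60.0, max(1.0, span / 400.0))

    ident = sparse.identity(n, format="csc")
    lu_cache: dict[tuple[float, float], object] = {}

    def step(c, dt, th):
        key = (round(dt, 9), th)
        if key not in lu_cache:
            lu_cache[key] = splu((ident - th * dt * A).tocsc())
        rhs = c if th == 1.0 else c + (1.0 - th) * dt * (A @ c)
        return lu_cache[key].solve(rhs)

    c = np.full(n, float(species.c0))
    profiles = []
    out_times = []
    if include_t0 or times[0] == 0.0:
        profiles.append(c.copy())
        out_times.append(0.0)

    t_now = 0.0
    startup_left = 2 if theta < 1.0 else 0
    for t_target in times:
        if t_target == 0.0:
            continue
        dt_span = t_target - t_now
        n_sub = max(1, int(np.ceil(dt_span / dt_max)))
        dt = dt_span / n_sub
        for _ in range(n_sub):
            if startup_left > 0:
                c = step(c, dt, 1.0)
                startup_left -= 1
            else:
                c = step(c, dt, theta)
        t_now = t_target
        profiles.append(c.copy())
        out_times.append(t_now)

    return LammSolution(
        radii=centers,
        times=np.asarray(out_times),
        profiles=np.asarray(profiles),
        meniscus=r_m,
        bottom=r_b,
        c0=species.c0,
    )
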