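"""Multiwavelength sedimentation analysis: 2D c(s, lambda) distributions.

Consecutive per-wavelength c(s) fits against a single shared Lamm kernel
are assembled into a sedimentation-coefficient x emission-wavelength
distribution; species are extracted as ridges in that distribution and can
be refined by a global discrete-species fit across selected wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .hydro import RotorProtocol, SolventModel, Species, solve_lamm
from .instrument import ScanSet
from .cs import CsModel, FitConfig, _project_noise

__all__ = [
    "C2D",
    "SpeciesEstimate",
    "MultiWavelengthModel",
    "fit_cs_lambda",
    "extract_species",
    "global_species_fit",
    "GlobalSpeciesFit",
]


@dataclass
class SpeciesEstimate:
    """One sedimenting emitter extracted from a 2D distribution."""

    s: float                     # Svedberg (weighted mean over the ridge)
    spectrum: np.ndarray         # amplitude over the wavelength grid
    wavelength_nm: np.ndarray
    lambda_max_nm: float         # quadratic interpolation around the maximum
    abundance: float             # share of total integrated signal
    support: tuple[int, int]     # index range on the s grid


@dataclass
class C2D:
    """Sedimentation-coefficient x emission-wavelength distribution."""

    s_grid: np.ndarray           # (n_s,)
    wavelength_nm: np.ndarray    # (n_lambda,)
    amplitudes: np.ndarray       # (n_s, n_lambda), >= 0, rescaled units
    rmsd: np.ndarray             # per-wavelength rmsd
    alpha: np.ndarray            # per-wavelength penalty weight
    vbar: float
    ff0: float
    meniscus: float
    scale_factor: float
    config: FitConfig
    ti_noise: np.ndarray | None = None   # (n_radii, n_lambda)
    ri_noise: np.ndarray | None = None   # (n_scans, n_lambda)

    def integrated_cs(self) -> np.ndarray:
        """c(s) summed over the wavelength axis."""
        return self.amplitudes.sum(axis=1)

    def extract_species(self, threshold: float = 0.05) -> list[SpeciesEstimate]:
        return extract_species(self, threshold=threshold)

    def summary(self) -> str:
        lines = [
            "2D sedimentation-wavelength distribution",
            "=" * 54,
            f"  s grid      : {self.s_grid.size} points, "
            f"{self.s_grid[0]:.3g}-{self.s_grid[-1]:.3g} S",
            f"  wavelengths : {self.wavelength_nm.size} steps, "
            f"{self.wavelength_nm[0]:.1f}-{self.wavelength_nm[-1]:.1f} nm",
            f"  shared vbar/ff0 : {self.vbar:.4f} / {self.ff0:.3f}",
            f"  median rmsd : {np.median(self.rmsd):.5g} (rescaled units)",
            "  species (>=5% of max, lambda-integrated):",
        ]
        species = self.extract_species()
        for sp in species:
            lines.append(
                f"    s = {sp.s:7.3f} S   lambda_max = {sp.lambda_max_nm:6.1f} nm"
                f"   abundance = {sp.abundance:6.1%}")
        if not species:
            lines.append("    (none)")
        return "\n".join(lines)


class MultiWavelengthModel:
    """Consecutive per-wavelength c(s) analyses of one multiwavelength run.

    The Lamm kernel depends only on the shared hydrodynamic parameters and
    is computed once; per-wavelength fits are pure functions of their slice,
    so processing order (or parallel execution) cannot change the result.
    A single rescaling factor (global maximum below ``config.rescale_max``)
    keeps amplitudes comparable across wavelengths.
    """

    def __init__(self, scanset: ScanSet, protocol: RotorProtocol | None = None,
                 solvent: SolventModel | None = None,
                 config: FitConfig | None = None):
        self.scanset = scanset
        self.config = config or FitConfig()
        self.solvent = solvent or SolventModel(density=1.0)
        if protocol is None:
            if scanset.meniscus_cm is None:
                raise ValueError("scan set carries no geometry; pass a protocol")
            protocol = RotorProtocol(
                speed_rpm=scanset.speed_rpm,
                meniscus_cm=scanset.meniscus_cm,
                bottom_cm=scanset.bottom_cm,
                n_scans=scanset.n_scans,
            )
        self.protocol = protocol

    def fit(self, *, wavelength_step_nm: float = 1.5,
            window_nm: tuple[float, float] | None = None,
            wavelengths_nm: Sequence[float] | None = None,
            bin_nm: float | None = None) -> C2D:
        """Fit c(s) at every wavelength step and assemble the 2D distribution.

        ``wavelength_step_nm`` bins sensor pixels to the analysis step
        (1.5 nm by default); ``window_nm`` restricts the spectral range;
        alternatively an explicit list of wavelengths selects slices
        (single-pixel, or averaged over ``bin_nm``).
        """
        ss = self.scanset
        if wavelengths_nm is not None:
            lam = np.asarray(wavelengths_nm, dtype=float)
            if lam.size == 0:
                raise ValueError("empty wavelength selection")
            sig = np.stack([ss.slice_wavelength(l, bin_nm=bin_nm)
                            for l in lam], axis=2)
        else:
            lam, sig = ss.binned(wavelength_step_nm, window_nm)
            if lam.size == 0:
                raise ValueError("empty wavelength selection")

        scale_ref = np.abs(sig).max()
        cfg = self.config
        scale = scale_ref / cfg.rescale_max if scale_ref > cfg.rescale_max \
            else 1.0

        # one model per wavelength, all sharing a single kernel
        model0 = CsModel(sig[:, :, 0], ss.radius_cm, ss.times_s, self.protocol,
                         self.solvent, cfg)
        kernel = model0.kernel()
        n_s = cfg.n_s
        amps = np.zeros((n_s, lam.size))
        rmsd = np.zeros(lam.size)
        alpha = np.zeros(lam.size)
        ti = np.zeros((model0.radii.size, lam.size))
        ri = np.zeros((ss.n_scans, lam.size))
        for j in range(lam.size):
            model = CsModel(sig[:, :, j] / scale, ss.radius_cm, ss.times_s,
                            self.protocol, self.solvent, cfg, kernel=kernel)
            dist = model.fit()
            amps[:, j] = dist.amplitudes * dist.scale_factor
            rmsd[j] = dist.rmsd * dist.scale_factor
            alpha[j] = dist.alpha
            ti[:, j] = dist.ti_noise
            ri[:, j] = dist.ri_noise
        return C2D(s_grid=kernel.s_grid, wavelength_nm=lam, amplitudes=amps,
                   rmsd=rmsd, alpha=alpha, vbar=cfg.vbar, ff0=cfg.ff0,
                   meniscus=kernel.meniscus, scale_factor=scale, config=cfg,
                   ti_noise=ti, ri_noise=ri)


def fit_cs_lambda(scanset: ScanSet, config: FitConfig | None = None,
                  wavelength_step_nm: float = 1.5, *, protocol=None,
                  solvent=None, window_nm=None) -> C2D:
    """Functional wrapper around :class:`MultiWavelengthModel`."""
    return MultiWavelengthModel(scanset, protocol, solvent, config).fit(
        wavelength_step_nm=wavelength_step_nm, window_nm=window_nm)


def _quadratic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Peak abscissa by quadratic interpolation around the discrete maximum."""
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (x[i + 1] - x[i - 1])
    return float(x[i] + np.clip(delta, -1, 1) * step)


def extract_species(c2d: C2D, threshold: float = 0.05,
                    min_prominence: float = 0.2) -> list[SpeciesEstimate]:
    """Species as peaks of the wavelength-integrated c(s).

    Support regions are the contiguous stretches above ``threshold`` times
    the global maximum; a region containing several local maxima of
    relative prominence >= ``min_prominence`` is split at the interior
    minima between them (distinct species often share a broad plateau in
    the integrated distribution while their ridges separate cleanly along
    the wavelength axis).  Each species' emission spectrum is the amplitude
    slice summed over its s-support, with the emission maximum located by
    quadratic interpolation.  An all-zero distribution yields an empty list.
    """
    from scipy.signal import find_peaks

    total = c2d.integrated_cs()
    if total.max() <= 0:
        return []
    mask = total >= threshold * total.max()
    grand = total.sum()
    out: list[SpeciesEstimate] = []

    def emit(i, j):
        w = total[i:j + 1]
        s_mean = float((w * c2d.s_grid[i:j + 1]).sum() / w.sum())
        spectrum = c2d.amplitudes[i:j + 1, :].sum(axis=0)
        lam_max = _quadratic_peak(c2d.wavelength_nm, spectrum)
        out.append(SpeciesEstimate(
            s=s_mean, spectrum=spectrum, wavelength_nm=c2d.wavelength_nm,
            lambda_max_nm=lam_max, abundance=float(w.sum() / grand),
            support=(i, j)))

    i, n = 0, total.size
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        seg = total[i:j + 1]
        peaks, _ = find_peaks(seg, prominence=min_prominence * seg.max())
        if seg.argmax() not in peaks:
            peaks = np.sort(np.append(peaks, seg.argmax()))
        if peaks.size > 1:
            cuts = [int(i + peaks[k] + np.argmin(seg[peaks[k]:peaks[k + 1]]))
                    for k in range(peaks.size - 1)]
            lo = i
            for cut in cuts:
                emit(lo, cut)
                lo = cut + 1
            emit(lo, j)
        else:
            emit(i, j)
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# global discrete-species fit
# ---------------------------------------------------------------------------

@dataclass
class GlobalSpeciesFit:
    """Result of a K-species global fit across wavelengths."""

    s_values: np.ndarray             # (K,), Svedberg, shared across wavelengths
    amplitudes: np.ndarray           # (K, n_lambda)
    wavelength_nm: np.ndarray
    rmsd: float
    ff0: float
    vbar: float
    degenerate: bool                 # near-coincident s estimates flagged

    def summary(self) -> str:
        lines = ["global discrete-species fit", "=" * 54,
                 f"  wavelengths: {', '.join(f'{l:.0f}' for l in self.wavelength_nm)} nm",
                 f"  rmsd: {self.rmsd:.5g}"]
        for k, s in enumerate(self.s_values):
            lines.append(f"  species {k + 1}: s = {s:7.3f} S, amplitudes "
                         + np.array2string(self.amplitudes[k], precision=3))
        if self.degenerate:
            lines.append("  WARNING: near-degenerate s values; K likely "
                         "exceeds the identifiable number of species")
        return "\n".join(lines)


def global_species_fit(
    scanset: ScanSet,
    K: int,
    wavelengths_nm: Sequence[float],
    *,
    protocol: RotorProtocol | None = None,
    solvent: SolventModel | None = None,
    config: FitConfig | None = None,
    s_init: Sequence[float] | None = None,
    bin_nm: float = 3.0,
) -> GlobalSpeciesFit:
    """Fit K discrete species with shared s values across wavelengths.

    Nonlinear parameters are the K sedimentation coefficients (log-space);
    per-wavelength amplitudes and TI/RI noise are profiled out linearly at
    every trial (variable projection).  Initial s values come from
    ``s_init`` or from species extraction on a quick 2D analysis.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    cfg = config or FitConfig()
    solvent = solvent or SolventModel(density=1.0)
    model = MultiWavelengthModel(scanset, protocol, solvent, cfg)
    protocol = model.protocol
    lam = np.asarray(wavelengths_nm, dtype=float)
    if lam.size == 0:
        raise ValueError("no wavelengths selected")

    slices = [scanset.slice_wavelength(l, bin_nm=bin_nm) for l in lam]
    # window like CsModel does
    radii = scanset.radius_cm
    lo = cfg.window_lo_cm or protocol.meniscus_cm + 0.005
    hi = cfg.window_hi_cm or protocol.bottom_cm - 0.010
    keep = (radii >= lo) & (radii <= hi)
    radii_w = radii[keep]
    slices = [y[:, keep] for y in slices]
    times = scanset.times_s
    scale = max(np.abs(y).max() for y in slices) / cfg.rescale_max
    scale = max(scale, 1e-300)
    slices = [y / scale for y in slices]

    if s_init is None:
        c2d = model.fit(wavelengths_nm=lam, bin_nm=bin_nm)
        est = extract_species(c2d)
        if len(est) >= K:
            est = sorted(est, key=lambda e: -e.abundance)[:K]
            s0 = np.sort([e.s for e in est])
        else:
            base = [e.s for e in est] if est else [np.sqrt(cfg.s_min * cfg.s_max)]
            s0 = np.sort(np.concatenate([
                base, np.geomspace(cfg.s_min * 1.5, cfg.s_max / 1.5,
                                   K - len(base))]))[:K]
    else:
        s0 = np.sort(np.asarray(s_init, dtype=float))
        if s0.size != K:
            raise ValueError("s_init must provide K values")

    def design(s_values):
        cols = []
        for s in s_values:
            sp = Species(name="g", s=float(s), ff0=cfg.ff0, vbar=cfg.vbar,
                         c0=1.0)
            sol = solve_lamm(sp, solvent, protocol, times,
                             n_radial=max(300, 2 * radii_w.size))
            cols.append(sol.interp(radii_w))
        return cols  # list of (n_t, n_r)

    nt, nr = slices[0].shape

    def residuals(log_s):
        s_values = np.exp(log_s)
        cols = design(s_values)
        Dh = np.stack([
            _project_noise(c, cfg.fit_ti, cfg.fit_ri).ravel() for c in cols],
            axis=1)
        res = []
        amp = np.zeros((K, lam.size))
        for j, y in enumerate(slices):
            yh = _project_noise(y, cfg.fit_ti, cfg.fit_ri).ravel()
            a, *_ = np.linalg.lstsq(Dh, yh, rcond=None)
            amp[:, j] = a
            res.append(yh - Dh @ a)
        return np.concatenate(res), amp

    out = optimize.least_squares(
        lambda p: residuals(p)[0], np.log(s0),
        method="lm" if K * lam.size > 1 else "trf",
        xtol=1e-8, ftol=1e-10)
    s_fit = np.exp(out.x)
    resid, amp = residuals(out.x)
    order = np.argsort(s_fit)
    s_fit, amp = s_fit[order], amp[order]
    rmsd = float(np.sqrt(np.mean(resid ** 2)))
    degenerate = bool(np.any(np.diff(np.sort(s_fit)) / s_fit[:-1] < 0.02)) \
        if K > 1 else False
    return GlobalSpeciesFit(s_values=s_fit, amplitudes=amp * scale,
                            wavelength_nm=lam, rmsd=rmsd * scale,
                            ff0=cfg.ff0, vbar=cfg.vbar, degenerate=degenerate)
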