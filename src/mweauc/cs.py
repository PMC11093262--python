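"""Regularized c(s) inversion of single-wavelength sedimentation data.

The model for one wavelength slice of a velocity run is

    y(r_j, t_k) = sum_i a_i L(r_j, t_k; s_i) + ti(r_j) + ri(t_k) + noise

where the kernel columns L are unit-loading Lamm solutions with the
diffusion coefficient tied to s through a single frictional ratio,
a_i >= 0 is the loading carried by grid value s_i, ti is a fixed radial
pattern (time-invariant noise) and ri a per-scan offset (radial-invariant
noise).  The systematic-noise parameters enter linearly and are eliminated
algebraically by projecting data and kernel onto the orthogonal complement
of the noise subspace; on the complete scans x radii grid that projection
is exact double centering.

Regularization (second-derivative Tikhonov or maximum entropy) is scaled so
that the chi-square of the regularized fit stays within a one-sided
F-statistic bound relative to the unregularized fit at the configured
confidence level (0.683 by default, the one-sigma convention).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal
import warnings

import numpy as np
from scipy import optimize, stats

from .hydro import (
    RotorProtocol,
    SolventModel,
    Species,
    solve_lamm,
)

__all__ = [
    "FitConfig",
    "LammKernel",
    "build_lamm_kernel",
    "CsModel",
    "CsDistribution",
    "fit_cs",
    "select_regularization",
    "optimize_nonlinear",
]


@dataclass
class FitConfig:
    """Settings of a c(s) analysis.

    The s grid holds 150 log-spaced values by convention; exactly one of
    ff0/vbar may float in a nonlinear refinement at a time.
    """

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
    window_lo_cm: float | None = None   # analysis window (default: meniscus
    window_hi_cm: float | None = None   # + 50 um .. bottom - 100 um)
    rescale_max: float = 10.0
    kernel_n_radial: int | None = None
    kernel_dt_max: float | None = None

    def __post_init__(self):
        if not 0 < self.s_min < self.s_max:
            raise ValueError("need 0 < s_min < s_max")
        if self.n_s < 2:
            raise ValueError("n_s must be >= 2")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")

    def s_grid(self) -> np.ndarray:
        return np.geomspace(self.s_min, self.s_max, self.n_s)


@dataclass
class LammKernel:
    """Design matrix of unit-loading Lamm solutions on (times x radii)."""

    s_grid: np.ndarray
    radii: np.ndarray
    times: np.ndarray
    matrix: np.ndarray        # (n_times * n_radii, n_s), scan-major
    ff0: float
    vbar: float
    meniscus: float
    bottom: float

    @property
    def n_data(self) -> int:
        return self.matrix.shape[0]


def build_lamm_kernel(
    s_grid: np.ndarray,
    ff0: float,
    vbar: float,
    solvent: SolventModel,
    protocol: RotorProtocol,
    radii: np.ndarray,
    times: np.ndarray,
    *,
    n_radial: int | None = None,
    dt_max: float | None = None,
) -> LammKernel:
    """One unit-loading Lamm solution per s value, sampled at (times, radii).

    The kernel is computed once per set of hydrodynamic parameters and
    reused across wavelengths.
    """
    radii = np.asarray(radii, dtype=float)
    times = np.asarray(times, dtype=float)
    if radii[0] < protocol.meniscus_cm - 1e-9 or radii[-1] > protocol.bottom_cm + 1e-9:
        raise ValueError("analysis radii fall outside [meniscus, bottom]")
    if n_radial is None:
        # a few cells per data step is ample for the inversion kernel
        n_radial = max(300, 2 * radii.size)
    cols = np.empty((times.size * radii.size, s_grid.size))
    for i, s in enumerate(s_grid):
        sp = Species(name=f"s{i}", s=float(s), ff0=ff0, vbar=vbar, c0=1.0)
        sol = solve_lamm(sp, solvent, protocol, times, n_radial=n_radial,
                         dt_max=dt_max)
        cols[:, i] = sol.interp(radii).ravel()
    return LammKernel(s_grid=np.asarray(s_grid, float), radii=radii,
                      times=times, matrix=cols, ff0=ff0, vbar=vbar,
                      meniscus=protocol.meniscus_cm, bottom=protocol.bottom_cm)


# ---------------------------------------------------------------------------
# linear solve machinery
# ---------------------------------------------------------------------------

def _project_noise(y2d: np.ndarray, fit_ti: bool, fit_ri: bool) -> np.ndarray:
    """Project a (scans x radii) matrix orthogonal to the TI/RI subspace.

    TI spans all per-radius constants, RI all per-scan constants; on a
    complete grid the orthogonal projection is double centering.
    """
    out = y2d
    if fit_ti and fit_ri:
        out = out - out.mean(axis=0, keepdims=True) \
                  - out.mean(axis=1, keepdims=True) + out.mean()
    elif fit_ti:
        out = out - out.mean(axis=0, keepdims=True)
    elif fit_ri:
        out = out - out.mean(axis=1, keepdims=True)
    return out


def _second_difference(n: int) -> np.ndarray:
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i:i + 3] = (1.0, -2.0, 1.0)
    return L


def _chi2(a: np.ndarray, G: np.ndarray, b: np.ndarray, yty: float) -> float:
    return float(yty - 2.0 * a @ b + a @ G @ a)


def _maxent_solve(G, b, yty, alpha, prior):
    """Minimize chi2(a) + 2*alpha*sum(a ln(a/m) - a + m) over a >= 0."""
    n = G.shape[0]
    m = prior

    def fun(a):
        a = np.maximum(a, 1e-300)
        pen = np.sum(a * np.log(a / m) - a + m)
        grad = G @ a - b + alpha * np.log(a / m)
        return 0.5 * _chi2(a, G, b, yty) + alpha * pen, grad

    a0 = np.full(n, m)
    res = optimize.minimize(fun, a0, jac=True, method="L-BFGS-B",
                            bounds=[(1e-14, None)] * n,
                            options={"maxiter": 500, "ftol": 1e-12})
    return np.maximum(res.x, 0.0)


def select_regularization(chi2_of_alpha, chi2_0: float, confidence: float,
                          n_data: int, *, alpha0: float = 1e-6,
                          max_iter: int = 50, rtol: float = 1e-3):
    """Largest penalty weight whose chi2 stays within the F-statistic bound.

    The bound is chi2_0 * F^{-1}(confidence; n, n) with n the number of data
    points (the one-sigma convention of the c(s) method: lower confidence
    admits more chi-square inflation, hence stronger smoothing).  Bisection
    on log(alpha) to ``rtol`` relative tolerance within ``max_iter`` steps.

    Returns (alpha, bound).
    """
    ratio = stats.f.ppf(confidence, n_data, n_data)
    bound = chi2_0 * ratio
    if chi2_of_alpha(alpha0) > bound:
        return 0.0, bound
    lo = alpha0
    hi = alpha0
    for _ in range(60):
        hi *= 10.0
        if chi2_of_alpha(hi) > bound:
            break
    else:
        return hi, bound  # even huge smoothing stays within the bound
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        if chi2_of_alpha(mid) <= bound:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0 + rtol:
            break
    return lo, bound


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class CsDistribution:
    """Fitted c(s) distribution and its systematic-noise estimates.

    ``amplitudes`` holds nonnegative loadings per s-grid point in rescaled
    signal units (data are rescaled below ``rescale_max`` before fitting;
    ``scale_factor`` restores the original units).
    """

    s_grid: np.ndarray
    amplitudes: np.ndarray
    ti_noise: np.ndarray
    ri_noise: np.ndarray
    meniscus: float
    ff0: float
    vbar: float
    rmsd: float
    rmsd_unregularized: float
    alpha: float
    chi2_bound: float
    scale_factor: float
    n_data: int
    config: FitConfig
    radii: np.ndarray | None = None
    times: np.ndarray | None = None

    def density(self) -> np.ndarray:
        """c(s) as a density (signal per Svedberg) on the s grid."""
        ds = np.gradient(self.s_grid)
        return self.amplitudes / ds

    def total_loading(self) -> float:
        return float(self.amplitudes.sum())

    def peaks(self, threshold: float = 0.05) -> list[dict]:
        """Contiguous regions above threshold * max, with weighted-mean s.

        This is the species-assignment rule used throughout the package:
        support regions on the s grid, weighted-mean s, and loading share.
        """
        a = self.amplitudes
        if a.max() <= 0:
            return []
        mask = a >= threshold * a.max()
        peaks = []
        i = 0
        n = a.size
        while i < n:
            if not mask[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            w = a[i:j + 1]
            s_mean = float((w * self.s_grid[i:j + 1]).sum() / w.sum())
            peaks.append({
                "s": s_mean,
                "loading": float(w.sum()),
                "fraction": float(w.sum() / a.sum()),
                "support": (i, j),
            })
            i = j + 1
        return peaks

    def summary(self) -> str:
        lines = [
            "c(s) distribution fit",
            "=" * 54,
            f"  s grid           : {self.s_grid.size} points, "
            f"{self.s_grid[0]:.3g}-{self.s_grid[-1]:.3g} S (log-spaced)",
            f"  regularization   : {self.config.regularization}, "
            f"alpha = {self.alpha:.3g} "
            f"(confidence {self.config.confidence:g})",
            f"  rmsd             : {self.rmsd:.5g} (unregularized "
            f"{self.rmsd_unregularized:.5g}, rescaled units)",
            f"  meniscus         : {self.meniscus:.4f} cm",
            f"  ff0 / vbar       : {self.ff0:.3f} / {self.vbar:.4f}",
            f"  signal rescaling : x {self.scale_factor:.4g}",
            f"  data points      : {self.n_data}",
            "  peaks (>=5% of max):",
        ]
        for p in self.peaks():
            lines.append(f"    s = {p['s']:7.3f} S   fraction = "
                         f"{p['fraction']:6.1%}")
        if not self.peaks():
            lines.append("    (none)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class CsModel:
    """c(s) model for one wavelength slice of a velocity run.

    Parameters
    ----------
    y : (n_scans, n_radii) signal matrix (offset-subtracted counts).
    radii : radii (cm) of the columns of y.
    times : scan times (s) of the rows of y.
    protocol : rotor/cell geometry (meniscus, bottom, speed).
    solvent : density/viscosity/temperature for the kernel.
    config : fit settings; defaults follow standard practice (150 log-spaced
        s values, confidence 0.683, TI+RI noise fitted).
    kernel : optionally a prebuilt :class:`LammKernel` (shared across
        wavelengths); it must match radii/times after windowing.
    """

    def __init__(self, y, radii, times, protocol: RotorProtocol,
                 solvent: SolventModel | None = None,
                 config: FitConfig | None = None,
                 kernel: LammKernel | None = None):
        self.config = config or FitConfig()
        self.solvent = solvent or SolventModel(density=1.0)
        self.protocol = protocol
        y = np.asarray(y, dtype=float)
        radii = np.asarray(radii, dtype=float)
        times = np.asarray(times, dtype=float)
        if y.shape != (times.size, radii.size):
            raise ValueError("y must be (n_scans, n_radii)")
        lo = self.config.window_lo_cm
        hi = self.config.window_hi_cm
        if lo is None:
            lo = protocol.meniscus_cm + 0.005
        if hi is None:
            hi = protocol.bottom_cm - 0.010  # exclude back-diffusion spike
        keep = (radii >= lo) & (radii <= hi)
        if keep.sum() < 5:
            raise ValueError("analysis window leaves fewer than 5 radii")
        self.y = y[:, keep]
        self.radii = radii[keep]
        self.times = times
        self._kernel = kernel

    # -- kernel ------------------------------------------------------------
    def kernel(self, ff0=None, vbar=None, meniscus=None) -> LammKernel:
        cfg = self.config
        ff0 = cfg.ff0 if ff0 is None else ff0
        vbar = cfg.vbar if vbar is None else vbar
        if (self._kernel is not None and meniscus is None
                and self._kernel.ff0 == ff0 and self._kernel.vbar == vbar):
            return self._kernel
        protocol = self.protocol
        if meniscus is not None:
            protocol = replace(protocol, meniscus_cm=meniscus)
        k = build_lamm_kernel(cfg.s_grid(), ff0, vbar, self.solvent, protocol,
                              self.radii, self.times,
                              n_radial=cfg.kernel_n_radial,
                              dt_max=cfg.kernel_dt_max)
        if meniscus is None:
            self._kernel = k
        return k

    # -- fitting -----------------------------------------------------------
    def fit(self, *, alpha: float | None = None,
            kernel: LammKernel | None = None) -> CsDistribution:
        """Solve the regularized nonnegative inversion.

        With ``alpha=None`` the penalty is chosen by the F-ratio criterion;
        ``alpha=0`` gives the unregularized maximum-likelihood fit.
        """
        cfg = self.config
        kern = kernel or self.kernel()
        K = kern.matrix
        nt, nr = self.y.shape
        n_data = nt * nr

        ymax = np.abs(self.y).max()
        scale = ymax / cfg.rescale_max if ymax > cfg.rescale_max else 1.0
        y = self.y / scale

        yhat = _project_noise(y, cfg.fit_ti, cfg.fit_ri)
        K3 = K.reshape(nt, nr, -1)
        Khat = np.empty_like(K3)
        for i in range(K3.shape[2]):
            Khat[:, :, i] = _project_noise(K3[:, :, i], cfg.fit_ti, cfg.fit_ri)
        Khat2 = Khat.reshape(n_data, -1)
        yvec = yhat.ravel()
        yty = float(yvec @ yvec)

        if yty == 0.0:
            a = np.zeros(cfg.n_s)
            return self._package(a, kern, 0.0, 0.0, scale, 0.0, 0.0)

        # economy QR of the projected design: the triangular factor is
        # shared across penalty weights (and across wavelengths through the
        # cached kernel) and avoids squaring the condition number
        from scipy.linalg import qr

        Q, R = qr(Khat2, mode="economic")
        z = Q.T @ yvec

        L = _second_difference(cfg.n_s)
        G = R.T @ R
        b = R.T @ z
        prior = max(b.max() / max(np.diag(G).max(), 1e-300), 1e-8) / cfg.n_s

        def solve_at(al):
            if cfg.regularization == "maximum_entropy" and al > 0:
                return _maxent_solve(G, b, yty, al, prior)
            if al > 0:
                A = np.vstack([R, np.sqrt(al) * L])
                rhs = np.concatenate([z, np.zeros(L.shape[0])])
            else:
                A, rhs = R, z
            a, _ = optimize.nnls(A, rhs)
            return a

        a0 = solve_at(0.0)
        chi2_0 = _chi2(a0, G, b, yty)

        if alpha is None:
            alpha, bound = select_regularization(
                lambda al: _chi2(solve_at(al), G, b, yty),
                chi2_0, cfg.confidence, n_data)
        else:
            bound = np.nan
        a = solve_at(alpha) if alpha > 0 else a0
        chi2_a = _chi2(a, G, b, yty)
        return self._package(a, kern, alpha, bound, scale,
                             np.sqrt(max(chi2_a, 0.0) / n_data),
                             np.sqrt(max(chi2_0, 0.0) / n_data))

    def _package(self, a, kern, alpha, bound, scale, rmsd, rmsd0):
        cfg = self.config
        nt, nr = self.y.shape
        resid = self.y / scale - (kern.matrix @ a).reshape(nt, nr)
        ti = np.zeros(nr)
        ri = np.zeros(nt)
        if cfg.fit_ti and cfg.fit_ri:
            ti = resid.mean(axis=0)
            ti = ti - ti.mean()          # zero-mean TI convention
            ri = (resid - ti[None, :]).mean(axis=1)
        elif cfg.fit_ti:
            ti = resid.mean(axis=0)
        elif cfg.fit_ri:
            ri = resid.mean(axis=1)
        return CsDistribution(
            s_grid=kern.s_grid, amplitudes=a, ti_noise=ti * scale,
            ri_noise=ri * scale, meniscus=kern.meniscus, ff0=kern.ff0,
            vbar=kern.vbar, rmsd=rmsd, rmsd_unregularized=rmsd0, alpha=alpha,
            chi2_bound=bound, scale_factor=scale, n_data=nt * nr, config=cfg,
            radii=self.radii, times=self.times)

    # -- nonlinear refinement ----------------------------------------------
    def fit_float(self, parameter: Literal["meniscus", "ff0", "vbar"],
                  bounds: tuple[float, float], *, start: float | None = None,
                  coarse_n_s: int = 60, xtol: float = 1e-4):
        """Optimize one nonlinear parameter by bounded scalar minimization.

        The inner problem (unregularized c(s)) is re-solved at every trial
        value on a coarsened s grid, then the full fit is repeated at the
        optimum.  Returns (best value, CsDistribution).  A warning is issued
        when the optimum sits at an interval boundary.
        """
        lo, hi = bounds
        if not lo < hi:
            raise ValueError("bounds must satisfy lo < hi")
        coarse_cfg = replace(self.config, n_s=min(coarse_n_s, self.config.n_s))
        coarse = CsModel(self.y, self.radii, self.times, self.protocol,
                         self.solvent, coarse_cfg)
        # CsModel windows again; self.y/self.radii are already windowed, so
        # widen the coarse window to keep them intact
        coarse.y, coarse.radii = self.y, self.radii

        def rmsd_of(val):
            kw = {parameter if parameter != "meniscus" else "meniscus": val}
            kern = coarse.kernel(**kw)
            return coarse.fit(alpha=0.0, kernel=kern).rmsd

        res = optimize.minimize_scalar(
            rmsd_of, bounds=(lo, hi), method="bounded",
            options={"xatol": xtol * (hi - lo)})
        best = float(res.x)
        if min(best - lo, hi - best) < 2 * xtol * (hi - lo):
            warnings.warn(
                f"optimum for {parameter} ({best:.5g}) sits at the search "
                "interval boundary", stacklevel=2)
        kw = {parameter if parameter != "meniscus" else "meniscus": best}
        kern = self.kernel(**kw)
        dist = self.fit(kernel=kern)
        return best, dist


# ---------------------------------------------------------------------------
# spec-surface wrappers
# ---------------------------------------------------------------------------

def fit_cs(y, radii, times, protocol, solvent=None, config=None,
           kernel=None, alpha=None) -> CsDistribution:
    """Functional wrapper: build a :class:`CsModel` and fit it."""
    return CsModel(y, radii, times, protocol, solvent, config,
                   kernel=kernel).fit(alpha=alpha)


def optimize_nonlinear(y, radii, times, protocol, parameter, bounds,
                       solvent=None, config=None, **kw):
    """Functional wrapper for :meth:`CsModel.fit_float`."""
    return CsModel(y, radii, times, protocol, solvent, config).fit_float(
        parameter, bounds, **kw)
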