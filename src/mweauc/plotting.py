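"""Figure-style plots: z-scans, SNR curves, c(s) overlays, s-lambda heatmaps."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_zscan", "plot_snr_curve", "plot_cs", "plot_c2d"]


def plot_zscan(zscans, labels=None, ax=None, normalize=True):
    """Overlay one or more z-scans (optionally normalized to their maxima)."""
    if ax is None:
        _, ax = plt.subplots()
    if not isinstance(zscans, (list, tuple)):
        zscans = [zscans]
    for i, zs in enumerate(zscans):
        y = zs.counts.astype(float).sum(axis=1)
        if normalize and y.max() > 0:
            y = y / y.max()
        label = labels[i] if labels else None
        ax.plot(zs.z_mm, y, label=label)
    ax.set_xlabel("z position (mm)")
    ax.set_ylabel("signal (norm.)" if normalize else "counts")
    if labels:
        ax.legend()
    return ax


def plot_snr_curve(curve, ax=None):
    """SNR vs amplitude on log-log axes with slope-1 and slope-1/2 guides."""
    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(curve.amplitude_counts, curve.snr, "o", ms=4)
    a = np.geomspace(curve.amplitude_counts.min(),
                     curve.amplitude_counts.max(), 50)
    ref = curve.snr[np.argmin(np.abs(curve.amplitude_counts
                                     - np.median(curve.amplitude_counts)))]
    mid = np.median(curve.amplitude_counts)
    ax.loglog(a, ref * a / mid, "--", lw=0.8, label="slope 1")
    ax.loglog(a, ref * np.sqrt(a / mid), "--", lw=0.8, label="slope 0.5")
    ax.set_xlabel("signal amplitude (counts)")
    ax.set_ylabel("SNR")
    ax.legend()
    return ax


def plot_cs(distributions, labels=None, ax=None):
    """Overlay c(s) distributions (density per Svedberg)."""
    if ax is None:
        _, ax = plt.subplots()
    if not isinstance(distributions, (list, tuple)):
        distributions = [distributions]
    for i, d in enumerate(distributions):
        ax.plot(d.s_grid, d.density(),
                label=labels[i] if labels else None)
    ax.set_xlabel("sedimentation coefficient (S)")
    ax.set_ylabel("c(s) (signal / S)")
    if labels:
        ax.legend()
    return ax


def plot_c2d(c2d, ax=None, cmap="viridis"):
    """Heatmap of the sedimentation-coefficient x wavelength distribution."""
    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(c2d.wavelength_nm, c2d.s_grid, c2d.amplitudes,
                         cmap=cmap, shading="auto")
    ax.set_xlabel("emission wavelength (nm)")
    ax.set_ylabel("sedimentation coefficient (S)")
    plt.colorbar(mesh, ax=ax, label="amplitude")
    return ax
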