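"""Log-log diagnostic plots for the microrheology chain.

Conventions follow the field's standard figures: MSD vs lag time,
G'/G'' vs ω with solid lines for measured points and dashed for
fit-extrapolated ones, and η(ω) with the detected low-frequency
plateau shaded.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .containers import MaxwellFit, ModuliCurves, MSDCurve, ViscositySpectrum


def plot_msd(curve: MSDCurve, path: str | Path, smoothed: Optional[MSDCurve] = None) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.loglog(curve.lags, curve.msd, "o", ms=3, alpha=0.6, label="ensemble MSD")
    if smoothed is not None:
        ax.loglog(smoothed.lags, smoothed.msd, "-", lw=1.5, label="smoothed")
    ax.set_xlabel("lag time τ (s)")
    ax.set_ylabel("⟨Δr²(τ)⟩ (µm²)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_moduli(moduli: ModuliCurves, path: str | Path, fit: Optional[MaxwellFit] = None) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    m = moduli.measured
    ax.loglog(moduli.omega[m], moduli.Gp[m], "-", color="C0", label="G′ measured")
    ax.loglog(moduli.omega[m], moduli.Gpp[m], "-", color="C1", label="G″ measured")
    if (~m).any():
        ax.loglog(moduli.omega[~m], moduli.Gp[~m], "--", color="C0", alpha=0.6, label="G′ extrapolated")
        ax.loglog(moduli.omega[~m], moduli.Gpp[~m], "--", color="C1", alpha=0.6, label="G″ extrapolated")
    if fit is not None:
        ax.axvline(fit.omega_c, color="grey", ls="--", lw=1, label="ω_c")
    ax.set_xlabel("ω (rad/s)")
    ax.set_ylabel("G′, G″ (Pa)")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_viscosity(spectrum: ViscositySpectrum, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    pos = spectrum.eta > 0
    ax.loglog(spectrum.omega[pos], spectrum.eta[pos], "-", color="C2", label="η = G″/ω")
    if spectrum.plateau_range is not None:
        ax.axvspan(*spectrum.plateau_range, color="C2", alpha=0.15, label="plateau")
    if spectrum.eta0 is not None:
        ax.axhline(spectrum.eta0, color="grey", ls=":", lw=1, label=f"η₀ = {spectrum.eta0:.2g} Pa·s")
    ax.set_xlabel("ω (rad/s)")
    ax.set_ylabel("η (Pa·s)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
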