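"""Viscoelastic medium models and their closed-form passive microrheology.

A tracer bead of radius *a* embedded in a medium at temperature *T*
explores the medium's creep compliance J(t): the generalized
Stokes–Einstein relation (GSER) links the three-dimensional mean squared
displacement to J by

    ⟨Δr²(t)⟩₃D = (kT / (π a)) · J(t),

so in-plane (2D) tracking observes (2/3) of that.  Two media are
modelled:

* **Newtonian** fluid of viscosity η: J(t) = t/η, giving pure diffusion
  with D = kT/(6πηa) and MSD₂D = 4Dt.
* **Maxwell** fluid with zero-shear viscosity η₀ and relaxation time τ
  (plateau modulus G₀ = η₀/τ): J(t) = 1/G₀ + t/η₀, an elastic offset
  plus terminal flow.  Its moduli are

      G'(ω)  = G₀ ω²τ² / (1 + ω²τ²),
      G''(ω) = G₀ ωτ   / (1 + ω²τ²),

  which cross at ω_c = 1/τ where both equal G₀/2; the terminal
  relaxation time is 1/ω_c and η(ω) = G''/ω plateaus at η₀ as ω → 0.

These closed forms serve as the generative oracle the stochastic
simulator and the GSER inversion are validated against.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .containers import ModuliCurves, MSDCurve

#: Boltzmann constant, J/K.
K_B = 1.380649e-23

#: Default temperature: samples equilibrated at 30 °C before imaging.
DEFAULT_TEMPERATURE_K = 303.15

#: Default tracer radius: 100 nm diameter fluorescent beads.
DEFAULT_BEAD_RADIUS_M = 50e-9


@dataclass(frozen=True)
class MediumModel:
    """A homogeneous viscoelastic medium seen by a spherical tracer.

    Use the :meth:`newtonian` / :meth:`maxwell` constructors; ``eta`` is
    only meaningful for the Newtonian kind, ``eta0``/``tau`` only for
    Maxwell.
    """

    kind: str
    eta: Optional[float] = None        # Pa·s, newtonian
    eta0: Optional[float] = None       # Pa·s, maxwell zero-shear viscosity
    tau: Optional[float] = None        # s, maxwell relaxation time
    temperature: float = DEFAULT_TEMPERATURE_K
    bead_radius: float = DEFAULT_BEAD_RADIUS_M

    def __post_init__(self) -> None:
        if self.kind not in ("newtonian", "maxwell"):
            raise ValueError(f"unknown medium kind {self.kind!r}")
        if self.temperature <= 0 or self.bead_radius <= 0:
            raise ValueError("temperature and bead_radius must be positive")
        if self.kind == "newtonian":
            if self.eta is None or self.eta <= 0:
                raise ValueError("newtonian medium requires eta > 0")
        else:
            if self.eta0 is None or self.eta0 <= 0:
                raise ValueError("maxwell medium requires eta0 > 0")
            if self.tau is None or self.tau <= 0:
                raise ValueError("maxwell medium requires tau > 0")
            if not np.isfinite(self.G0) or self.G0 <= 0:
                raise ValueError("implied G0 = eta0/tau must be finite and positive")

    @classmethod
    def newtonian(
        cls,
        eta: float,
        temperature: float = DEFAULT_TEMPERATURE_K,
        bead_radius: float = DEFAULT_BEAD_RADIUS_M,
    ) -> "MediumModel":
        return cls(kind="newtonian", eta=eta, temperature=temperature, bead_radius=bead_radius)

    @classmethod
    def maxwell(
        cls,
        eta0: float,
        tau: float,
        temperature: float = DEFAULT_TEMPERATURE_K,
        bead_radius: float = DEFAULT_BEAD_RADIUS_M,
    ) -> "MediumModel":
        return cls(kind="maxwell", eta0=eta0, tau=tau, temperature=temperature, bead_radius=bead_radius)

    @property
    def kT(self) -> float:
        return K_B * self.temperature

    @property
    def G0(self) -> float:
        """Plateau modulus η₀/τ (maxwell only)."""
        if self.kind != "maxwell":
            raise AttributeError("G0 is defined for maxwell media only")
        return self.eta0 / self.tau

    @property
    def diffusivity(self) -> float:
        """Long-time Stokes–Einstein diffusivity D = kT/(6πηa), m²/s.

        For the Maxwell medium the terminal flow viscosity η₀ applies.
        """
        eta = self.eta if self.kind == "newtonian" else self.eta0
        return self.kT / (6.0 * np.pi * eta * self.bead_radius)

    def creep_compliance(self, t: np.ndarray) -> np.ndarray:
        """J(t) in 1/Pa."""
        t = np.asarray(t, dtype=float)
        if self.kind == "newtonian":
            return t / self.eta
        return 1.0 / self.G0 + t / self.eta0


def analytic_msd(model: MediumModel, lags: Sequence[float]) -> MSDCurve:
    """Exact 2D ensemble MSD (µm²) at the given lag times (s).

    MSD₂D(t) = (2/3)·(kT/(πa))·J(t); a zero lag maps to zero
    displacement.  Lags must be non-negative and sorted ascending.
    """
    lags = np.asarray(lags, dtype=float)
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    if np.any(np.diff(lags) <= 0):
        raise ValueError("lags must be strictly increasing")
    prefactor = (2.0 / 3.0) * model.kT / (np.pi * model.bead_radius)  # m²·Pa units
    msd_m2 = prefactor * model.creep_compliance(lags)
    msd_m2 = np.where(lags == 0.0, 0.0, msd_m2)
    return MSDCurve(
        lags=lags,
        msd=msd_m2 * 1e12,  # m² → µm²
        n_obs=np.full(lags.shape, np.inf),
        dim=2,
        bead_radius_m=model.bead_radius,
        temperature_K=model.temperature,
    )


def analytic_moduli(model: MediumModel, omegas: Sequence[float]) -> ModuliCurves:
    """Exact G'(ω), G''(ω) for the medium at angular frequencies ω (rad/s)."""
    omegas = np.asarray(omegas, dtype=float)
    if np.any(omegas <= 0):
        raise ValueError("omegas must be positive")
    if np.any(np.diff(omegas) <= 0):
        raise ValueError("omegas must be strictly increasing")
    if model.kind == "newtonian":
        Gp = np.zeros_like(omegas)
        Gpp = model.eta * omegas
        alpha = np.ones_like(omegas)
        omega_c = None
    else:
        wt = omegas * model.tau
        denom = 1.0 + wt**2
        Gp = model.G0 * wt**2 / denom
        Gpp = model.G0 * wt / denom
        # MSD log-slope of the Maxwell creep MSD at t = 1/ω: t/(t+τ).
        alpha = 1.0 / (1.0 + wt)
        omega_c = 1.0 / model.tau
    return ModuliCurves(omega=omegas, Gp=Gp, Gpp=Gpp, alpha=alpha, omega_c=omega_c)
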