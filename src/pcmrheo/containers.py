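"""In-memory containers shared across the pipeline stages.

Conventions
-----------
Lengths at the interface are micrometres (µm), times are seconds, moduli
are pascals; SI units are used internally where thermal energy enters
(bead radius in metres, temperature in kelvin).  Trajectory tables follow
the column schema ``trajectory_id, frame, t_s, x_um, y_um`` and travel
with an acquisition-metadata sidecar (frame interval, pixel size, bead
radius, temperature, seed).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = ["trajectory_id", "frame", "t_s", "x_um", "y_um"]


@dataclass
class TrajectorySet:
    """Time-stamped 2D bead positions plus acquisition metadata.

    ``data`` holds one row per (trajectory, frame) with positions in µm;
    ``dt`` is the frame interval in seconds, ``bead_radius_m`` the tracer
    radius in metres and ``temperature_K`` the temperature assumed for
    thermal energy kT downstream.
    """

    data: pd.DataFrame
    dt: float
    bead_radius_m: float = 50e-9
    temperature_K: float = 303.15
    pixel_size_um: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_trajectories(self) -> int:
        return self.data["trajectory_id"].nunique()

    def lengths(self) -> pd.Series:
        return self.data.groupby("trajectory_id").size()

    def to_padded_array(self) -> np.ndarray:
        """(n_traj, n_frames, 2) array of positions in µm, NaN where absent."""
        frames = self.data["frame"].to_numpy()
        f0, f1 = int(frames.min()), int(frames.max())
        ids, idx = np.unique(self.data["trajectory_id"].to_numpy(), return_inverse=True)
        arr = np.full((len(ids), f1 - f0 + 1, 2), np.nan)
        arr[idx, frames - f0, 0] = self.data["x_um"].to_numpy()
        arr[idx, frames - f0, 1] = self.data["y_um"].to_numpy()
        return arr

    def metadata(self) -> dict:
        return {
            "dt": self.dt,
            "pixel_size": self.pixel_size_um,
            "bead_radius_m": self.bead_radius_m,
            "temperature_K": self.temperature_K,
            "seed": self.seed,
        }

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.metadata(), indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, **overrides) -> "TrajectorySet":
        path = Path(path)
        data = pd.read_csv(path)
        missing = [c for c in TRAJECTORY_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(
                f"trajectory CSV {path.name} missing required columns: {missing}"
            )
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        kwargs = dict(
            dt=meta.get("dt", 1.0),
            bead_radius_m=meta.get("bead_radius_m", 50e-9),
            temperature_K=meta.get("temperature_K", 303.15),
            pixel_size_um=meta.get("pixel_size"),
            seed=meta.get("seed"),
        )
        kwargs.update(overrides)
        return cls(data=data, **kwargs)


@dataclass
class MSDCurve:
    """Ensemble mean squared displacement vs lag time.

    ``msd`` is in µm² at dimensionality ``dim`` (2 for in-plane tracking);
    ``n_obs`` counts displacement pairs entering each lag and ``n_eff``
    approximates the number of statistically independent pairs.
    """

    lags: np.ndarray          # s, strictly increasing
    msd: np.ndarray           # µm²
    n_obs: np.ndarray
    dim: int = 2
    n_eff: Optional[np.ndarray] = None
    bead_radius_m: float = 50e-9
    temperature_K: float = 303.15
    dt: Optional[float] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_obs = np.asarray(self.n_obs)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("MSD must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "msd_um2": self.msd, "n_obs": self.n_obs})


@dataclass
class ModuliCurves:
    """Storage/loss moduli G'(ω), G''(ω) with the local MSD log-slope α."""

    omega: np.ndarray         # rad/s, strictly increasing
    Gp: np.ndarray            # Pa, elastic
    Gpp: np.ndarray           # Pa, viscous
    alpha: np.ndarray         # local log-slope of MSD at t = 1/ω, in [0, 1]
    measured: np.ndarray = None  # bool per point: measured vs extrapolated
    omega_c: Optional[float] = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.Gp = np.asarray(self.Gp, dtype=float)
        self.Gpp = np.asarray(self.Gpp, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.measured is None:
            self.measured = np.ones_like(self.omega, dtype=bool)
        else:
            self.measured = np.asarray(self.measured, dtype=bool)
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "omega_rad_s": self.omega,
                "Gp_Pa": self.Gp,
                "Gpp_Pa": self.Gpp,
                "alpha": self.alpha,
                "measured": self.measured,
            }
        )


@dataclass
class ViscositySpectrum:
    """Frequency-dependent viscosity η(ω) = G''(ω)/ω with plateau metadata."""

    omega: np.ndarray
    eta: np.ndarray           # Pa·s
    plateau_range: Optional[Tuple[float, float]] = None
    eta0: Optional[float] = None
    eta0_from_fit: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"omega_rad_s": self.omega, "eta_Pa_s": self.eta})


@dataclass
class MaxwellFit:
    """Single-relaxation-time Maxwell fluid fit: G0 (plateau modulus), τ."""

    G0: float                 # Pa
    tau: float                # s
    residual: float = np.nan  # RMS of log-space residuals
    ok: bool = True           # False when the Maxwell form is a poor model

    def __post_init__(self) -> None:
        if self.G0 <= 0 or self.tau <= 0:
            raise ValueError("G0 and tau must be positive")

    @property
    def eta0_fit(self) -> float:
        return self.G0 * self.tau

    @property
    def omega_c(self) -> float:
        return 1.0 / self.tau

    def to_dict(self) -> dict:
        return {
            "G0_Pa": self.G0,
            "tau_s": self.tau,
            "eta0_Pa_s": self.eta0_fit,
            "omega_c_rad_s": self.omega_c,
            "residual": self.residual,
            "ok": self.ok,
        }


@dataclass
class IntensityTrace:
    """Fluorescence intensity vs time for FRAP / dilution / persistence assays."""

    t: np.ndarray             # s, strictly increasing
    value: np.ndarray
    role: str = "normalized"  # bleached | reference | background | normalized

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have the same shape")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "value": self.value})

    @classmethod
    def from_csv(cls, path: str | Path, role: str = "normalized") -> "IntensityTrace":
        df = pd.read_csv(path)
        if "t_s" not in df.columns or "value" not in df.columns:
            raise ValueError(f"trace CSV {Path(path).name} needs columns t_s,value")
        return cls(t=df["t_s"].to_numpy(), value=df["value"].to_numpy(), role=role)


@dataclass
class ImageStack:
    """Frame × row × col intensity stack with acquisition metadata.

    ``truth`` optionally carries the generator's ground-truth positions
    (per frame, in px) for synthetic stacks.
    """

    pixels: np.ndarray
    dt: float
    pixel_size_um: float
    truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be 2D (single frame) or 3D (stack)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        arr = np.clip(self.pixels, 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, arr)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps({"dt": self.dt, "pixel_size": self.pixel_size_um}, indent=2)
        )

    @classmethod
    def from_tiff(cls, path: str | Path, dt: float = None, pixel_size_um: float = None) -> "ImageStack":
        import tifffile

        path = Path(path)
        pixels = tifffile.imread(path).astype(float)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            pixels=pixels,
            dt=dt if dt is not None else meta.get("dt", 1.0),
            pixel_size_um=pixel_size_um
            if pixel_size_um is not None
            else meta.get("pixel_size", 1.0),
        )


@dataclass
class LineScanProfile:
    """Intensity profile along a 5 µm line scan across a centrosome."""

    position_um: np.ndarray
    intensity: np.ndarray
    t: float = 0.0
    landmark_max_um: float = 1.82
    landmark_min_um: float = 2.60

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        lo, hi = self.position_um.min(), self.position_um.max()
        for lm in (self.landmark_max_um, self.landmark_min_um):
            if not (lo <= lm <= hi):
                raise ValueError("landmark position outside profile support")
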