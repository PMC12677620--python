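"""Synthetic data generation: bead trajectories, rendered videos,
condensate fields, FRAP recovery traces and persistence traces.

The trajectory generator is built so that its sampled statistics match
:func:`pcmrheo.media.analytic_msd` exactly (not just asymptotically):

* Newtonian medium — a plain random walk with independent Gaussian
  increments of per-axis variance 2·D·dt.
* Maxwell medium — the Maxwell creep compliance J(t) = 1/G₀ + t/η₀
  makes the MSD an offset plus a linear ramp.  That is realized as free
  diffusion at D = kT/(6πη₀a) plus an i.i.d. per-frame Gaussian "cage"
  displacement of per-axis variance kT/(6πaG₀); for every lag ≥ dt the
  sampled MSD is then exactly 4Dt + (2/3)·kT/(πaG₀).

This avoids a generalized-Langevin integrator entirely; the price is
that sub-frame dynamics are not modelled, which is irrelevant because
no observable exists below one frame interval.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import ImageStack, IntensityTrace, TrajectorySet
from .media import MediumModel


@dataclass(frozen=True)
class SimConfig:
    """Acquisition-matched simulation settings.

    Defaults mirror the video particle tracking acquisition: 15 ms/frame
    stream acquisition with at least 10 000 frames per movie.
    """

    n_beads: int = 300
    n_frames: int = 10_000
    dt: float = 0.015          # s
    seed: int = 0
    droplet_radius_um: Optional[float] = None   # reflecting confinement, off by default

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class RenderConfig:
    """Camera/optics model for rendering synthetic fluorescence images."""

    pixel_size_um: float = 0.1
    psf_sigma_px: float = 1.3
    peak_signal: float = 2000.0    # photons at a bead centre
    background: float = 100.0      # photons per pixel
    read_noise_sd: float = 3.0     # counts
    image_shape: tuple = (64, 64)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.psf_sigma_px <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")
        if self.peak_signal < 0:
            raise ValueError("peak_signal must be non-negative")


def _cage_sd_um(model: MediumModel) -> float:
    """Per-axis cage jitter SD (µm) reproducing the Maxwell MSD offset."""
    var_m2 = model.kT / (6.0 * np.pi * model.bead_radius * model.G0)
    return np.sqrt(var_m2) * 1e6


def simulate_trajectories(
    model: MediumModel,
    sim: SimConfig,
    initial_positions_um: Optional[np.ndarray] = None,
    elastic_only: bool = False,
) -> TrajectorySet:
    """Draw thermal 2D bead trajectories in the given medium.

    Parameters
    ----------
    initial_positions_um
        Optional (n_beads, 2) start positions; defaults to the origin
        (or uniform inside the droplet when confinement is on).
    elastic_only
        Test hook for the η₀ → ∞ limit of a Maxwell medium: suppresses
        the diffusive component so the MSD is flat at the cage offset.
    """
    rng = np.random.default_rng(sim.seed)
    n, m = sim.n_beads, sim.n_frames

    D_um2_s = model.diffusivity * 1e12
    if elastic_only:
        if model.kind != "maxwell":
            raise ValueError("elastic_only applies to maxwell media")
        D_um2_s = 0.0
    step_sd = np.sqrt(2.0 * D_um2_s * sim.dt)   # per-axis, µm

    if sim.droplet_radius_um is not None:
        if sim.droplet_radius_um <= 2.0 * step_sd:
            raise ValueError(
                "droplet_radius smaller than the expected per-frame step; "
                "confinement would dominate every displacement"
            )

    if initial_positions_um is None:
        if sim.droplet_radius_um is not None:
            # uniform in the disk
            r = sim.droplet_radius_um * np.sqrt(rng.uniform(size=n))
            th = rng.uniform(0, 2 * np.pi, size=n)
            start = np.column_stack([r * np.cos(th), r * np.sin(th)])
        else:
            start = np.zeros((n, 2))
    else:
        start = np.asarray(initial_positions_um, dtype=float)
        if start.shape != (n, 2):
            raise ValueError("initial_positions_um must have shape (n_beads, 2)")

    steps = rng.normal(scale=step_sd, size=(n, m - 1, 2)) if step_sd > 0 else np.zeros((n, m - 1, 2))
    walk = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    pos = start[:, None, :] + walk

    if model.kind == "maxwell":
        pos = pos + rng.normal(scale=_cage_sd_um(model), size=(n, m, 2))

    if sim.droplet_radius_um is not None:
        pos = _reflect_into_disk(pos, sim.droplet_radius_um)

    frames = np.tile(np.arange(m), n)
    ids = np.repeat(np.arange(n), m)
    data = pd.DataFrame(
        {
            "trajectory_id": ids,
            "frame": frames,
            "t_s": frames * sim.dt,
            "x_um": pos[:, :, 0].ravel(),
            "y_um": pos[:, :, 1].ravel(),
        }
    )
    return TrajectorySet(
        data=data,
        dt=sim.dt,
        bead_radius_m=model.bead_radius,
        temperature_K=model.temperature,
        seed=sim.seed,
    )


def _reflect_into_disk(pos: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect positions outside the disk back across the rim."""
    r = np.sqrt(pos[..., 0] ** 2 + pos[..., 1] ** 2)
    outside = r > radius
    if np.any(outside):
        scale = np.where(outside, (2.0 * radius - r) / np.maximum(r, 1e-300), 1.0)
        # clamp pathological double-crossings to the rim
        scale = np.clip(scale, 0.0, None)
        pos = pos * scale[..., None]
    return pos


def render_video(
    traj: TrajectorySet,
    render: RenderConfig,
    seed: int = 0,
    offset_um: tuple = (0.0, 0.0),
) -> ImageStack:
    """Render a trajectory set as a noisy fluorescence video.

    Beads become 2D Gaussian spots of width ``psf_sigma_px`` and peak
    amplitude ``peak_signal`` on a uniform ``background``; Poisson
    photon noise and Gaussian read noise are applied per pixel.  The
    ground-truth pixel positions are retained on the returned stack.
    ``offset_um`` shifts all positions (trajectories are often centred
    on the origin) before the µm→px conversion.
    """
    rng = np.random.default_rng(seed)
    h, w = render.image_shape
    px = render.pixel_size_um

    frames = np.sort(traj.data["frame"].unique())
    x_px = (traj.data["x_um"].to_numpy() + offset_um[0]) / px
    y_px = (traj.data["y_um"].to_numpy() + offset_um[1]) / px
    if np.any(x_px < 0) or np.any(x_px > w - 1) or np.any(y_px < 0) or np.any(y_px > h - 1):
        raise ValueError("trajectory positions fall outside the image bounds")

    truth = traj.data.copy()
    truth["x_px"] = x_px
    truth["y_px"] = y_px

    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    sig2 = 2.0 * render.psf_sigma_px**2
    stack = np.empty((len(frames), h, w))
    by_frame = truth.groupby("frame")
    for i, f in enumerate(frames):
        sub = by_frame.get_group(f)
        field = np.full((h, w), float(render.background))
        for xc, yc in zip(sub["x_px"].to_numpy(), sub["y_px"].to_numpy()):
            field += render.peak_signal * np.exp(-((xx - xc) ** 2 + (yy - yc) ** 2) / sig2)
        noisy = rng.poisson(field).astype(float)
        if render.read_noise_sd > 0:
            noisy += rng.normal(scale=render.read_noise_sd, size=(h, w))
        stack[i] = noisy

    return ImageStack(pixels=stack, dt=traj.dt, pixel_size_um=px, truth=truth)


def simulate_frap_trace(
    mobile_fraction: float,
    k: float,
    noise_sd: float,
    t_grid: Sequence[float],
    seed: int = 0,
) -> IntensityTrace:
    """One-phase FRAP recovery: I(t) = mobile_fraction·(1 − e^(−kt)) + noise.

    ``t_grid`` defaults in callers to the in-vivo sampling scheme (every
    20 s until 140 s); here it is explicit.
    """
    if not (0.0 <= mobile_fraction <= 1.0):
        raise ValueError("mobile_fraction must lie in [0, 1]")
    if k <= 0:
        raise ValueError("k must be positive")
    t = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    value = mobile_fraction * (1.0 - np.exp(-k * t))
    if noise_sd > 0:
        value = value + rng.normal(scale=noise_sd, size=t.shape)
    return IntensityTrace(t=t, value=value, role="normalized")


def frap_time_grid(interval_s: float = 20.0, t_end_s: float = 140.0) -> np.ndarray:
    """Post-bleach sampling grid: every ``interval_s`` until ``t_end_s``."""
    return np.arange(0.0, t_end_s + 0.5 * interval_s, interval_s)


def simulate_persistence_trace(
    stable_fraction: float,
    tau_decay: float,
    noise_sd: float,
    t_grid: Sequence[float],
    seed: int = 0,
) -> IntensityTrace:
    """Biphasic persistence: I(t) = s + (1−s)·e^(−t/τ_decay) + noise.

    Emulates extruded-centrosome integrated density that declines
    rapidly then plateaus at the stable fraction ``s``.
    """
    if not (0.0 <= stable_fraction <= 1.0):
        raise ValueError("stable_fraction must lie in [0, 1]")
    if tau_decay <= 0:
        raise ValueError("tau_decay must be positive")
    t = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    value = stable_fraction + (1.0 - stable_fraction) * np.exp(-t / tau_decay)
    if noise_sd > 0:
        value = value + rng.normal(scale=noise_sd, size=t.shape)
    return IntensityTrace(t=t, value=value, role="normalized")


def persistence_time_grid(interval_s: float = 120.0, t_end_s: float = 3600.0) -> np.ndarray:
    """Extrusion imaging grid: every 2 min for 1 h by default."""
    return np.arange(0.0, t_end_s + 0.5 * interval_s, interval_s)


def simulate_condensate_field(
    n: int,
    radii_px: Sequence[float] | float = 8.0,
    intensities: Sequence[float] | float = 500.0,
    render: RenderConfig = RenderConfig(image_shape=(256, 256)),
    seed: int = 0,
    centers_px: Optional[np.ndarray] = None,
    touching_pairs: int = 0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a field of disk-shaped condensates with ground truth.

    Disks get soft (PSF-blurred) edges over a noisy background.  Returns
    the single-frame stack and a ground-truth table with one row per
    object: centre, radius, true pixel area (counted on the noiseless
    mask), injected total intensity above background, and a ``chain_id``
    grouping deliberately touching pairs (for watershed tests).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = render.image_shape
    radii = np.broadcast_to(np.asarray(radii_px, dtype=float), (n,)).copy()
    amps = np.broadcast_to(np.asarray(intensities, dtype=float), (n,)).copy()

    chain_id = np.full(n, -1)
    if centers_px is None:
        centers = np.zeros((n, 2))  # (x, y)
        placed = 0
        k = 0
        while placed < n and k < 10_000:
            k += 1
            r = radii[placed]
            if chain_id_needed := (placed < 2 * touching_pairs and placed % 2 == 1):
                # place touching its predecessor
                prev = centers[placed - 1]
                th = rng.uniform(0, 2 * np.pi)
                cand = prev + (radii[placed - 1] + r) * np.array([np.cos(th), np.sin(th)])
            else:
                cand = rng.uniform([r + 4, r + 4], [w - r - 4, h - r - 4])
            if not (r + 1 <= cand[0] <= w - r - 1 and r + 1 <= cand[1] <= h - r - 1):
                continue
            # keep non-chained objects disjoint
            ok = True
            for j in range(placed):
                sep = np.linalg.norm(cand - centers[j])
                min_sep = radii[j] + r + (0 if chain_id_needed and j == placed - 1 else 6)
                if sep < min_sep:
                    ok = False
                    break
            if ok:
                centers[placed] = cand
                if chain_id_needed:
                    chain_id[placed - 1] = chain_id[placed] = placed // 2
                placed += 1
        if placed < n:
            raise RuntimeError("could not place all condensates without overlap")
    else:
        centers = np.asarray(centers_px, dtype=float)

    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    field = np.zeros((h, w))
    rows = []
    for i in range(n):
        xc, yc = centers[i]
        mask = (xx - xc) ** 2 + (yy - yc) ** 2 <= radii[i] ** 2
        field += amps[i] * mask
        rows.append(
            {
                "object_id": i,
                "x_px": xc,
                "y_px": yc,
                "radius_px": radii[i],
                "true_area_px": int(mask.sum()),
                "total_intensity": amps[i] * mask.sum(),
                "chain_id": int(chain_id[i]),
            }
        )
    field = gaussian_filter(field, render.psf_sigma_px) + render.background
    noisy = rng.poisson(np.clip(field, 0, None)).astype(float)
    if render.read_noise_sd > 0:
        noisy += rng.normal(scale=render.read_noise_sd, size=(h, w))

    truth = pd.DataFrame(
        rows,
        columns=[
            "object_id", "x_px", "y_px", "radius_px",
            "true_area_px", "total_intensity", "chain_id",
        ],
    )
    stack = ImageStack(pixels=noisy[None], dt=1.0, pixel_size_um=render.pixel_size_um)
    return stack, truth
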