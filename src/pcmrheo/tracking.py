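"""Sub-pixel bead detection and trajectory linking.

Implements the classic video particle tracking chain: spatial bandpass
(suppress pixel noise and slow background), local-maximum candidate
detection, iterative intensity-weighted centroid refinement to
sub-pixel precision, and frame-to-frame linking by globally optimal
assignment (Hungarian algorithm) with a finite search radius and a
short "memory" for bridging missed detections.

Coordinate convention: pixel centres sit at integer coordinates,
origin at the top-left pixel, ``x`` = column, ``y`` = row.  Feature
tables are in pixels; trajectory output converts to µm.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter, uniform_filter
from scipy.optimize import linear_sum_assignment

from .containers import ImageStack, TrajectorySet

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ["frame", "x", "y", "mass", "size", "ecc"]

#: Default tracking parameters for rendered fixtures.
DEFAULT_DIAMETER = 7
DEFAULT_MAX_DISP = 5.0
DEFAULT_MEMORY = 3
DEFAULT_MIN_LENGTH = 100


def bandpass(image: np.ndarray, noise_scale: float, feature_scale: int) -> np.ndarray:
    """Suppress pixel noise and large-scale background.

    Gaussian blur at ``noise_scale`` (px) minus a boxcar background
    over ``feature_scale`` (px); negative values are clipped so the
    result is non-negative.
    """
    image = np.asarray(image, dtype=float)
    if not (0 < noise_scale < feature_scale):
        raise ValueError("require 0 < noise_scale < feature_scale")
    if feature_scale >= min(image.shape):
        raise ValueError("feature_scale must be smaller than the image")
    smoothed = gaussian_filter(image, noise_scale)
    background = uniform_filter(image, int(feature_scale))
    return np.clip(smoothed - background, 0.0, None)


def _refine_centroid(
    image: np.ndarray, y0: int, x0: int, radius: int, max_iter: int = 10
) -> Optional[Tuple[float, float, float, float, float]]:
    """Iterative intensity-weighted centroid within a circular mask.

    Returns (x, y, mass, size, ecc) or None if the window leaves the
    image.  The window re-centres whenever the centroid shifts by more
    than half a pixel, up to ``max_iter`` iterations.
    """
    h, w = image.shape
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    mask = (yy**2 + xx**2) <= radius**2
    cy, cx = y0, x0
    for _ in range(max_iter):
        if not (radius <= cy < h - radius and radius <= cx < w - radius):
            return None
        win = image[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1]
        win = np.where(mask, win, 0.0)
        mass = win.sum()
        if mass <= 0:
            return None
        dy = (win * yy).sum() / mass
        dx = (win * xx).sum() / mass
        if abs(dy) <= 0.5 and abs(dx) <= 0.5:
            rg2 = (win * (yy**2 + xx**2)).sum() / mass
            m20 = (win * (xx - dx) ** 2).sum() / mass
            m02 = (win * (yy - dy) ** 2).sum() / mass
            m11 = (win * (xx - dx) * (yy - dy)).sum() / mass
            denom = m20 + m02
            ecc = np.sqrt((m20 - m02) ** 2 + 4 * m11**2) / denom if denom > 0 else 0.0
            return cx + dx, cy + dy, mass, np.sqrt(rg2), ecc
        cy += int(round(dy))
        cx += int(round(dx))
    # did not settle within the iteration cap; report the last window
    return cx + dx, cy + dy, mass, np.sqrt((win * (yy**2 + xx**2)).sum() / mass), 0.0


def locate_features(
    image: np.ndarray,
    diameter: int = DEFAULT_DIAMETER,
    min_mass: float = 0.0,
    percentile_threshold: float = 99.0,
    frame: int = 0,
) -> pd.DataFrame:
    """Find bright spots and refine them to sub-pixel centroids.

    ``diameter`` (odd, ≥ 3) sets both the local-maximum footprint and
    the refinement window.  Candidates must exceed the given intensity
    percentile of the image; detections with summed intensity below
    ``min_mass`` are discarded.  Returns an (possibly empty) table with
    columns frame, x, y, mass, size, ecc.
    """
    image = np.asarray(image, dtype=float)
    if diameter < 3 or diameter % 2 == 0:
        raise ValueError("diameter must be odd and >= 3")
    radius = diameter // 2
    threshold = np.percentile(image, percentile_threshold)
    footprint = np.ones((diameter, diameter), dtype=bool)
    is_max = (image == maximum_filter(image, footprint=footprint)) & (image > threshold)
    # exclude the margin where the refinement window would not fit
    is_max[:radius, :] = is_max[-radius:, :] = False
    is_max[:, :radius] = is_max[:, -radius:] = False

    rows = []
    for y0, x0 in zip(*np.nonzero(is_max)):
        ref = _refine_centroid(image, int(y0), int(x0), radius)
        if ref is None:
            continue
        x, y, mass, size, ecc = ref
        if mass >= min_mass:
            rows.append((frame, x, y, mass, size, ecc))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def locate_stack(
    stack: ImageStack,
    diameter: int = DEFAULT_DIAMETER,
    min_mass: float = 0.0,
    percentile_threshold: float = 99.0,
    noise_scale: float = 1.0,
    feature_scale: Optional[int] = None,
    do_bandpass: bool = True,
) -> pd.DataFrame:
    """Bandpass + locate every frame of a stack into one feature table."""
    if feature_scale is None:
        feature_scale = 2 * diameter - 1
    tables = []
    for i in range(stack.n_frames):
        img = stack.pixels[i]
        if do_bandpass:
            img = bandpass(img, noise_scale, feature_scale)
        tables.append(
            locate_features(
                img,
                diameter=diameter,
                min_mass=min_mass,
                percentile_threshold=percentile_threshold,
                frame=i,
            )
        )
    return pd.concat(tables, ignore_index=True)


def link_features(
    features: pd.DataFrame,
    max_disp: float = DEFAULT_MAX_DISP,
    memory: int = DEFAULT_MEMORY,
    dt: float = 1.0,
    pixel_size_um: float = 1.0,
    bead_radius_m: float = 50e-9,
    temperature_K: float = 303.15,
) -> TrajectorySet:
    """Link detections into trajectories by optimal assignment.

    Frame by frame, candidate links within ``max_disp`` px are resolved
    by minimizing total squared displacement (Hungarian algorithm with
    birth/death costs at max_disp²); each detection joins at most one
    trajectory.  A track missing a detection stays eligible for up to
    ``memory`` frames before being retired.  Positions convert to µm
    via ``pixel_size_um`` and times via ``dt``.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if memory < 0:
        raise ValueError("memory must be >= 0")
    required = {"frame", "x", "y"}
    if not required <= set(features.columns):
        raise ValueError(f"feature table needs columns {sorted(required)}")

    BIG = 1e12
    death_cost = max_disp**2
    next_id = 0
    # active tracks: id -> (last_frame, x, y)
    active: dict[int, tuple[int, float, float]] = {}
    assignments = np.full(len(features), -1, dtype=np.int64)
    features = features.sort_values(["frame", "x"], kind="stable").reset_index(drop=True)

    for frame, sub in features.groupby("frame", sort=True):
        frame = int(frame)
        # retire stale tracks
        active = {tid: s for tid, s in active.items() if frame - s[0] <= memory + 1}
        det_idx = sub.index.to_numpy()
        dx = sub["x"].to_numpy()
        dy = sub["y"].to_numpy()
        tids = list(active.keys())
        if tids:
            tx = np.array([active[t][1] for t in tids])
            ty = np.array([active[t][2] for t in tids])
            d2 = (tx[:, None] - dx[None, :]) ** 2 + (ty[:, None] - dy[None, :]) ** 2
            cost = np.where(d2 <= max_disp**2, d2, BIG)
            n_t, n_d = len(tids), len(det_idx)
            # square matrix with death (track unmatched) and birth rows
            M = np.full((n_t + n_d, n_d + n_t), death_cost)
            M[:n_t, :n_d] = cost
            M[n_t:, n_d:] = 0.0  # dummy corner
            rows, cols = linear_sum_assignment(M)
            for r, c in zip(rows, cols):
                if r < n_t and c < n_d and M[r, c] < BIG:
                    tid = tids[r]
                    assignments[det_idx[c]] = tid
                    active[tid] = (frame, dx[c], dy[c])
        for j, i_det in enumerate(det_idx):
            if assignments[i_det] < 0:
                assignments[i_det] = next_id
                active[next_id] = (frame, dx[j], dy[j])
                next_id += 1

    out = pd.DataFrame(
        {
            "trajectory_id": assignments,
            "frame": features["frame"].to_numpy().astype(int),
            "t_s": features["frame"].to_numpy() * dt,
            "x_um": features["x"].to_numpy() * pixel_size_um,
            "y_um": features["y"].to_numpy() * pixel_size_um,
        }
    ).sort_values(["trajectory_id", "frame"], ignore_index=True)
    return TrajectorySet(
        data=out,
        dt=dt,
        pixel_size_um=pixel_size_um,
        bead_radius_m=bead_radius_m,
        temperature_K=temperature_K,
    )


def filter_trajectories(
    traj: TrajectorySet,
    min_length: int = DEFAULT_MIN_LENGTH,
    center_mask: Optional[Tuple[float, float, float]] = None,
) -> TrajectorySet:
    """Drop short trajectories and, optionally, off-centre beads.

    ``min_length`` is the minimum number of recorded frames (≥ 2).
    ``center_mask`` is a disk ``(cx_um, cy_um, radius_um)``; only
    trajectories whose *mean* position lies inside it are kept — the
    analysis convention of keeping beads near the condensate centre to
    minimize confinement effects (a half-radius disk about the
    condensate centroid is the usual choice).
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    lengths = traj.data.groupby("trajectory_id").size()
    keep = set(lengths[lengths >= min_length].index)
    if center_mask is not None:
        cx, cy, r = center_mask
        means = traj.data.groupby("trajectory_id")[["x_um", "y_um"]].mean()
        inside = (means["x_um"] - cx) ** 2 + (means["y_um"] - cy) ** 2 <= r**2
        keep &= set(means[inside].index)
    data = traj.data[traj.data["trajectory_id"].isin(keep)].reset_index(drop=True)
    if data.empty:
        log.warning("filter_trajectories removed every trajectory")
    return TrajectorySet(
        data=data,
        dt=traj.dt,
        pixel_size_um=traj.pixel_size_um,
        bead_radius_m=traj.bead_radius_m,
        temperature_K=traj.temperature_K,
        seed=traj.seed,
    )


def static_msd_offset(traj: TrajectorySet, n_lags: int = 10) -> float:
    """Localization-noise MSD floor (µm²) from stationary-bead fixtures.

    For immobilized beads the apparent MSD is the constant 4σ_loc²;
    this returns the mean MSD over the first ``n_lags`` frame lags.
    """
    from .rheology import ensemble_msd  # local import avoids a cycle

    lags = np.arange(1, n_lags + 1) * traj.dt
    curve = ensemble_msd(traj, lag_grid=lags)
    return float(curve.msd.mean())
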