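"""Looming-object trajectory geometry and stimulus rendering.

An object of physical diameter ``d`` approaching the observer along a
straight line subtends a visual angle ``2·atan(d / 2D)`` at distance
``D``, and its remaining time-to-collision at constant approach speed
``v`` is ``D / v``.  This module generates full 3D trajectories (world
coordinates relative to the cyclopean eye), projects them to angular
screen coordinates, aligns projections across trajectory conditions by
their image center of mass, renders anti-aliased grayscale frame
sequences, and builds balanced randomized trial schedules.

Conventions: +x is rightward, +y is upward; upper visual-field
quadrants have positive angular elevation.  All angles are in degrees.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySpec",
    "ProjectedPath",
    "TrialSchedule",
    "FrameSequence",
    "angular_diameter",
    "time_to_collision",
    "offset_components",
    "project_trajectory",
    "align_by_centroid",
    "render_frames",
    "make_trial_schedule",
]

Quadrant = Literal["UL", "UR", "LL", "LR"]
Direction = Literal["approach", "recede"]

#: sign of (x, y) for each visual-field quadrant
_QUADRANT_SIGNS: dict[str, tuple[int, int]] = {
    "UL": (-1, 1),
    "UR": (1, 1),
    "LL": (-1, -1),
    "LR": (1, -1),
}


@dataclass(frozen=True)
class TrajectorySpec:
    """Full 3D geometry of one looming or receding trial.

    Distances are measured along the viewing axis from the cyclopean
    eye; lateral/vertical offsets are unsigned magnitudes whose signs
    are taken from ``quadrant`` (impact offsets keep the horizontal
    sign of the quadrant).
    """

    start_distance: float  # m
    end_distance: float  # m
    speed: float  # m/s
    start_lateral_offset: float = 0.0  # m
    start_vertical_offset: float = 0.0  # m
    impact_lateral_offset: float = 0.0  # m, would-be impact point
    sphere_diameter: float = 0.06  # m
    viewing_distance: float = 1.3  # m, eye to screen
    quadrant: Quadrant = "UR"
    direction: Direction = "approach"

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be positive")
        if self.viewing_distance <= 0:
            raise ValueError("viewing_distance must be positive")
        far, near = self.start_distance, self.end_distance
        if self.direction == "recede":
            far, near = near, far
        if not (far > near >= 0):
            raise ValueError(
                "approach requires start_distance > end_distance >= 0 "
                "(reversed for recede)"
            )


@dataclass
class ProjectedPath:
    """Angular screen coordinates of a trajectory, frame by frame."""

    frame_times: np.ndarray  # s
    angular_x: np.ndarray  # deg, signed horizontal visual angle
    angular_y: np.ndarray  # deg
    angular_size: np.ndarray  # deg, full angular diameter
    centroid_shift: tuple[float, float] = (0.0, 0.0)  # deg, applied shift
    quadrant: Quadrant | None = None

    def __post_init__(self) -> None:
        n = len(self.frame_times)
        if not (len(self.angular_x) == len(self.angular_y) == len(self.angular_size) == n):
            raise ValueError("per-frame arrays must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def centroid(self) -> tuple[float, float]:
        """Center of mass of the projected image sequence, in degrees.

        Each frame contributes its disc center weighted by the disc's
        image mass (area, proportional to angular size squared), so
        later, larger frames dominate — the center of mass of the
        space-time luminance volume for a uniform disc.
        """
        w = self.angular_size**2
        if w.sum() == 0:
            w = np.ones_like(w)
        return (
            float(np.average(self.angular_x, weights=w)),
            float(np.average(self.angular_y, weights=w)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_time": self.frame_times,
                "ang_x_deg": self.angular_x,
                "ang_y_deg": self.angular_y,
                "ang_size_deg": self.angular_size,
            }
        )


@dataclass
class TrialSchedule:
    """Balanced randomized trial table with onsets and ISIs."""

    table: pd.DataFrame  # run, trial_index, <factors...>, onset_time, isi
    factors: Mapping[str, Sequence]
    seed: int

    def counts_per_cell(self) -> pd.Series:
        return self.table.groupby(list(self.factors), observed=True).size()


@dataclass
class FrameSequence:
    """Grayscale raster stack of rendered stimulus frames."""

    frames: np.ndarray  # (n_frames, ny, nx), values in [0, 1]
    pixel_pitch: float  # degrees per pixel
    frame_rate: float  # Hz
    background_level: float = 0.5

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) stack")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


def angular_diameter(sphere_diameter, distance):
    """Full angular diameter in degrees of a sphere seen at ``distance``.

    ``2·atan((d/2)/D)`` — the small-angle linear approximation is not
    used.  Accepts scalars or arrays; both arguments must be positive.
    """
    d = np.asarray(sphere_diameter, dtype=float)
    dist = np.asarray(distance, dtype=float)
    if np.any(d <= 0) or np.any(dist <= 0):
        raise ValueError("sphere_diameter and distance must be positive")
    out = np.degrees(2.0 * np.arctan((d / 2.0) / dist))
    return float(out) if out.ndim == 0 else out


def time_to_collision(distance, speed):
    """Remaining time-to-collision in integer milliseconds.

    ``1000·D/v`` rounded half away from zero (matching how printed
    stimulus timings are quoted).
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if np.any(np.asarray(distance) < 0):
        raise ValueError("distance must be non-negative")
    ms = 1000.0 * np.asarray(distance, dtype=float) / speed
    rounded = np.floor(ms + 0.5).astype(int)
    return int(rounded) if rounded.ndim == 0 else rounded


def offset_components(eccentricity_deg: float, polar_angle_deg: float) -> tuple[float, float]:
    """Decompose an eccentricity into (horizontal, vertical) screen offsets.

    ``polar_angle_deg`` is measured from the vertical meridian, so a
    3.8° eccentricity at 60° polar angle sits 1.90° above (or below)
    the horizontal through fixation.
    """
    pa = math.radians(polar_angle_deg)
    return (
        eccentricity_deg * math.sin(pa),
        eccentricity_deg * math.cos(pa),
    )


def project_trajectory(spec: TrajectorySpec, n_frames: int = 20) -> ProjectedPath:
    """Project a 3D trajectory to angular screen coordinates.

    The object moves at constant speed along the straight segment from
    its start point to the would-be impact point (at distance 0);
    frames sample the visible portion between ``start_distance`` and
    ``end_distance`` uniformly in time.  Angular coordinates are
    ``atan(offset / distance)`` relative to the cyclopean eye; angular
    size uses the instantaneous viewing-axis distance.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    sx, sy = _QUADRANT_SIGNS[spec.quadrant]
    d0, d1 = spec.start_distance, spec.end_distance
    if spec.direction == "recede":
        d0, d1 = d1, d0
    p_start = np.array(
        [sx * spec.start_lateral_offset, sy * spec.start_vertical_offset, d0]
    )
    p_impact = np.array([sx * spec.impact_lateral_offset, 0.0, 0.0])
    # fraction of the full start->impact segment covered when z reaches d1
    if d0 <= 0:
        raise ValueError("trajectory start must be in front of the observer")
    s_end = 1.0 - d1 / d0
    full_len = float(np.linalg.norm(p_impact - p_start))
    duration = s_end * full_len / spec.speed
    s = np.linspace(0.0, s_end, n_frames)
    pos = p_start[None, :] + s[:, None] * (p_impact - p_start)[None, :]
    x, y, z = pos.T
    if np.any(z[:-1] <= 0):
        raise ValueError("trajectory passes through the observer before the final frame")
    if np.any(z <= 0):
        raise ValueError("trajectory reaches distance 0; angular size is undefined")
    times = np.linspace(0.0, duration, n_frames)
    if spec.direction == "recede":
        x, y, z = x[::-1].copy(), y[::-1].copy(), z[::-1].copy()
    return ProjectedPath(
        frame_times=times,
        angular_x=np.degrees(np.arctan2(x, z)),
        angular_y=np.degrees(np.arctan2(y, z)),
        angular_size=angular_diameter(spec.sphere_diameter, z),
        quadrant=spec.quadrant,
    )


def align_by_centroid(
    paths: Sequence[ProjectedPath],
    target: tuple[float, float] | None = None,
) -> list[ProjectedPath]:
    """Rigidly shift paths so their image centroids coincide.

    Each path is translated in angular coordinates so that its
    mass-weighted image centroid equals ``target`` — by default the
    across-condition mean centroid, or an explicit screen location
    (e.g. the designed stimulus eccentricity).  The applied shift is
    recorded in ``centroid_shift``.  Idempotent.
    """
    if len(paths) == 0:
        raise ValueError("need at least one path to align")
    quadrants = {p.quadrant for p in paths}
    if len(quadrants) > 1:
        raise ValueError("paths must come from the same quadrant")
    centroids = np.array([p.centroid() for p in paths])
    if target is None:
        target = centroids.mean(axis=0)
    target = np.asarray(target, dtype=float)
    out = []
    for p, c in zip(paths, centroids):
        dx, dy = target - c
        out.append(
            replace(
                p,
                angular_x=p.angular_x + dx,
                angular_y=p.angular_y + dy,
                centroid_shift=(
                    p.centroid_shift[0] + float(dx),
                    p.centroid_shift[1] + float(dy),
                ),
            )
        )
    return out


def render_frames(
    path: ProjectedPath,
    resolution: int = 256,
    field_of_view: float = 12.0,
    texture: Literal["solid", "checkerboard"] = "solid",
    polarity: Literal["bright_on_dark", "dark_on_bright"] = "bright_on_dark",
    frame_rate: float = 60.0,
    background_level: float | None = None,
    checker_period_deg: float = 0.25,
    center: tuple[float, float] | None = None,
) -> FrameSequence:
    """Render a projected path as an anti-aliased grayscale disc stack.

    The image spans ``field_of_view`` degrees, centered on the mean
    disc position by default (pass ``center=(0, 0)`` for a
    fixation-centered image, e.g. for eccentricity diagnostics);
    anti-aliasing uses a one-pixel linear coverage ramp at the disc
    edge.  A disc that would leave the field of view is clipped with a
    warning.
    """
    if resolution < 32:
        raise ValueError("resolution must be at least 32 pixels")
    pitch = field_of_view / resolution
    if background_level is None:
        background_level = 0.0 if polarity == "bright_on_dark" else 1.0
    fg = 1.0 - background_level if polarity == "bright_on_dark" else 0.0
    cx0, cy0 = path.centroid() if center is None else center
    half = field_of_view / 2.0
    xs = cx0 - half + (np.arange(resolution) + 0.5) * pitch
    ys = cy0 + half - (np.arange(resolution) + 0.5) * pitch  # +y upward
    gx, gy = np.meshgrid(xs, ys)
    frames = np.full((path.n_frames, resolution, resolution), background_level)
    for k in range(path.n_frames):
        r = path.angular_size[k] / 2.0
        if r <= 0:
            continue
        ax, ay = path.angular_x[k], path.angular_y[k]
        if (
            ax - r < cx0 - half
            or ax + r > cx0 + half
            or ay - r < cy0 - half
            or ay + r > cy0 + half
        ):
            warnings.warn("disc exceeds the field of view; clipping", stacklevel=2)
        dist = np.hypot(gx - ax, gy - ay)
        coverage = np.clip((r - dist) / pitch + 0.5, 0.0, 1.0)
        if texture == "checkerboard":
            checker = (
                (np.floor((gx - ax) / checker_period_deg) + np.floor((gy - ay) / checker_period_deg))
                % 2
            )
            level = np.where(checker > 0, fg, 1.0 - fg)
        else:
            level = fg
        frames[k] = background_level * (1 - coverage) + level * coverage
    return FrameSequence(
        frames=np.clip(frames, 0.0, 1.0),
        pixel_pitch=pitch,
        frame_rate=frame_rate,
        background_level=background_level,
    )


def make_trial_schedule(
    factors: Mapping[str, Sequence],
    runs: int,
    trials_per_run: int,
    isi_choices: Sequence[float],
    seed: int,
    stimulus_duration: float = 0.33,
    start_time: float = 0.0,
) -> TrialSchedule:
    """Build a balanced, seeded-random trial schedule.

    Every factor cell appears equally often within each run
    (``trials_per_run`` must be divisible by the number of cells) and
    ISIs are drawn uniformly from ``isi_choices``.  Same seed, same
    schedule, bit for bit.
    """
    names = list(factors)
    cells = list(itertools.product(*(factors[n] for n in names)))
    if trials_per_run % len(cells) != 0:
        raise ValueError(
            f"trials_per_run={trials_per_run} not divisible by {len(cells)} factor cells"
        )
    reps = trials_per_run // len(cells)
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(1, runs + 1):
        order = np.array(cells * reps, dtype=object)
        rng.shuffle(order, axis=0)
        isis = rng.choice(np.asarray(isi_choices, dtype=float), size=trials_per_run)
        t = start_time
        for idx, (cell, isi) in enumerate(zip(order, isis)):
            rows.append((run, idx, *cell, t, float(isi)))
            t += stimulus_duration + float(isi)
    table = pd.DataFrame(
        rows, columns=["run", "trial_index", *names, "onset_time", "isi"]
    )
    return TrialSchedule(table=table, factors=dict(factors), seed=seed)
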