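"""Canonical stimulus geometries of the three collision-detection experiments.

These constructors encode the published trajectory parameters — a
baseball-sized sphere approaching at 24 m/s from one of the four
visual-field quadrants, with the would-be impact point varied between
hitting and narrowly missing the observer's head:

* Experiment 1 (psychophysics): 11.3 → 3.3 m, 6-cm sphere, impact
  offsets 0 / 3 / 6 / 12 cm, stimulus at 3.8° eccentricity (60° polar
  angle), vanishing at 138 ms time-to-collision.
* Experiment 2 (7T fMRI): 8.75 → 0.75 m, hit-the-eye vs 6-cm near
  miss, ~5° eccentricity, on-screen size 0.4 → 4.5°.
* Experiment 3 (patients): 10.75 → 2.75 m, 5-cm near miss, 6-cm
  sphere at 7T (8.4 cm at 3T), vanishing at 115 ms time-to-collision.

Lateral/vertical world offsets are derived from the designed
eccentricity: a stimulus at eccentricity ``e`` and polar angle 60°
from the vertical meridian sits at horizontal offset ``e·sin 60°`` and
vertical offset ``e·cos 60°`` on the screen.
"""

from __future__ import annotations

import math

import numpy as np

from .optflow import eccentricity_profile, horn_schunck_flow, overall_flow_magnitude
from .stimgeom import (
    FrameSequence,
    TrajectorySpec,
    align_by_centroid,
    offset_components,
    project_trajectory,
    render_frames,
)

__all__ = [
    "exp1_spec",
    "exp2_spec",
    "exp3_spec",
    "exp2_rendered_pair",
    "total_flow_magnitude",
]

SPEED_M_S = 24.0

#: impact-point offsets of experiment 1 (cm from the nasion)
EXP1_IMPACT_OFFSETS_CM = {"hit_nasion": 0.0, "hit_eye": 3.0, "near_miss": 6.0, "far_miss": 12.0}


def _world_offsets(start_distance: float, eccentricity_deg: float,
                   polar_angle_deg: float = 60.0) -> tuple[float, float]:
    """World-space start offsets placing the object at the designed eccentricity."""
    h, v = offset_components(eccentricity_deg, polar_angle_deg)
    return (
        start_distance * math.tan(math.radians(h)),
        start_distance * math.tan(math.radians(v)),
    )


def exp1_spec(impact_offset_cm: float = 0.0, quadrant: str = "UR") -> TrajectorySpec:
    """Experiment-1 behavioral geometry: 11.3 → 3.3 m, 6-cm sphere."""
    lat, vert = _world_offsets(11.3, 3.8)
    return TrajectorySpec(
        start_distance=11.3,
        end_distance=3.3,
        speed=SPEED_M_S,
        start_lateral_offset=lat,
        start_vertical_offset=vert,
        impact_lateral_offset=impact_offset_cm / 100.0,
        sphere_diameter=0.06,
        viewing_distance=1.3,
        quadrant=quadrant,
    )


def exp2_spec(trajectory: str = "hit", quadrant: str = "UR") -> TrajectorySpec:
    """Experiment-2 fMRI geometry: 8.75 → 0.75 m, hit vs 6-cm near miss."""
    impact = {"hit": 0.0, "near_miss": 0.06}[trajectory]
    lat, vert = _world_offsets(8.75, 5.0)
    # sphere sized so the start image is the printed 0.4 deg
    sphere = 2 * 8.75 * math.tan(math.radians(0.4 / 2))
    return TrajectorySpec(
        start_distance=8.75,
        end_distance=0.75,
        speed=SPEED_M_S,
        start_lateral_offset=lat,
        start_vertical_offset=vert,
        impact_lateral_offset=impact,
        sphere_diameter=sphere,
        viewing_distance=0.75,
        quadrant=quadrant,
    )


def exp3_spec(trajectory: str = "hit", scanner: str = "7T", quadrant: str = "UR") -> TrajectorySpec:
    """Experiment-3 patient geometry: 10.75 → 2.75 m, 5-cm near miss."""
    impact = {"hit": 0.0, "near_miss": 0.05}[trajectory]
    ecc = {"7T": 3.99, "3T": 5.58}[scanner]
    sphere = {"7T": 0.06, "3T": 0.084}[scanner]
    lat, vert = _world_offsets(10.75, ecc)
    direction = "approach"
    d0, d1 = 10.75, 2.75
    if trajectory == "receding":
        impact, direction = 0.0, "recede"
        d0, d1 = 2.75, 10.75
    return TrajectorySpec(
        start_distance=d0,
        end_distance=d1,
        speed=SPEED_M_S,
        start_lateral_offset=lat,
        start_vertical_offset=vert,
        impact_lateral_offset=impact,
        sphere_diameter=sphere,
        viewing_distance=1.0,
        quadrant=quadrant,
        direction=direction,
    )


def exp2_rendered_pair(
    n_frames: int = 20,
    resolution: int = 96,
    field_of_view: float = 24.0,
) -> tuple[FrameSequence, FrameSequence]:
    """Centroid-aligned, fixation-centered hit and near-miss frame stacks.

    Paths are aligned to the designed stimulus location (5° eccentricity
    at 60° polar angle) as in the experiment.  The default 0.25°/pixel
    pitch keeps per-frame edge displacements within the small-motion
    regime where Horn–Schunck flow estimates are reliable.
    """
    hit_p = project_trajectory(exp2_spec("hit"), n_frames=n_frames)
    miss_p = project_trajectory(exp2_spec("near_miss"), n_frames=n_frames)
    target = offset_components(5.0, 60.0)
    hit_p, miss_p = align_by_centroid([hit_p, miss_p], target=target)
    kwargs = dict(
        resolution=resolution,
        field_of_view=field_of_view,
        center=(0.0, 0.0),  # fixation-centered, for eccentricity diagnostics
        polarity="dark_on_bright",  # exp-2 object darker than background
    )
    return render_frames(hit_p, **kwargs), render_frames(miss_p, **kwargs)


def total_flow_magnitude(seq: FrameSequence, alpha: float = 1.0,
                         n_iterations: int = 100) -> float:
    """Overall optical-flow magnitude summed over all consecutive frame pairs."""
    return sum(
        overall_flow_magnitude(horn_schunck_flow(a, b, alpha=alpha, n_iterations=n_iterations))
        for a, b in zip(seq.frames[:-1], seq.frames[1:])
    )
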