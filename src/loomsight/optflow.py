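"""Horn–Schunck optical flow and retinotopic stimulus diagnostics.

Dense flow is estimated with the classical Horn–Schunck (1981)
variational method: brightness constancy plus a global smoothness
penalty weighted by ``alpha``, solved by Jacobi iteration with the
original averaging and derivative stencils.  Summary diagnostics — the
overall flow magnitude (sum over pixels of the squared vector modulus)
and time-integrated flow or luminance-change profiles binned by
eccentricity — quantify the low-level retinotopic drive of rendered
looming stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import convolve, correlate

from .stimgeom import FrameSequence

__all__ = [
    "FlowField",
    "EccentricityProfile",
    "horn_schunck_flow",
    "overall_flow_magnitude",
    "eccentricity_profile",
]

# Horn & Schunck neighbourhood average (their eq. 12 weights)
_AVG_KERNEL = np.array(
    [
        [1 / 12, 1 / 6, 1 / 12],
        [1 / 6, 0.0, 1 / 6],
        [1 / 12, 1 / 6, 1 / 12],
    ]
)


@dataclass
class FlowField:
    """Dense optical flow between two frames, in pixels/frame."""

    u: np.ndarray  # horizontal component
    v: np.ndarray  # vertical component
    alpha: float
    n_iterations: int


@dataclass
class EccentricityProfile:
    """Per-ring time-integrated flow magnitude or luminance change."""

    ring_edges: np.ndarray  # deg, len n_rings + 1
    values: np.ndarray  # len n_rings
    metric: Literal["flow", "luminance"]


def _hs_derivatives(a: np.ndarray, b: np.ndarray):
    """Spatio-temporal derivative estimates averaged over the 2x2x2 cube."""
    kx = 0.25 * np.array([[-1.0, 1.0], [-1.0, 1.0]])
    ky = 0.25 * np.array([[-1.0, -1.0], [1.0, 1.0]])
    kt = 0.25 * np.ones((2, 2))
    mode = "nearest"  # boundary replication
    # correlate, not convolve: the stencils are directional
    ex = correlate(a, kx, mode=mode) + correlate(b, kx, mode=mode)
    ey = correlate(a, ky, mode=mode) + correlate(b, ky, mode=mode)
    et = correlate(b, kt, mode=mode) - correlate(a, kt, mode=mode)
    return ex, ey, et


def horn_schunck_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    alpha: float = 1.0,
    n_iterations: int = 100,
) -> FlowField:
    """Estimate dense flow from ``frame_a`` to ``frame_b``.

    Deterministic Jacobi iteration from a zero flow initialisation;
    ``alpha`` is the smoothness weight (larger → smoother fields) and
    boundary pixels are handled by replication.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    ex, ey, et = _hs_derivatives(a, b)
    denom = alpha**2 + ex**2 + ey**2
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    for _ in range(n_iterations):
        u_avg = convolve(u, _AVG_KERNEL, mode="nearest")
        v_avg = convolve(v, _AVG_KERNEL, mode="nearest")
        t = (ex * u_avg + ey * v_avg + et) / denom
        u = u_avg - ex * t
        v = v_avg - ey * t
    return FlowField(u=u, v=v, alpha=alpha, n_iterations=n_iterations)


def overall_flow_magnitude(flow: FlowField) -> float:
    """Sum over pixels of the squared flow-vector modulus, u² + v²."""
    return float(np.sum(flow.u**2 + flow.v**2))


def hs_energy(flow: FlowField, frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Horn–Schunck objective (data + alpha²·smoothness) for a flow field."""
    ex, ey, et = _hs_derivatives(np.asarray(frame_a, float), np.asarray(frame_b, float))
    data = (ex * flow.u + ey * flow.v + et) ** 2
    gu = np.gradient(flow.u)
    gv = np.gradient(flow.v)
    smooth = gu[0] ** 2 + gu[1] ** 2 + gv[0] ** 2 + gv[1] ** 2
    return float(np.sum(data + flow.alpha**2 * smooth))


def _ring_masks(shape: tuple[int, int], pixel_pitch: float, ring_edges: np.ndarray):
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    ecc = np.hypot(xx - (nx - 1) / 2.0, yy - (ny - 1) / 2.0) * pixel_pitch
    if ecc.min() < ring_edges[0] or ecc.max() >= ring_edges[-1]:
        raise ValueError("ring_edges do not cover the image")
    idx = np.searchsorted(ring_edges, ecc, side="right") - 1
    return [idx == k for k in range(len(ring_edges) - 1)]


def eccentricity_profile(
    frames: FrameSequence,
    metric: Literal["flow", "luminance"],
    ring_edges: Sequence[float],
    alpha: float = 1.0,
    n_iterations: int = 100,
) -> EccentricityProfile:
    """Time-integrated flow magnitude or luminance change per eccentricity ring.

    Rings are concentric annuli around the image center (edges in
    degrees, ``np.inf`` allowed as the last edge); the flow metric sums
    the squared flow modulus over all consecutive frame pairs, the
    luminance metric sums ``|pixel − background|`` over all frames.
    """
    edges = np.asarray(ring_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("ring_edges must be a strictly increasing 1D sequence")
    stack = frames.frames
    masks = _ring_masks(stack.shape[1:], frames.pixel_pitch, edges)
    if metric == "flow":
        if stack.shape[0] < 2:
            raise ValueError("flow metric needs at least 2 frames")
        total = np.zeros(stack.shape[1:])
        for a, b in zip(stack[:-1], stack[1:]):
            f = horn_schunck_flow(a, b, alpha=alpha, n_iterations=n_iterations)
            total += f.u**2 + f.v**2
    elif metric == "luminance":
        total = np.abs(stack - frames.background_level).sum(axis=0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    values = np.array([total[m].sum() for m in masks])
    return EccentricityProfile(ring_edges=edges, values=values, metric=metric)
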