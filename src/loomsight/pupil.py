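"""Pupil-trace preprocessing and cluster-length permutation inference.

Raw pupil-diameter traces are cleaned in a fixed order — blink gaps
linearly interpolated, zero-phase low-pass filtering (4th-order
Butterworth, default 40 Hz cutoff), baseline subtraction over a
pre-stimulus window (default −200–0 ms), and SD normalization — and
condition differences over time are tested with a cluster-based
permutation test.  Pointwise paired t tests define candidate clusters
as maximal runs of samples with p below a cluster-forming alpha; the
family-wise-corrected p of each cluster is the proportion of a
permutation null (maximum cluster *length* under within-subject
condition swaps) at least as long as the observed run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "PupilTrace",
    "TimeClusterResult",
    "preprocess_pupil",
    "cluster_time_permutation",
    "windowed_mean",
]


@dataclass
class PupilTrace:
    """Uniformly sampled pupil-diameter trace, time in ms from onset."""

    time: np.ndarray  # ms
    diameter: np.ndarray  # normalized units
    sampling_rate: float  # Hz
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    normalization: Literal["raw", "baseline_subtracted", "sd_normalized"] = "raw"
    valid: bool = True


@dataclass
class TimeClusterResult:
    clusters: list[tuple[float, float, int]]  # (start_ms, end_ms, length_in_samples)
    cluster_p: np.ndarray
    null_lengths: np.ndarray
    n_permutations: int
    seed: int | None
    point_alpha: float
    t_values: np.ndarray

    def significant_clusters(self, alpha: float = 0.05):
        return [
            c for c, p in zip(self.clusters, self.cluster_p) if p < alpha
        ]


def _interpolate_gaps(y: np.ndarray, missing: np.ndarray) -> np.ndarray:
    out = y.astype(float).copy()
    if missing.any():
        good = ~missing
        if not good.any():
            raise ValueError("trace contains no valid samples")
        idx = np.arange(len(y))
        out[missing] = np.interp(idx[missing], idx[good], out[good])
    return out


def preprocess_pupil(
    raw_trace,
    sampling_rate: float,
    lowpass_cutoff: float = 40.0,
    baseline_window: tuple[float, float] = (-200.0, 0.0),
    time: np.ndarray | None = None,
    missing: np.ndarray | None = None,
    sd_window: Literal["whole_trace", "baseline"] = "whole_trace",
) -> PupilTrace:
    """Interpolate → filter → baseline-subtract → SD-normalize, in that order.

    ``missing`` marks blink samples (NaNs in ``raw_trace`` are also
    treated as missing).  A gap spanning the entire baseline window
    flags the trial invalid (``valid=False``) rather than raising.
    The SD used for normalization is the whole-trace SD by default
    (``sd_window="baseline"`` uses the baseline window instead).
    """
    y = np.asarray(raw_trace, dtype=float)
    if sampling_rate <= 2 * lowpass_cutoff:
        raise ValueError("sampling_rate must exceed twice the low-pass cutoff")
    if time is None:
        time = np.arange(len(y)) * 1000.0 / sampling_rate + baseline_window[0]
    time = np.asarray(time, dtype=float)
    miss = np.isnan(y)
    if missing is not None:
        miss = miss | np.asarray(missing, dtype=bool)

    in_baseline = (time >= baseline_window[0]) & (time < baseline_window[1])
    if not in_baseline.any():
        raise ValueError("baseline window contains no samples")
    valid = bool((~miss[in_baseline]).any())

    y = _interpolate_gaps(y, miss)
    sos = signal.butter(4, lowpass_cutoff, btype="low", fs=sampling_rate, output="sos")
    y = signal.sosfiltfilt(sos, y)  # zero phase: no latency shift of clusters
    y = y - y[in_baseline].mean()
    sd_mask = in_baseline if sd_window == "baseline" else np.ones_like(in_baseline)
    sd = y[sd_mask].std(ddof=1)
    if sd > 0:
        y = y / sd
    return PupilTrace(
        time=time,
        diameter=y,
        sampling_rate=sampling_rate,
        baseline_window=baseline_window,
        normalization="sd_normalized",
        valid=valid,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open (start, stop) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _max_run_lengths(masks: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a 2D boolean array."""
    n_rows, n_t = masks.shape
    padded = np.zeros((n_rows, n_t + 2), dtype=np.int8)
    padded[:, 1:-1] = masks
    d = np.diff(padded, axis=1)
    row_s, col_s = np.nonzero(d == 1)
    _, col_e = np.nonzero(d == -1)  # same row order; runs pair up elementwise
    lengths = col_e - col_s
    out = np.zeros(n_rows, dtype=int)
    if len(lengths):
        bounds = np.searchsorted(row_s, np.arange(n_rows))
        has_runs = np.diff(np.append(bounds, len(row_s))) > 0
        out[has_runs] = np.maximum.reduceat(lengths, bounds[has_runs])
    return out


def cluster_time_permutation(
    cond_a_traces,
    cond_b_traces,
    n_permutations: int = 10_000,
    point_alpha: float = 0.05,
    seed: int | None = None,
    time: np.ndarray | None = None,
) -> TimeClusterResult:
    """Cluster-length permutation test between paired trace conditions.

    Inputs are (n_subjects, n_time) arrays of per-subject mean traces,
    paired across conditions.  The null distribution is the maximum
    cluster length under random within-subject condition swaps (sign
    flips of the paired difference); cluster p-values use the add-one
    estimate so they lie in (0, 1].
    """
    a = np.atleast_2d(np.asarray(cond_a_traces, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b_traces, dtype=float))
    if a.shape != b.shape:
        raise ValueError("conditions must have matching (n_subjects, n_time) shapes")
    n_subj, n_time = a.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if time is None:
        time = np.arange(n_time, dtype=float)
    diff = a - b
    t_crit = stats.t.ppf(1 - point_alpha / 2, df=n_subj - 1)

    def t_stats(x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=0)
        s = x.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s > 0, m / (s / np.sqrt(n_subj)), 0.0)

    t_obs = t_stats(diff)
    obs_runs = _runs(np.abs(t_obs) > t_crit)

    rng = np.random.default_rng(seed)
    sumsq = (diff**2).sum(axis=0)
    null = np.empty(n_permutations, dtype=int)
    chunk = max(1, min(n_permutations, int(2e7 / max(n_time, 1))))
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(k, n_subj))
        means = signs @ diff / n_subj
        var = (sumsq[None, :] - n_subj * means**2) / (n_subj - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.where(var > 0, means / np.sqrt(var / n_subj), 0.0)
        null[done : done + k] = _max_run_lengths(np.abs(t_null) > t_crit)
        done += k

    clusters = []
    pvals = []
    for start, stop in obs_runs:
        length = stop - start
        clusters.append((float(time[start]), float(time[stop - 1]), int(length)))
        pvals.append((1 + int(np.sum(null >= length))) / (n_permutations + 1))
    return TimeClusterResult(
        clusters=clusters,
        cluster_p=np.asarray(pvals),
        null_lengths=null,
        n_permutations=n_permutations,
        seed=seed,
        point_alpha=point_alpha,
        t_values=t_obs,
    )


def windowed_mean(trace: PupilTrace | np.ndarray, window_ms: tuple[float, float],
                  time: np.ndarray | None = None) -> float:
    """Mean diameter over a time window (default use: 1,000–1,364 ms)."""
    if isinstance(trace, PupilTrace):
        y, t = trace.diameter, trace.time
    else:
        y = np.asarray(trace, dtype=float)
        if time is None:
            raise ValueError("time axis required for a bare array")
        t = np.asarray(time, dtype=float)
    mask = (t >= window_ms[0]) & (t <= window_ms[1])
    if not mask.any():
        raise ValueError("window contains no samples")
    return float(y[mask].mean())
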