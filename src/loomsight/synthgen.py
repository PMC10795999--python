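"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of (config, seed) and emulates the
statistical structure its downstream analysis assumes:

* behavioral trial tables — Bernoulli hit/miss responses from the
  cumulative-normal psychometric model, per subject and visual field;
* pupil traces — AR(1) noise plus a Gaussian-bump condition effect at
  a configurable latency, with injected blink gaps;
* voxel cohorts — per-subject hit/miss beta maps of spatially smoothed
  Gaussian noise, with an additive spherical "collision-sensitive"
  cluster in the hit maps scaled to a target Cohen's d;
* beta series — draws from a recursive path model x = (I-B)^-1 e with
  e ~ N(0, Psi), so the cross-ROI covariance follows the closed form
  (I-B)^-1 Psi (I-B)^-T;
* BOLD time series — per-trial amplitudes convolved with an HRF plus
  AR(1) noise and linear drift, with the ground truth returned.

Defaults mirror the study scale: 20 subjects, 16 trials per condition
cell, ISIs of 8/10/12 s, TR 2 s, 1.5-mm voxels on a 20x20x20 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .pathnet import BetaSeries, PathModel
from .roistats import HRFModel, _convolved_regressor

__all__ = [
    "CohortConfig",
    "gen_behavior",
    "gen_pupil",
    "gen_voxel_cohort",
    "gen_beta_series",
    "gen_bold",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of a synthetic cohort."""

    n_subjects: int = 20
    # psychometric truth, per visual field (cm)
    psy_mu: Mapping[str, float] = field(
        default_factory=lambda: {"upper": 6.0, "lower": 6.0}
    )
    psy_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"upper": 1.0, "lower": 1.5}
    )
    psy_impact_points_cm: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0)
    psy_trials_per_level: int = 50  # 400 trials = 4 points x 2 fields x 50
    psy_adaptive_placement: bool = True  # near/far miss at ~50% / ~2% hit rate
    psy_subject_sd: float = 0.15  # lognormal jitter of individual sigma
    # pupil effect (hit minus miss constriction)
    pupil_sampling_rate: float = 250.0  # Hz
    pupil_duration_ms: tuple[float, float] = (-500.0, 2500.0)
    pupil_effect_latency_ms: float = 1100.0
    pupil_effect_width_ms: float = 250.0
    pupil_effect_amplitude: float = -0.5  # constriction, in noise-SD units
    pupil_ar1: float = 0.95  # per-sample at 1 kHz
    pupil_blink_rate_hz: float = 0.2
    pupil_blink_duration_ms: float = 100.0
    n_pupil_trials: int = 32
    # voxel cohort truth
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 1.5
    effect_center: tuple[int, int, int] = (10, 10, 10)
    effect_radius_vox: float = 1.4  # about 30 ul at 1.5 mm isotropic
    effect_cohens_d: float = 0.7
    smoothness_fwhm_vox: float = 1.5
    # path-model truth
    trials_per_condition: int = 64
    bold_tr: float = 2.0
    bold_ar1: float = 0.3
    bold_noise_sd: float = 0.5
    isi_choices_s: tuple[float, ...] = (8.0, 10.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be at least 3")
        if any(s <= 0 for s in self.psy_sigma.values()):
            raise ValueError("psychometric sigma must be positive")
        shape = np.asarray(self.grid_shape)
        center = np.asarray(self.effect_center)
        if np.any(center - self.effect_radius_vox < 0) or np.any(
            center + self.effect_radius_vox >= shape
        ):
            raise ValueError("effect cluster must lie inside the grid")


def gen_behavior(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Trial table of Bernoulli hit/miss responses.

    P(hit | x) = 1 - Phi((x - mu)/sigma) at the configured impact
    points, with per-subject lognormal jitter of sigma; columns are
    (subject, visual_field, impact_point_cm, response_hit).  With
    ``psy_adaptive_placement`` the near- and far-miss points are placed
    per subject at roughly 50% and 2% hit rate, as in an adaptive
    preliminary session; the two hit points stay at their physical
    offsets.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(config.n_subjects):
        jitter = float(np.exp(rng.normal(0.0, config.psy_subject_sd)))
        for vf, mu in config.psy_mu.items():
            sigma = config.psy_sigma[vf] * jitter
            if config.psy_adaptive_placement:
                points = (
                    config.psy_impact_points_cm[0],
                    config.psy_impact_points_cm[1],
                    mu,  # ~50% hit response
                    mu + norm.isf(0.02) * sigma,  # ~2% hit response
                )
            else:
                points = config.psy_impact_points_cm
            for x in points:
                p_hit = float(norm.sf((x - mu) / sigma))
                hits = rng.random(config.psy_trials_per_level) < p_hit
                for h in hits:
                    rows.append((f"S{s + 1:02d}", vf, x, int(h)))
    return pd.DataFrame(
        rows, columns=["subject", "visual_field", "impact_point_cm", "response_hit"]
    )


def _ar1_noise(rng, n_samples: int, rho: float, n_series: int = 1) -> np.ndarray:
    e = rng.normal(0.0, 1.0, size=(n_series, n_samples))
    out = np.empty_like(e)
    out[:, 0] = e[:, 0] / np.sqrt(1 - rho**2)
    for t in range(1, n_samples):
        out[:, t] = rho * out[:, t - 1] + e[:, t]
    return out * np.sqrt(1 - rho**2)  # unit marginal variance


def gen_pupil(config: CohortConfig, seed: int):
    """Per-subject mean pupil traces for hit and miss conditions.

    Returns ``(time_ms, hit, miss, missing)`` where hit/miss are
    (n_subjects, n_time) averages over ``n_pupil_trials`` noisy trials;
    the hit condition carries an extra Gaussian constriction bump at
    the configured latency.  ``missing`` flags the blink gaps injected
    into the single-trial data before averaging (already interpolated
    out of the returned means).
    """
    rng = np.random.default_rng(seed)
    fs = config.pupil_sampling_rate
    t0, t1 = config.pupil_duration_ms
    time = np.arange(t0, t1, 1000.0 / fs)
    n_t = len(time)
    # rescale the 1 kHz AR coefficient to this sampling rate
    rho = config.pupil_ar1 ** (1000.0 / fs)
    bump = np.exp(
        -0.5 * ((time - config.pupil_effect_latency_ms) / config.pupil_effect_width_ms) ** 2
    )
    n_subj, n_trials = config.n_subjects, config.n_pupil_trials
    hit = np.empty((n_subj, n_t))
    miss = np.empty((n_subj, n_t))
    missing_any = np.zeros((n_subj, n_t), dtype=bool)
    blink_len = max(1, int(config.pupil_blink_duration_ms * fs / 1000.0))
    p_blink_start = config.pupil_blink_rate_hz / fs
    for s in range(n_subj):
        for cond, store in (("hit", hit), ("miss", miss)):
            trials = _ar1_noise(rng, n_t, rho, n_trials)
            if cond == "hit":
                trials = trials + config.pupil_effect_amplitude * bump
            starts = rng.random((n_trials, n_t)) < p_blink_start
            for k in range(n_trials):
                for st in np.flatnonzero(starts[k]):
                    stop = min(st + blink_len, n_t)
                    trial = trials[k]
                    lo = trial[st - 1] if st > 0 else trial[min(stop, n_t - 1)]
                    hi = trial[stop] if stop < n_t else lo
                    trial[st:stop] = np.linspace(lo, hi, stop - st)
                    missing_any[s, st:stop] = True
            store[s] = trials.mean(axis=0)
    return time, hit, miss, missing_any


def gen_voxel_cohort(config: CohortConfig, seed: int):
    """Per-subject hit/miss beta maps with a localized effect cluster.

    Noise per subject and condition is white Gaussian smoothed to the
    configured FWHM and rescaled to unit voxel variance, so hit - miss
    noise has SD sqrt(2); the hit maps receive an additive effect of
    ``effect_cohens_d * sqrt(2)`` inside the spherical cluster, making
    the across-subject voxelwise d of the difference equal the target.
    Returns ``(hit_maps, miss_maps, mask, cluster_mask)`` with maps of
    shape (n_subjects, *grid_shape).
    """
    rng = np.random.default_rng(seed)
    shape = config.grid_shape
    sigma = config.smoothness_fwhm_vox * _FWHM_TO_SIGMA

    def smooth_noise(n: int) -> np.ndarray:
        # smooth on a padded grid and crop so the field is stationary
        # (no boundary-induced variance gradient), then normalize
        pad = int(np.ceil(3 * sigma)) if sigma > 0 else 0
        padded_shape = tuple(s + 2 * pad for s in shape)
        raw = rng.normal(size=(n, *padded_shape))
        sl = tuple(slice(pad, pad + s) for s in shape)
        out = np.stack([gaussian_filter(v, sigma)[sl] for v in raw])
        return out / out.std(axis=(1, 2, 3), keepdims=True)

    hit = smooth_noise(config.n_subjects)
    miss = smooth_noise(config.n_subjects)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = config.effect_center
    cluster = (
        (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    ) <= config.effect_radius_vox**2
    amplitude = config.effect_cohens_d * np.sqrt(2.0)
    hit[:, cluster] += amplitude
    mask = np.ones(shape, dtype=bool)
    return hit, miss, mask, cluster


def gen_beta_series(
    config: CohortConfig,
    seed: int,
    B: np.ndarray | None = None,
    Psi: np.ndarray | None = None,
    variables: Sequence[str] = ("SC", "vmPul", "VTA", "VC", "AttNet"),
    condition_shift: Mapping[str, float] | None = None,
    model: PathModel | None = None,
) -> BetaSeries:
    """Multi-ROI beta series drawn from a recursive path model.

    Per trial, x = (I - B)^-1 e with e ~ N(0, Psi); ``B[i, j]`` is the
    path from variable j to variable i and must be permutable to
    strictly lower triangular (recursive).  Optional per-condition
    mean shifts emulate amplitude differences between trajectory
    conditions.  If ``model`` is given, its edges define which B
    entries may be nonzero (a consistency check).
    """
    rng = np.random.default_rng(seed)
    p = len(variables)
    if B is None:
        B = np.zeros((p, p))
        B[1, 0] = 0.6  # SC -> vmPul
        B[2, 0] = 0.5  # SC -> VTA
        B[3, 1] = 0.4  # vmPul -> VC
        B[4, 3] = 0.5  # VC -> AttNet
    B = np.asarray(B, dtype=float)
    if Psi is None:
        Psi = np.eye(p)
    Psi = np.asarray(Psi, dtype=float)
    # recursiveness check: nilpotent B (acyclic influence graph)
    power = np.eye(p)
    for _ in range(p):
        power = power @ B
    if not np.allclose(power, 0):
        raise ValueError("B is not recursive (influence graph contains a cycle)")
    if model is not None:
        idx = {v: i for i, v in enumerate(variables)}
        allowed = np.zeros((p, p), dtype=bool)
        for src, tgt in model.edges:
            allowed[idx[tgt], idx[src]] = True
        if np.any((B != 0) & ~allowed):
            raise ValueError("B has paths outside the model's edge set")
    conditions = ["hit", "miss"]
    n_total = config.trials_per_condition * len(conditions)
    e = rng.multivariate_normal(np.zeros(p), Psi, size=n_total)
    x = np.linalg.solve(np.eye(p) - B, e.T).T
    labels = np.repeat(conditions, config.trials_per_condition)
    if condition_shift:
        for cond, shift in condition_shift.items():
            x[labels == cond] += shift
    return BetaSeries(
        betas=pd.DataFrame(x, columns=list(variables)),
        condition=labels,
        subject_id="synthetic",
        z_scored=False,
    )


def gen_bold(
    config: CohortConfig,
    schedule: pd.DataFrame,
    hrf: HRFModel,
    seed: int,
    condition_amplitudes: Mapping[str, float] | None = None,
    amplitude_sd: float = 0.0,
    drift_per_scan: float = 0.0,
):
    """HRF-convolved ROI BOLD series with AR(1) noise and drift.

    ``schedule`` needs columns ``onset_time`` and ``condition``;
    per-trial amplitudes are the condition means plus N(0,
    ``amplitude_sd``) jitter.  Returns ``(timeseries, truth)`` where
    ``truth`` is the per-trial amplitude table.
    """
    rng = np.random.default_rng(seed)
    if condition_amplitudes is None:
        condition_amplitudes = {"hit": 1.0, "miss": 0.8}
    onsets = schedule["onset_time"].to_numpy(dtype=float)
    conds = schedule["condition"].to_numpy()
    amps = np.array([condition_amplitudes[c] for c in conds])
    amps = amps + rng.normal(0.0, amplitude_sd, size=len(amps))
    tr = config.bold_tr
    n_scans = int(np.ceil((onsets.max() + 30.0) / tr))
    # build the signal from the same per-trial regressors the GLM uses,
    # so the noiseless round trip is exact
    signal = np.zeros(n_scans)
    for onset, a in zip(onsets, amps):
        signal += a * _convolved_regressor(
            n_scans, tr, np.array([onset]), np.array([0.33]), hrf
        )
    noise = config.bold_noise_sd * _ar1_noise(rng, n_scans, config.bold_ar1)[0]
    drift = drift_per_scan * np.arange(n_scans)
    truth = pd.DataFrame(
        {"onset_time": onsets, "condition": conds, "amplitude": amps}
    )
    return signal + noise + drift, truth
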