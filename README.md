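# loomsight

Analysis toolkit for collision-trajectory detection experiments: looming
stimuli, psychophysics, pupillometry, voxel-grid permutation statistics, and
beta-series path-model search.

When an object approaches an observer's head, its retinal image expands; the
difference between a true collision course and a near miss of a few
centimeters is carried by subtle trajectory cues. Studies of this ability
combine looming-stimulus geometry, psychometric discrimination fits, pupil
responses, event-related fMRI with small anatomical ROIs, and effective
connectivity between subcortical nuclei (superior colliculus, ventromedial
pulvinar, VTA) and cortex. `loomsight` packages that entire computational
chain for reuse, with seeded synthetic-data generators so every stage can be
validated end to end.

## What it computes

- **Stimulus geometry** (`stimgeom`, `study`): angular size `2·atan(d/2D)`,
  time-to-collision `D/v`, 3D-to-screen projection of looming trajectories,
  center-of-mass alignment across conditions, anti-aliased frame rendering,
  balanced trial schedules.
- **Optical flow** (`optflow`): Horn–Schunck dense flow, overall flow
  magnitude Σ(u²+v²), time-integrated flow/luminance profiles by eccentricity.
- **Psychophysics** (`psychofit`): maximum-likelihood cumulative-normal fits
  of hit/miss responses, P(hit|x) = 1 − Φ((x−μ)/σ); sensitivity ln(1/σ);
  exact sign-flip permutation tests.
- **Pupillometry** (`pupil`): blink interpolation, zero-phase low-pass,
  baselining, SD normalization; cluster-length permutation inference over
  time.
- **Voxel/ROI statistics** (`roistats`): fixed-HRF GLMs (canonical and
  subcortical double-gamma kernels), cluster-mass permutation with
  small-volume correction (demeaning and 15–85% exchange filtering),
  LOSO/LORO cross-validated ROI effects, 2×2 repeated-measures ANOVA with
  ηp² and Cohen's d, Holm and Benjamini–Hochberg corrections, robust-MCD
  outlier filtering.
- **Connectivity** (`pathnet`): trial-wise beta series, condition z-scoring,
  beta-series connectivity, enumeration of a 216-model directed-path space,
  ML path fitting with χ²/CFI/GFI/AGFI/PGFI/RMSEA/RMR, PGFI-filter/AGFI-rank
  model selection, and max-|r| permutation FWE for correlation matrices.
- **Synthetic cohorts** (`synthgen`): seeded generators for every input the
  pipeline consumes, with the statistical structure the analyses assume.

## Worked example

Fit a synthetic behavioral cohort and test the upper- vs lower-field
sensitivity difference:

```python
import numpy as np
from loomsight import psychofit, synthgen

cfg = synthgen.CohortConfig(n_subjects=15)   # upper-field sigma 1.0, lower 1.5
table = synthgen.gen_behavior(cfg, seed=1)

sens = {}
for (subj, vf), grp in table.groupby(["subject", "visual_field"]):
    agg = grp.groupby("impact_point_cm")["response_hit"].agg(["sum", "count"])
    fit = psychofit.fit_psychometric(agg.index, agg["sum"], agg["count"])
    sens[(subj, vf)] = fit.sensitivity

subjects = sorted({s for s, _ in sens})
diffs = np.array([sens[s, "upper"] - sens[s, "lower"] for s in subjects])
res = psychofit.exact_sign_permutation(diffs)
print(f"mean sensitivity difference {res.observed_stat:.3f}, "
      f"exact p = {res.p_value:.5f} ({res.n_permutations} permutations)")
```

```
mean sensitivity difference 0.623, exact p = 0.00336 (32768 permutations)
```

The mean difference of ln(1/σ) ≈ 0.62 reflects the generating σ ratio
(ln 1.5 ≈ 0.41, plus the finite-sample bias differential of the σ
estimates at 50 trials per probe point), and the exact test — all 2¹⁵ sign
assignments — rejects the null of no field difference.

Searching the 216-model path space on a synthetic beta-series cohort:

```python
from loomsight import pathnet, synthgen

series = synthgen.gen_beta_series(synthgen.CohortConfig(trials_per_condition=1000), seed=1)
data = pathnet.zscore_by_condition(series).betas.to_numpy()
fits = [pathnet.fit_path_model(m, data=data)
        for m in pathnet.enumerate_model_space(pathnet.default_model_space())]
sel = pathnet.select_best_model(fits)
print(sel.best.model.edges, round(sel.best.indices.AGFI, 4))
```

```
(('vmPul', 'VC'), ('VTA', 'AttNet'), ('SC', 'vmPul'), ('VTA', 'SC'), ('VC', 'AttNet')) 0.9967
```

The winner keeps the generating SC→vmPul path and drops all three optional
connections, as the sparse generating model implies.

A `loomsight` command-line interface wraps the same functions
(`loomsight stim|flow|psycho|pupil|sem|synth --help`).

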