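"""Beta-series connectivity and structural-equation path-model search.

Trial-wise response amplitudes (one GLM regressor per trial) form a
"beta series" per ROI; after z-scoring within each trajectory
condition, pairwise regressions between ROI series quantify functional
connectivity, and a path analysis over observed variables infers
effective connectivity.  A path model with coefficient matrix ``B``
(entry ``B[i, j]`` is the influence of variable j on variable i) and
diagonal residual covariance ``Psi`` implies the covariance

    Sigma(theta) = (I - B)^-1 Psi (I - B)^-T

and is fitted by minimising the maximum-likelihood discrepancy

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

over the free entries of ``B`` and ``Psi``, with chi^2 = (N - 1) F_ML
at the optimum.  The candidate space is the Cartesian product of
directed-edge "slots" (fixed edges, two-direction choices, and
either-direction-or-absent choices); with three two-option and three
three-option slots this yields the full 216-model space.  Model
selection first drops models with PGFI > 0.1 and then ranks the
survivors by AGFI, cross-checking that alternative rankings (chi^2,
CFI, GFI, RMSEA, RMR) agree on the winner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .roistats import HRFModel, build_design_matrix

__all__ = [
    "BetaSeries",
    "PathModel",
    "ModelSpaceSpec",
    "FitIndices",
    "CorrelationFweResult",
    "beta_series_extract",
    "zscore_by_condition",
    "beta_connectivity",
    "enumerate_model_space",
    "default_model_space",
    "fit_path_model",
    "select_best_model",
    "correlation_matrix_fwe",
]


# ---------------------------------------------------------------------------
# Beta series


@dataclass
class BetaSeries:
    """Per-trial GLM amplitudes for one or more ROIs."""

    betas: pd.DataFrame  # columns = ROI names, rows = trials
    condition: np.ndarray  # per-trial labels
    subject_id: str = ""
    z_scored: bool = False

    def __post_init__(self) -> None:
        if len(self.condition) != len(self.betas):
            raise ValueError("condition labels must match trial count")


def beta_series_extract(
    roi_timeseries,
    trial_onsets,
    hrf: HRFModel,
    tr: float,
    condition_labels=None,
    nuisance_regressors=None,
    stimulus_duration: float = 0.33,
    roi_names: Sequence[str] | None = None,
    subject_id: str = "",
) -> BetaSeries:
    """Estimate one beta per trial per ROI with a separate-regressor GLM.

    ``roi_timeseries`` is (n_scans,) or (n_scans, n_rois); each trial
    gets its own HRF-convolved regressor, so betas are returned in
    trial order and permuting trial onsets permutes betas identically.
    """
    y = np.asarray(roi_timeseries, dtype=float)
    y = y.reshape(len(y), -1)
    onsets = np.asarray(trial_onsets, dtype=float)
    n_trials = len(onsets)
    cond_onsets = {f"trial_{i:04d}": np.array([t]) for i, t in enumerate(onsets)}
    X, names = build_design_matrix(
        y.shape[0], tr, cond_onsets, stimulus_duration, hrf, nuisance_regressors
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, :n_trials].T)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise np.linalg.LinAlgError(
            f"rank-deficient trialwise design (rank {rank} < {X.shape[1]}); "
            f"most collinear trials: {i} and {j}"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    trial_betas = coef[:n_trials]
    if roi_names is None:
        roi_names = [f"roi_{k}" for k in range(y.shape[1])]
    if condition_labels is None:
        condition_labels = np.array(["all"] * n_trials)
    return BetaSeries(
        betas=pd.DataFrame(trial_betas, columns=list(roi_names)),
        condition=np.asarray(condition_labels),
        subject_id=subject_id,
        z_scored=False,
    )


def zscore_by_condition(series: BetaSeries) -> BetaSeries:
    """Z-score each ROI's beta series within each trajectory condition.

    Removes mean-amplitude differences between conditions so that
    connectivity reflects trial-to-trial covariation only.
    """
    out = series.betas.copy().astype(float)
    for cond in np.unique(series.condition):
        rows = series.condition == cond
        if rows.sum() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 trials")
        block = out.loc[rows]
        sd = block.std(ddof=1)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance beta series in condition {cond!r}")
        out.loc[rows] = (block - block.mean()) / sd
    return replace(series, betas=out, z_scored=True)


def beta_connectivity(series_a, series_b) -> tuple[float, float]:
    """Second-level regression slope of series b on series a, with p.

    For z-scored inputs the slope equals the Pearson correlation.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    res = stats.linregress(a, b)
    return float(res.slope), float(res.pvalue)


# ---------------------------------------------------------------------------
# Model space


Edge = tuple[str, str]


@dataclass(frozen=True)
class PathModel:
    """Directed path model over observed variables."""

    variables: tuple[str, ...]
    edges: tuple[Edge, ...]  # directed (source, target)
    model_id: str = ""

    def __post_init__(self) -> None:
        names = set(self.variables)
        for s, t in self.edges:
            if s not in names or t not in names:
                raise ValueError(f"edge ({s}, {t}) uses unknown variable")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in model")

    @property
    def is_recursive(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return nx.is_directed_acyclic_graph(g)

    @property
    def n_free_parameters(self) -> int:
        return len(self.edges) + len(self.variables)  # paths + diagonal Psi

    def degrees_of_freedom(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free_parameters


@dataclass(frozen=True)
class ModelSpaceSpec:
    """Slot structure of a candidate path-model space.

    ``common_edges`` appear in every model; each two-option slot
    contributes one of the two orientations of its pair; each
    three-option slot contributes one orientation or nothing.
    """

    variables: tuple[str, ...]
    common_edges: tuple[Edge, ...] = ()
    two_option_slots: tuple[tuple[str, str], ...] = ()
    three_option_slots: tuple[tuple[str, str], ...] = ()


def default_model_space() -> ModelSpaceSpec:
    """Default 216-model space over {SC, vmPul, VTA, VC, AttNet}.

    A reconstruction of the candidate anatomical connections between
    the superior colliculus, ventromedial pulvinar, ventral tegmental
    area, visual cortex and frontoparietal attention network: two
    fixed feed-forward projections, three always-present connections
    with free direction, and three optional connections that may take
    either direction or be absent (2^3 x 3^3 = 216 candidates; with
    all optional edges present each model has 8 paths and df = 2).
    """
    return ModelSpaceSpec(
        variables=("SC", "vmPul", "VTA", "VC", "AttNet"),
        common_edges=(("vmPul", "VC"), ("VTA", "AttNet")),
        two_option_slots=(("SC", "vmPul"), ("SC", "VTA"), ("VC", "AttNet")),
        three_option_slots=(("SC", "VC"), ("SC", "AttNet"), ("VTA", "VC")),
    )


def enumerate_model_space(
    spec: ModelSpaceSpec, drop_cyclic: bool = False
) -> list[PathModel]:
    """Enumerate every slot combination as a PathModel.

    Each two-option slot contributes its two orientations; each
    three-option slot additionally allows absence.  Duplicate edges
    are impossible by construction when slot pairs are distinct.  With
    ``drop_cyclic`` models containing a directed cycle are excluded
    (their count is recorded on the returned list as
    ``enumerate_model_space.n_cyclic_excluded``).
    """
    all_pairs = list(spec.two_option_slots) + list(spec.three_option_slots)
    seen_pairs = {frozenset(p) for p in all_pairs} | {
        frozenset(e) for e in spec.common_edges
    }
    if len(seen_pairs) != len(all_pairs) + len(spec.common_edges):
        raise ValueError("slot/common pairs must be distinct")
    slot_options: list[list[tuple[Edge, ...]]] = []
    for a, b in spec.two_option_slots:
        slot_options.append([((a, b),), ((b, a),)])
    for a, b in spec.three_option_slots:
        slot_options.append([((a, b),), ((b, a),), ()])
    models = []
    n_cyclic = 0
    for k, combo in enumerate(itertools.product(*slot_options)):
        edges = tuple(spec.common_edges) + tuple(
            e for choice in combo for e in choice
        )
        model = PathModel(
            variables=spec.variables, edges=edges, model_id=f"m{k:03d}"
        )
        if drop_cyclic and not model.is_recursive:
            n_cyclic += 1
            continue
        models.append(model)
    enumerate_model_space.n_cyclic_excluded = n_cyclic
    return models


# ---------------------------------------------------------------------------
# ML fitting and fit indices


@dataclass
class FitIndices:
    chi2: float
    df: int
    CFI: float
    GFI: float
    AGFI: float
    PGFI: float
    RMSEA: float
    RMR: float


@dataclass
class FittedPathModel:
    model: PathModel
    B: np.ndarray  # coefficient matrix, B[i, j]: j -> i
    Psi: np.ndarray  # diagonal residual variances
    indices: FitIndices
    converged: bool
    f_ml: float
    coefficient_z: dict[Edge, float] = field(default_factory=dict)


def ml_discrepancy(sigma: np.ndarray, s: np.ndarray) -> float:
    """F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p."""
    p = s.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(s)
    return float(logdet_sigma - logdet_s + np.trace(s @ np.linalg.inv(sigma)) - p)


def implied_covariance(B: np.ndarray, psi_diag: np.ndarray) -> np.ndarray:
    iminusb = np.eye(len(psi_diag)) - B
    inv = np.linalg.inv(iminusb)
    return inv @ np.diag(psi_diag) @ inv.T


def _fit_indices(chi2: float, df: int, s: np.ndarray, sigma: np.ndarray,
                 n_obs: int, n_free: int) -> FitIndices:
    p = s.shape[0]
    # independence baseline: diagonal Sigma
    chi2_b = (n_obs - 1) * ml_discrepancy(np.diag(np.diag(s)), s)
    df_b = p * (p - 1) // 2
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    sigma_inv_s = np.linalg.inv(sigma) @ s
    resid = sigma_inv_s - np.eye(p)
    gfi = 1.0 - np.trace(resid @ resid) / np.trace(sigma_inv_s @ sigma_inv_s)
    half = p * (p + 1) / 2.0
    agfi = 1.0 - (half / df) * (1.0 - gfi) if df > 0 else np.nan
    pgfi = (df / half) * gfi
    rmsea = (
        np.sqrt(max(chi2 - df, 0.0) / (df * (n_obs - 1))) if df > 0 else 0.0
    )
    tril = np.tril_indices(p)
    rmr = float(np.sqrt(np.mean((s - sigma)[tril] ** 2)))
    return FitIndices(
        chi2=float(chi2),
        df=int(df),
        CFI=float(np.clip(cfi, 0.0, 1.0)),
        GFI=float(np.clip(gfi, 0.0, 1.0)),
        AGFI=float(agfi),
        PGFI=float(pgfi),
        RMSEA=float(rmsea),
        RMR=rmr,
    )


def fit_path_model(
    model: PathModel,
    data: np.ndarray | pd.DataFrame | None = None,
    n_obs: int | None = None,
    sample_cov: np.ndarray | None = None,
    n_restarts: int = 5,
    tol: float = 1e-9,
    seed: int = 0,
) -> FittedPathModel:
    """Fit a path model by maximum likelihood.

    Accepts either raw ``data`` (rows = observations, columns ordered
    as ``model.variables``) or a precomputed ``sample_cov`` with
    ``n_obs``.  Free parameters are the path coefficients and the
    log-scale residual variances, optimised by quasi-Newton from
    B = 0, Psi = diag(S), with jittered restarts on failure.
    Approximate z statistics for the path coefficients come from the
    inverse Hessian of the (N-1)/2-scaled discrepancy.
    """
    if sample_cov is None:
        if data is None:
            raise ValueError("provide data or sample_cov")
        x = np.asarray(data, dtype=float)
        if n_obs is None:
            n_obs = x.shape[0]
        s = np.cov(x, rowvar=False, ddof=1)
    else:
        s = np.asarray(sample_cov, dtype=float)
        if n_obs is None:
            raise ValueError("n_obs is required with sample_cov")
    p = len(model.variables)
    if s.shape != (p, p):
        raise ValueError("covariance shape does not match variables")
    if np.any(np.linalg.eigvalsh(s) <= 0):
        raise ValueError("sample covariance must be positive definite")
    df = model.degrees_of_freedom()
    if df < 0:
        raise ValueError("model is not identified (negative df)")
    index = {v: i for i, v in enumerate(model.variables)}
    edge_idx = [(index[t], index[src]) for src, t in model.edges]
    n_edges = len(edge_idx)

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        B = np.zeros((p, p))
        for k, (i, j) in enumerate(edge_idx):
            B[i, j] = theta[k]
        psi = np.exp(theta[n_edges:])
        return B, psi

    def objective(theta: np.ndarray) -> float:
        B, psi = unpack(theta)
        iminusb = np.eye(p) - B
        if abs(np.linalg.det(iminusb)) < 1e-12:
            return 1e6
        return ml_discrepancy(implied_covariance(B, psi), s)

    theta0 = np.concatenate([np.zeros(n_edges), np.log(np.diag(s))])
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.3, len(theta0))
        res = optimize.minimize(
            objective, start, method="L-BFGS-B", options={"ftol": tol, "gtol": 1e-10}
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if best.success and attempt >= 0 and best.fun < 1e5:
            break
    converged = bool(best.success and best.fun < 1e5)
    B, psi = unpack(best.x)
    f_ml = max(float(best.fun), 0.0)
    chi2 = (n_obs - 1) * f_ml
    sigma = implied_covariance(B, psi)
    indices = _fit_indices(chi2, df, s, sigma, n_obs, model.n_free_parameters)

    # z statistics from the observed information of the ML objective
    z: dict[Edge, float] = {}
    if converged and n_edges:
        try:
            h = _numerical_hessian(objective, best.x)
            cov_theta = np.linalg.inv(0.5 * (n_obs - 1) * h)
            se = np.sqrt(np.clip(np.diag(cov_theta), 0, None))
            for k, edge in enumerate(model.edges):
                z[edge] = float(best.x[k] / se[k]) if se[k] > 0 else np.inf
        except np.linalg.LinAlgError:
            pass
    return FittedPathModel(
        model=model,
        B=B,
        Psi=np.diag(psi),
        indices=indices,
        converged=converged,
        f_ml=f_ml,
        coefficient_z=z,
    )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    fx = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            h[i, j] = h[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    return h


# ---------------------------------------------------------------------------
# Model selection


@dataclass
class SelectionResult:
    best: FittedPathModel
    ranking: pd.DataFrame
    n_filtered: int
    ranking_invariant: bool
    tie: bool = False


def select_best_model(
    fits: Sequence[FittedPathModel],
    pgfi_threshold: float = 0.1,
) -> SelectionResult:
    """PGFI-filter then AGFI-rank model selection.

    The parsimony filter excludes models whose PGFI falls below
    ``pgfi_threshold`` — PGFI is proportional to the degrees of
    freedom, so a low value marks a near-saturated model that buys fit
    with parameters.  The survivors are ranked by AGFI descending,
    with non-converged fits ranked last and ties broken
    lexicographically by model id.  Alternate rankings by chi^2, CFI,
    GFI, RMSEA and RMR are also computed and the result records
    whether they agree on the winner.
    """
    if not fits:
        raise ValueError("no fitted models to select from")
    rows = []
    for f in fits:
        ix = f.indices
        rows.append(
            {
                "model_id": f.model.model_id,
                "converged": f.converged,
                "chi2": ix.chi2,
                "df": ix.df,
                "CFI": ix.CFI,
                "GFI": ix.GFI,
                "AGFI": ix.AGFI,
                "PGFI": ix.PGFI,
                "RMSEA": ix.RMSEA,
                "RMR": ix.RMR,
            }
        )
    table = pd.DataFrame(rows)
    surviving = table[table["PGFI"] >= pgfi_threshold].copy()
    n_filtered = len(table) - len(surviving)
    if surviving.empty:
        raise ValueError(
            "every model was excluded by the PGFI filter; review the threshold"
        )
    by_id = {f.model.model_id: f for f in fits}

    def rank(df: pd.DataFrame, col: str, ascending: bool) -> pd.DataFrame:
        return df.sort_values(
            ["converged", col, "model_id"],
            ascending=[False, ascending, True],
            kind="mergesort",
        )

    ranked = rank(surviving, "AGFI", ascending=False)
    winner_id = ranked.iloc[0]["model_id"]
    tie = bool(
        len(ranked) > 1
        and np.isclose(ranked.iloc[0]["AGFI"], ranked.iloc[1]["AGFI"], atol=1e-12)
    )
    alt_winners = {
        col: rank(surviving, col, ascending=asc).iloc[0]["model_id"]
        for col, asc in [
            ("chi2", True),
            ("CFI", False),
            ("GFI", False),
            ("RMSEA", True),
            ("RMR", True),
        ]
    }
    invariant = all(w == winner_id for w in alt_winners.values())
    return SelectionResult(
        best=by_id[winner_id],
        ranking=ranked.reset_index(drop=True),
        n_filtered=n_filtered,
        ranking_invariant=invariant,
        tie=tie,
    )


# ---------------------------------------------------------------------------
# Max-statistic FWE for correlation matrices


@dataclass
class CorrelationFweResult:
    r: pd.DataFrame
    p_uncorrected: pd.DataFrame
    p_fwe: pd.DataFrame
    n_permutations: int
    seed: int | None
    null_max_abs_r: np.ndarray
    n_outliers: pd.DataFrame | None = None


def correlation_matrix_fwe(
    subject_effect_table: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int | None = None,
    remove_outliers: bool = True,
) -> CorrelationFweResult:
    """Pairwise Pearson correlations with max-|r| permutation FWE.

    Each variable pair is correlated across subjects (optionally after
    robust-Mahalanobis outlier removal for that pair); the null
    records, per permutation of the subject correspondences, the
    largest |r| over the whole matrix, and corrected p-values are the
    proportion of the null at least as large as each observed |r|.
    """
    from .roistats import robust_outlier_filter  # local import: avoids cycle at import time

    df = pd.DataFrame(subject_effect_table).astype(float)
    cols = list(df.columns)
    n, k = df.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if k < 2:
        raise ValueError("need at least 2 variables")
    if np.any(df.std(ddof=1) == 0):
        bad = [c for c in cols if df[c].std(ddof=1) == 0]
        raise ValueError(f"constant columns: {bad}")
    x = df.to_numpy()

    r = np.eye(k)
    p_unc = np.zeros((k, k))
    n_out = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            pair = x[:, [i, j]]
            if remove_outliers:
                res = robust_outlier_filter(pair)
                pair = res.kept
                n_out[i, j] = n_out[j, i] = int(res.outlier_flags.sum())
            rij, pij = stats.pearsonr(pair[:, 0], pair[:, 1])
            r[i, j] = r[j, i] = rij
            p_unc[i, j] = p_unc[j, i] = pij

    rng = np.random.default_rng(seed)
    xc = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    null = np.empty(n_permutations)
    iu = np.triu_indices(k, 1)
    for m in range(n_permutations):
        perm = np.column_stack([xc[rng.permutation(n), j] for j in range(k)])
        corr = perm.T @ perm / (n - 1)
        null[m] = np.abs(corr[iu]).max()
    p_fwe = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p_fwe[i, j] = p_fwe[j, i] = (
                1 + int(np.sum(null >= abs(r[i, j])))
            ) / (n_permutations + 1)
    wrap = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationFweResult(
        r=wrap(r),
        p_uncorrected=wrap(p_unc),
        p_fwe=wrap(np.maximum(p_fwe, p_unc)),
        n_permutations=n_permutations,
        seed=seed,
        null_max_abs_r=null,
        n_outliers=wrap(n_out) if remove_outliers else None,
    )
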