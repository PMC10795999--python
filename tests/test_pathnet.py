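"""Beta series, model-space enumeration, ML path fitting and selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loomsight import pathnet, synthgen
from loomsight.pathnet import (
    BetaSeries,
    ModelSpaceSpec,
    PathModel,
    beta_connectivity,
    beta_series_extract,
    correlation_matrix_fwe,
    default_model_space,
    enumerate_model_space,
    fit_path_model,
    implied_covariance,
    ml_discrepancy,
    select_best_model,
    zscore_by_condition,
)
from loomsight.roistats import HRFModel
from loomsight.stimgeom import make_trial_schedule


def recursive_ml_closed_form(model: PathModel, S: np.ndarray):
    """Independent oracle: ML estimates of a recursive path model.

    For an acyclic model with diagonal residual covariance the
    likelihood factorizes over equations, so the ML path coefficients
    are the per-equation regression coefficients computed from the
    sample covariance, and each residual variance is the corresponding
    Schur complement.  Derived directly from S with linear algebra —
    no iterative optimisation shared with the implementation.
    """
    p = len(model.variables)
    idx = {v: i for i, v in enumerate(model.variables)}
    B = np.zeros((p, p))
    psi = np.zeros(p)
    parents: dict[int, list[int]] = {i: [] for i in range(p)}
    for src, tgt in model.edges:
        parents[idx[tgt]].append(idx[src])
    for i in range(p):
        pa = parents[i]
        if pa:
            coef = np.linalg.solve(S[np.ix_(pa, pa)], S[np.ix_(pa, [i])]).ravel()
            for k, j in enumerate(pa):
                B[i, j] = coef[k]
            psi[i] = S[i, i] - S[i, pa] @ coef
        else:
            psi[i] = S[i, i]
    return B, psi


@pytest.fixture(scope="module")
def beta_cov():
    """Sample covariance of a large synthetic beta-series cohort."""
    cfg = synthgen.CohortConfig(trials_per_condition=1000)
    series = synthgen.gen_beta_series(cfg, seed=1)
    data = zscore_by_condition(series).betas.to_numpy()
    return np.cov(data, rowvar=False, ddof=1), data.shape[0]


class TestBetaSeriesExtract:
    def _inputs(self, noise_sd=0.0, seed=0):
        cfg = synthgen.CohortConfig(bold_noise_sd=noise_sd)
        sched = make_trial_schedule(
            {"condition": ["hit", "miss"]}, runs=1, trials_per_run=12,
            isi_choices=[8.0, 10.0, 12.0], seed=seed,
        ).table
        hrf = HRFModel.subcortical()
        y, truth = synthgen.gen_bold(cfg, sched, hrf, seed=seed, amplitude_sd=0.3)
        return y, truth, hrf, cfg.bold_tr

    def test_noiseless_exact_recovery(self):
        y, truth, hrf, tr = self._inputs()
        series = beta_series_extract(
            y, truth["onset_time"], hrf, tr, condition_labels=truth["condition"]
        )
        assert np.allclose(
            series.betas.iloc[:, 0].to_numpy(), truth["amplitude"], atol=1e-8
        )

    def test_one_beta_per_trial(self):
        y, truth, hrf, tr = self._inputs(noise_sd=0.2)
        series = beta_series_extract(y, truth["onset_time"], hrf, tr)
        assert len(series.betas) == len(truth)

    def test_trial_order_equivariance(self):
        y, truth, hrf, tr = self._inputs()
        perm = np.random.default_rng(0).permutation(len(truth))
        direct = beta_series_extract(y, truth["onset_time"], hrf, tr)
        shuffled = beta_series_extract(y, truth["onset_time"].to_numpy()[perm], hrf, tr)
        assert np.allclose(
            shuffled.betas.iloc[:, 0].to_numpy(),
            direct.betas.iloc[:, 0].to_numpy()[perm],
            atol=1e-8,
        )


class TestZscoreByCondition:
    def _series(self, rng):
        betas = pd.DataFrame({"SC": rng.normal(2, 3, 40), "VC": rng.normal(size=40)})
        cond = np.repeat(["hit", "miss"], 20)
        return BetaSeries(betas=betas, condition=cond)

    def test_unit_moments_per_condition(self, rng):
        z = zscore_by_condition(self._series(rng))
        for cond in ("hit", "miss"):
            block = z.betas[z.condition == cond]
            assert np.allclose(block.mean(), 0.0, atol=1e-12)
            assert np.allclose(block.std(ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        s = self._series(rng)
        shifted = BetaSeries(betas=s.betas * 4.0 - 7.0, condition=s.condition)
        assert np.allclose(
            zscore_by_condition(s).betas, zscore_by_condition(shifted).betas
        )

    def test_single_condition_equals_global_zscore(self, rng):
        betas = pd.DataFrame({"SC": rng.normal(size=30)})
        s = BetaSeries(betas=betas, condition=np.array(["all"] * 30))
        z = zscore_by_condition(s)
        expected = (betas["SC"] - betas["SC"].mean()) / betas["SC"].std(ddof=1)
        assert np.allclose(z.betas["SC"], expected)

    def test_zero_variance_condition_rejected(self):
        s = BetaSeries(
            betas=pd.DataFrame({"SC": [1.0, 1.0, 2.0, 3.0]}),
            condition=np.array(["a", "a", "b", "b"]),
        )
        with pytest.raises(ValueError):
            zscore_by_condition(s)


class TestBetaConnectivity:
    def test_self_connectivity_is_one(self, rng):
        a = rng.normal(size=50)
        a = (a - a.mean()) / a.std(ddof=1)
        coef, _ = beta_connectivity(a, a)
        assert coef == pytest.approx(1.0)

    def test_slope_equals_pearson_for_zscored(self, rng):
        a = rng.normal(size=80)
        b = 0.5 * a + rng.normal(size=80)
        az = (a - a.mean()) / a.std(ddof=1)
        bz = (b - b.mean()) / b.std(ddof=1)
        coef, _ = beta_connectivity(az, bz)
        assert coef == pytest.approx(stats.pearsonr(a, b).statistic, abs=1e-12)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(9)
        pvals = [
            beta_connectivity(rng.normal(size=60), rng.normal(size=60))[1]
            for _ in range(400)
        ]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestEnumerateModelSpace:
    def test_default_space_has_216_models(self):
        models = enumerate_model_space(default_model_space())
        assert len(models) == 216
        ids = [m.model_id for m in models]
        assert len(set(ids)) == 216

    def test_all_present_models_have_df_two(self):
        # eight paths (2 fixed + 3 oriented + 3 optional present) leave
        # 15 - 13 = 2 degrees of freedom, as in the published best fits
        models = enumerate_model_space(default_model_space())
        assert min(m.degrees_of_freedom() for m in models) == 2
        assert max(m.degrees_of_freedom() for m in models) == 5

    def test_single_two_option_slot(self):
        spec = ModelSpaceSpec(
            variables=("A", "B"), two_option_slots=(("A", "B"),)
        )
        models = enumerate_model_space(spec)
        assert len(models) == 2
        assert {m.edges[0] for m in models} == {("A", "B"), ("B", "A")}

    def test_empty_slots_single_model(self):
        spec = ModelSpaceSpec(variables=("A", "B"), common_edges=(("A", "B"),))
        models = enumerate_model_space(spec)
        assert len(models) == 1

    def test_drop_cyclic_logs_count(self):
        spec = ModelSpaceSpec(
            variables=("A", "B", "C"),
            two_option_slots=(("A", "B"), ("B", "C"), ("C", "A")),
        )
        kept = enumerate_model_space(spec, drop_cyclic=True)
        assert enumerate_model_space.n_cyclic_excluded == 2  # the two 3-cycles
        assert len(kept) == 6
        assert all(m.is_recursive for m in kept)


class TestFitPathModel:
    def test_saturated_model_chi2_zero(self, beta_cov):
        S, N = beta_cov
        sat = PathModel(
            variables=("a", "b", "c", "d", "e"),
            edges=tuple(
                (f, t)
                for i, f in enumerate("abcde")
                for t in "abcde"[i + 1 :]
            ),
        )
        assert sat.degrees_of_freedom() == 0
        fit = fit_path_model(sat, sample_cov=S, n_obs=N)
        assert fit.indices.chi2 == pytest.approx(0.0, abs=1e-4)

    def test_discrepancy_zero_at_sample_covariance(self, beta_cov):
        S, _ = beta_cov
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_at_n_2000(self):
        variables = ("SC", "vmPul", "VTA", "VC", "AttNet")
        B_true = np.zeros((5, 5))
        B_true[1, 0], B_true[2, 0], B_true[3, 1], B_true[4, 3] = 0.6, 0.5, 0.4, 0.5
        cfg = synthgen.CohortConfig(trials_per_condition=1000)  # 2,000 trials
        series = synthgen.gen_beta_series(cfg, seed=21, B=B_true)
        model = PathModel(
            variables=variables,
            edges=(("SC", "vmPul"), ("SC", "VTA"), ("vmPul", "VC"), ("VC", "AttNet")),
        )
        fit = fit_path_model(model, data=series.betas.to_numpy())
        se = 1.0 / np.sqrt(2000)
        for (src, tgt), truth in [
            (("SC", "vmPul"), 0.6), (("SC", "VTA"), 0.5),
            (("vmPul", "VC"), 0.4), (("VC", "AttNet"), 0.5),
        ]:
            i = variables.index(tgt)
            j = variables.index(src)
            assert fit.B[i, j] == pytest.approx(truth, abs=4 * se)

    def test_matches_closed_form_oracle_on_random_models(self, beta_cov):
        S, N = beta_cov
        models = [
            m for m in enumerate_model_space(default_model_space()) if m.is_recursive
        ]
        picked = np.random.default_rng(2).choice(len(models), size=20, replace=False)
        for k in picked:
            model = models[k]
            fit = fit_path_model(model, sample_cov=S, n_obs=N)
            B, psi = recursive_ml_closed_form(model, S)
            f_oracle = ml_discrepancy(implied_covariance(B, psi), S)
            assert fit.f_ml == pytest.approx(f_oracle, abs=1e-6)
            assert np.abs(fit.B - B).max() < 1e-3
            # indices recomputed from the oracle solution agree to 1e-3
            chi2_oracle = (N - 1) * f_oracle
            assert fit.indices.chi2 == pytest.approx(chi2_oracle, abs=1e-3 * max(chi2_oracle, 1))

    def test_chi2_invariant_to_variable_reordering(self, beta_cov):
        S, N = beta_cov
        variables = ("SC", "vmPul", "VTA", "VC", "AttNet")
        edges = (("SC", "vmPul"), ("SC", "VTA"), ("vmPul", "VC"))
        model = PathModel(variables=variables, edges=edges)
        perm = [3, 0, 4, 1, 2]
        vars_p = tuple(variables[i] for i in perm)
        S_p = S[np.ix_(perm, perm)]
        fit = fit_path_model(model, sample_cov=S, n_obs=N)
        fit_p = fit_path_model(
            PathModel(variables=vars_p, edges=edges), sample_cov=S_p, n_obs=N
        )
        assert fit.indices.chi2 == pytest.approx(fit_p.indices.chi2, abs=1e-4)

    def test_chi2_monotone_in_nested_models(self, beta_cov):
        S, N = beta_cov
        variables = ("SC", "vmPul", "VTA", "VC", "AttNet")
        nested = [
            (("SC", "vmPul"),),
            (("SC", "vmPul"), ("SC", "VTA")),
            (("SC", "vmPul"), ("SC", "VTA"), ("vmPul", "VC")),
            (("SC", "vmPul"), ("SC", "VTA"), ("vmPul", "VC"), ("VC", "AttNet")),
        ]
        chi2 = [
            fit_path_model(
                PathModel(variables=variables, edges=e), sample_cov=S, n_obs=N
            ).indices.chi2
            for e in nested
        ]
        assert all(c2 <= c1 + 1e-6 for c1, c2 in zip(chi2, chi2[1:]))


class TestSelectBestModel:
    def test_single_survivor_selected(self, beta_cov):
        S, N = beta_cov
        model = PathModel(
            variables=("SC", "vmPul", "VTA", "VC", "AttNet"),
            edges=(("SC", "vmPul"),),
        )
        fit = fit_path_model(model, sample_cov=S, n_obs=N)
        sel = select_best_model([fit])
        assert sel.best is fit

    def test_identical_fits_tie_flagged(self, beta_cov):
        S, N = beta_cov
        m1 = PathModel(
            variables=("SC", "vmPul", "VTA", "VC", "AttNet"),
            edges=(("SC", "vmPul"),), model_id="m_a",
        )
        m2 = PathModel(
            variables=("SC", "vmPul", "VTA", "VC", "AttNet"),
            edges=(("SC", "vmPul"),), model_id="m_b",
        )
        fits = [fit_path_model(m, sample_cov=S, n_obs=N) for m in (m1, m2)]
        sel = select_best_model(fits)
        assert sel.tie
        assert sel.best.model.model_id == "m_a"  # lexicographic tie-break

    def test_generating_model_wins_in_small_space(self):
        # chain truth A -> B -> C vs collider and no-edge alternatives
        variables = ("A", "B", "C")
        space = ModelSpaceSpec(
            variables=variables,
            common_edges=(("A", "B"),),
            three_option_slots=(("B", "C"),),
        )
        B_true = np.zeros((3, 3))
        B_true[1, 0] = 0.7  # A -> B
        B_true[2, 1] = 0.6  # B -> C
        cfg = synthgen.CohortConfig(trials_per_condition=500)  # N = 1,000
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            series = synthgen.gen_beta_series(
                cfg, seed=seed, B=B_true, variables=variables
            )
            data = series.betas.to_numpy()
            fits = [
                fit_path_model(m, data=data)
                for m in enumerate_model_space(space)
            ]
            sel = select_best_model(fits, pgfi_threshold=0.0)
            if sel.best.model.edges == (("A", "B"), ("B", "C")):
                wins += 1
        assert wins > n_seeds / 2

    def test_all_filtered_raises(self, beta_cov):
        S, N = beta_cov
        sat = PathModel(
            variables=("a", "b", "c", "d", "e"),
            edges=tuple(
                (f, t) for i, f in enumerate("abcde") for t in "abcde"[i + 1 :]
            ),
        )
        fit = fit_path_model(sat, sample_cov=S, n_obs=N)  # df=0 -> PGFI=0
        with pytest.raises(ValueError):
            select_best_model([fit])


class TestCorrelationFwe:
    def test_duplicated_column_r_one(self, rng):
        x = rng.normal(size=20)
        table = pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-9, 20), "c": rng.normal(size=20)})
        res = correlation_matrix_fwe(table, n_permutations=200, seed=0, remove_outliers=False)
        assert res.r.loc["a", "b"] == pytest.approx(1.0, abs=1e-6)

    def test_corrected_p_dominates_uncorrected(self, rng):
        table = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        res = correlation_matrix_fwe(table, n_permutations=300, seed=1, remove_outliers=False)
        off = ~np.eye(4, dtype=bool)
        assert np.all(res.p_fwe.to_numpy()[off] >= res.p_uncorrected.to_numpy()[off] - 1e-12)

    def test_family_wise_error_calibrated(self):
        rng = np.random.default_rng(41)
        n_sims, fams = 800, 0
        for k in range(n_sims):
            table = pd.DataFrame(rng.normal(size=(20, 4)))
            res = correlation_matrix_fwe(
                table, n_permutations=250, seed=k, remove_outliers=False
            )
            off = ~np.eye(4, dtype=bool)
            if np.any(res.p_fwe.to_numpy()[off] < 0.05):
                fams += 1
        assert 0.03 <= fams / n_sims <= 0.07

    def test_constant_column_rejected(self, rng):
        table = pd.DataFrame({"a": np.ones(10), "b": rng.normal(size=10)})
        with pytest.raises(ValueError):
            correlation_matrix_fwe(table)
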