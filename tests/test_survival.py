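"""Cox machinery, inverse normal transform, panel training, and stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from gliolnc import synthdata
from gliolnc.survival import (
    PrognosticPanel,
    clinical_design,
    cox_fit,
    inverse_normal_transform,
    kaplan_meier,
    logrank_test,
    per_lncrna_prognosis,
    stratify_and_evaluate,
    summed_cox_score,
    tertile_km,
    train_panel,
    transform_matrix,
)


class TestInverseNormalTransform:
    def test_three_distinct_values(self):
        # Phi^-1(1/6), Phi^-1(3/6), Phi^-1(5/6)
        out = inverse_normal_transform([10.0, 20.0, 30.0])
        assert out == pytest.approx([-0.9674215661017014, 0.0, 0.9674215661017014], abs=1e-12)

    def test_monotone_transform_invariance(self):
        x = np.array([3.0, 1.0, 10.0, 7.0, 2.0])
        assert inverse_normal_transform(x) == pytest.approx(inverse_normal_transform(np.exp(x)), abs=1e-12)

    def test_mean_zero_for_distinct_inputs(self):
        rng = np.random.default_rng(0)
        out = inverse_normal_transform(rng.normal(size=101))
        assert abs(out.mean()) < 1e-12

    def test_identical_values_map_to_zero(self):
        assert inverse_normal_transform([5.0, 5.0, 5.0]) == pytest.approx([0.0, 0.0, 0.0])

    def test_output_is_normal_for_large_n(self):
        rng = np.random.default_rng(1)
        out = inverse_normal_transform(rng.exponential(size=200))
        assert stats.kstest(out, "norm").pvalue > 0.01


def _naive_efron_loglik(beta, x, times, events):
    """Independent oracle: Efron partial log-likelihood by explicit loops."""
    eta = beta * x
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        tied = (times == t) & (events == 1)
        risk = times >= t
        d = tied.sum()
        s_tie = np.exp(eta[tied]).sum()
        s_risk = np.exp(eta[risk]).sum()
        ll += eta[tied].sum()
        for l in range(d):
            ll -= np.log(s_risk - (l / d) * s_tie)
    return ll


class TestCoxFit:
    def test_matches_brute_force_oracle_small_n(self):
        """1-covariate fits equal direct maximization of the written-out likelihood."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 40:
            n = int(rng.integers(4, 9))
            x = rng.normal(size=n).round(1)
            if x.std() == 0:
                continue
            times = rng.integers(1, 6, size=n).astype(float)  # deliberate ties
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                continue
            fit = cox_fit(x[:, None], times, events, names=["x"])
            if not fit.converged or abs(fit.params[0]) > 5:
                continue  # near-separation: oracle comparison meaningless
            oracle = optimize.minimize_scalar(
                lambda b: -_naive_efron_loglik(b, x, times, events), bounds=(-10, 10), method="bounded",
                options={"xatol": 1e-10},
            )
            assert fit.params[0] == pytest.approx(oracle.x, abs=1e-5)
            assert fit.loglik == pytest.approx(-oracle.fun, abs=1e-9)
            checked += 1

    def test_matches_lifelines_multivariate(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 250
        X = np.column_stack([rng.normal(size=n), rng.binomial(1, 0.5, n)]).astype(float)
        t, e = synthdata.simulate_survival(0.5 * X[:, 0] - 0.7 * X[:, 1], seed=7, censor_rate=0.3)
        t = np.ceil(t / 30)  # force heavy ties
        fit = cox_fit(X, t, e, names=["a", "b"])
        df = pd.DataFrame(X, columns=["a", "b"]).assign(T=t, E=e)
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.params == pytest.approx(cph.params_.to_numpy(), abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_.to_numpy(), abs=1e-4)

    def test_loglik_history_non_decreasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 3))
        t, e = synthdata.simulate_survival(X @ [0.4, -0.3, 0.0], seed=3, censor_rate=0.2)
        fit = cox_fit(X, t, e)
        assert np.all(np.diff(fit.loglik_history) >= -1e-12)
        assert fit.converged

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 2))
        t, e = synthdata.simulate_survival(X @ [0.5, -0.5], seed=5, censor_rate=0.2)
        assert len(np.unique(t)) == len(t)
        efron = cox_fit(X, t, e)
        breslow = cox_fit(X, t, e, ties="breslow")
        assert efron.params == pytest.approx(breslow.params, abs=1e-10)
        assert efron.loglik == pytest.approx(breslow.loglik, abs=1e-9)

    def test_null_covariate_near_zero(self):
        big_z = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            t, e = synthdata.simulate_survival(np.zeros(200), seed=seed, censor_rate=0.25)
            fit = cox_fit(x[:, None], t, e)
            big_z += int(abs(fit.z[0]) >= 3)
        assert big_z <= 1

    def test_constant_column_rejected(self):
        t = np.arange(1.0, 21.0)
        e = np.ones(20, dtype=int)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.ones((20, 1)), t, e)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit(np.arange(10.0)[:, None], np.arange(1.0, 11.0), np.zeros(10, dtype=int))

    def test_separation_flagged(self):
        # covariate perfectly orders the event times: monotone likelihood
        t = np.arange(1.0, 13.0)
        x = np.arange(12.0)
        e = np.ones(12, dtype=int)
        with pytest.warns(UserWarning, match="separation"):
            fit = cox_fit(x[:, None], t, e)
        assert not fit.converged


class TestKaplanMeierLogrank:
    def test_no_censoring_equals_empirical_survival(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        km = kaplan_meier(times, np.ones(5, dtype=int))
        for t, s in zip(km.timeline, km.survival):
            assert s == pytest.approx(np.mean(times > t))
        assert km.median == 3.0

    def test_all_censored_flat_curve(self):
        km = kaplan_meier([5.0, 10.0, 15.0], [0, 0, 0])
        assert (km.survival == 1.0).all()
        assert km.median is None

    def test_logrank_two_identical_groups_calibrated(self):
        low_p = 0
        for seed in range(40):
            t, e = synthdata.simulate_survival(np.zeros(60), seed=seed, censor_rate=0.2)
            groups = np.repeat([0, 1], 30)
            _, p = logrank_test(t, e, groups)
            low_p += int(p < 0.1)
        assert low_p <= 10  # ~10% expected under the null


class TestPanelPipeline:
    @pytest.fixture(scope="class")
    @staticmethod
    def trained(small_lgg_cohort):
        cohort = small_lgg_cohort
        expr_test = cohort.expression[cohort.test_samples]
        panel = train_panel(
            transform_matrix(expr_test),
            cohort.clinical.loc[cohort.test_samples],
            n_subsamples=50,
            seed=2,
        )
        return cohort, panel

    def test_recovers_planted_prognostic_lncrnas(self, trained):
        cohort, panel = trained
        planted = set(cohort.truth.prognostic)
        assert len(set(panel.members.index) & planted) >= 3  # of 4 planted
        nulls = set(panel.members.index) - planted
        assert len(nulls) <= 0.1 * (40 - 4)

    def test_median_coefficient_signs_match_truth(self, trained):
        cohort, panel = trained
        for gene in set(panel.members.index) & set(cohort.truth.prognostic):
            assert np.sign(panel.members.loc[gene, "median_coef"]) == np.sign(cohort.truth.prognostic[gene])

    def test_selection_frequency_at_least_threshold(self, trained):
        _, panel = trained
        assert (panel.members["selection_freq"] >= 0.80).all()

    def test_deterministic_under_seed(self, small_lgg_cohort):
        cohort = small_lgg_cohort
        expr = transform_matrix(cohort.expression[cohort.test_samples])
        clin = cohort.clinical.loc[cohort.test_samples]
        p1 = train_panel(expr, clin, n_subsamples=20, seed=9)
        p2 = train_panel(expr, clin, n_subsamples=20, seed=9)
        pd.testing.assert_frame_equal(p1.members, p2.members)

    def test_panel_json_roundtrip(self, trained, tmp_path):
        _, panel = trained
        panel.to_json(tmp_path / "panel.json")
        back = PrognosticPanel.from_json(tmp_path / "panel.json")
        pd.testing.assert_frame_equal(panel.members, back.members, check_names=False)
        assert back.seed == panel.seed

    def test_validation_split_separates_risk_groups(self, trained):
        cohort, panel = trained
        res = stratify_and_evaluate(
            panel,
            cohort.expression[cohort.validation_samples],
            cohort.clinical.loc[cohort.validation_samples],
            mode="signed",
        )
        assert res.hazard_ratio is not None and res.hazard_ratio > 1
        assert res.logrank_p < 0.05


class TestSummedCoxScore:
    def _panel(self, coef=0.5):
        members = pd.DataFrame(
            {"median_coef": [coef], "selection_freq": [0.9], "ref_mean": [0.0], "ref_sd": [1.0]},
            index=pd.Index(["lncA"], name="lncRNA"),
        )
        return PrognosticPanel(members=members)

    def test_all_z_below_cutoff_gives_zero(self):
        expr = pd.DataFrame({"p1": [0.5], "p2": [-0.9]}, index=["lncA"])
        scores = summed_cox_score(self._panel(), expr)
        assert (scores == 0).all()

    def test_paper_literal_adds_coefficient_regardless_of_sign(self):
        expr = pd.DataFrame({"p1": [1.2], "p2": [-1.2]}, index=["lncA"])
        scores = summed_cox_score(self._panel(0.5), expr, mode="paper_literal")
        assert scores.to_numpy() == pytest.approx([0.5, 0.5])

    def test_signed_mode_flips_for_negative_z(self):
        expr = pd.DataFrame({"p1": [1.2], "p2": [-1.2]}, index=["lncA"])
        scores = summed_cox_score(self._panel(0.5), expr, mode="signed")
        assert scores.to_numpy() == pytest.approx([0.5, -0.5])

    def test_missing_panel_lncrna_is_error(self):
        expr = pd.DataFrame({"p1": [1.2]}, index=["other"])
        with pytest.raises(KeyError):
            summed_cox_score(self._panel(), expr)

    def test_zero_score_lands_in_good_group(self, small_lgg_cohort):
        cohort = small_lgg_cohort
        members = pd.DataFrame(
            {
                "median_coef": [0.0],
                "selection_freq": [1.0],
                "ref_mean": [0.0],
                "ref_sd": [1.0],
            },
            index=pd.Index([cohort.expression.index[0]], name="lncRNA"),
        )
        panel = PrognosticPanel(members=members)
        with pytest.warns(UserWarning, match="empty"):
            res = stratify_and_evaluate(panel, cohort.expression, cohort.clinical)
        assert res.group_sizes["poor"] == 0
        assert res.hazard_ratio is None


class TestPerLncrnaPrognosis:
    def test_planted_hazard_and_protective_directions(self, small_lgg_cohort):
        cohort = small_lgg_cohort
        table = per_lncrna_prognosis(cohort.expression, cohort.clinical)
        for gene, beta in cohort.truth.prognostic.items():
            expected = "poor" if beta > 0 else "good"
            assert table.loc[gene, "group"] == expected

    def test_null_call_rate_near_alpha(self):
        cohort = synthdata.simulate_lgg_cohort(n_samples=200, n_lncrnas=100, n_prognostic=0, seed=31)
        table = per_lncrna_prognosis(cohort.expression, cohort.clinical)
        assert (table["group"] != "ns").mean() <= 0.12


class TestTertileKm:
    def test_group_size_arithmetic(self, small_lgg_cohort):
        cohort = small_lgg_cohort
        six = cohort.expression.iloc[0, :6]
        out = tertile_km(six, cohort.clinical)
        assert out["n_per_group"] == 2

    def test_constant_expression_rejected(self, small_lgg_cohort):
        cohort = small_lgg_cohort
        const = pd.Series(1.0, index=cohort.expression.columns)
        with pytest.raises(ValueError, match="constant"):
            tertile_km(const, cohort.clinical)

    def test_monotone_effect_direction(self, small_lgg_cohort):
        cohort = small_lgg_cohort
        gene, beta = next(iter(cohort.truth.prognostic.items()))
        out = tertile_km(cohort.expression.loc[gene], cohort.clinical)
        assert (out["hr"] > 1) == (beta > 0)


class TestClinicalDesign:
    def test_coding_and_missing_handling(self, clinical_frame):
        clinical = clinical_frame.set_index("sample", drop=False)
        clinical.loc["s1", "idh_mut"] = np.nan
        design = clinical_design(clinical)
        assert "s1" not in design.index
        assert design.loc["s0", "sex"] == 1.0  # male
        assert design.loc["s1" if "s1" in design.index else "s3", "grade"] == 1.0  # grade III
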