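"""Tests for reliability, Bayes factor, trimming, and prediction statistics."""

import numpy as np
import pandas as pd
import pytest

from bandit_aif.cohort import CohortSpec, generate_cohort, plant_effect
from bandit_aif.stability import (
    bf10_from_r,
    change_score_analysis,
    grubbs_trim,
    icc31,
    jzs_bf_correlation,
    predictive_correlation,
    reliability_report,
    stay_shift_counts,
)


def anova_icc_oracle(x, y):
    """Independent two-way ANOVA-table computation of ICC(3,1)."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((data - grand) ** 2).sum() - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestIcc31:
    def test_identical_sessions(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert icc31(x, x)[0] == pytest.approx(1.0)

    def test_consistency_ignores_constant_shift(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert icc31(x, x + 0.7)[0] == pytest.approx(1.0)

    def test_matches_anova_oracle_on_small_example(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 3, 2, 5, 4])
        icc, _ = icc31(x, y)
        assert icc == pytest.approx(anova_icc_oracle(x, y), abs=1e-10)
        assert icc == pytest.approx(0.8, abs=1e-12)

    def test_matches_oracle_on_random_data(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            assert icc31(x, y)[0] == pytest.approx(anova_icc_oracle(x, y), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=25)
        y = 0.6 * x + rng.normal(scale=0.8, size=25)
        icc, p = icc31(x, y)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(25), 2),
                "rater": np.tile(["a", "b"], 25),
                "score": np.column_stack([x, y]).ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        row = ref[ref.Type == "ICC(C,1)"].iloc[0]  # consistency, single measure
        assert icc == pytest.approx(row.ICC, abs=1e-10)
        assert p == pytest.approx(row.pval, abs=1e-10)

    def test_zero_row_variance_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            icc31(np.ones(5), np.ones(5))

    def test_reliability_report_pools_groups(self, rng):
        n = 30
        table = pd.DataFrame(
            {
                "subject_id": np.repeat([f"S{i}" for i in range(n)], 2),
                "group": np.repeat(["hc"] * 15 + ["sud"] * 15, 2),
                "session": np.tile(["baseline", "followup"], n),
                "m": rng.normal(size=2 * n),
            }
        )
        rep = reliability_report(table, ["m"])
        assert set(rep.group) == {"all", "hc", "sud"}
        ns = rep.set_index("group")["n"]
        assert ns["all"] == ns["hc"] + ns["sud"]


class TestJzsBayesFactor:
    def test_null_data_favors_null(self, rng):
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        assert jzs_bf_correlation(x, y) < 1

    def test_strong_correlation_overwhelming(self, rng):
        x = rng.standard_normal(50)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(50)
        assert jzs_bf_correlation(x, y) > 100

    def test_symmetric_in_arguments(self, rng):
        x = rng.standard_normal(40)
        y = 0.4 * x + rng.standard_normal(40)
        assert jzs_bf_correlation(x, y) == pytest.approx(jzs_bf_correlation(y, x), rel=1e-9)

    def test_monotone_in_observed_correlation(self):
        bfs = [bf10_from_r(r, 60) for r in (0.0, 0.1, 0.2, 0.35, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(bfs) > 0)

    def test_matches_grid_integration_oracle(self):
        # same integrand evaluated on a dense fixed grid instead of
        # adaptive quadrature
        from scipy.special import betaln, gammaln, hyp2f1

        def log_density(r, rho, n):
            return (
                np.log(n - 2) + gammaln(n - 1) - 0.5 * np.log(2 * np.pi)
                - gammaln(n - 0.5) + 0.5 * (n - 1) * np.log1p(-(rho**2))
                + 0.5 * (n - 4) * np.log1p(-(r**2)) - (n - 1.5) * np.log1p(-rho * r)
                + np.log(hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (rho * r + 1.0)))
            )

        a = 3.0
        rho = np.linspace(-1 + 1e-9, 1 - 1e-9, 40001)
        log_prior = (a - 1) * (np.log1p(rho) + np.log1p(-rho)) - betaln(a, a) - (2 * a - 1) * np.log(2)
        for r, n in [(0.1, 30), (0.4, 58), (-0.5, 25)]:
            numer = np.trapezoid(np.exp(log_density(r, rho, n) + log_prior), rho)
            oracle = numer / np.exp(log_density(r, 0.0, n))
            assert bf10_from_r(r, n) == pytest.approx(oracle, rel=1e-5)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        for r, n in [(0.33, 58), (-0.29, 40), (0.05, 100)]:
            ref = float(pg.bayesfactor_pearson(r, n, method="ly", kappa=1 / 3))
            assert bf10_from_r(r, n) == pytest.approx(ref, rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            jzs_bf_correlation(np.ones(10), np.arange(10.0))


class TestGrubbsTrim:
    def test_clean_sample_unchanged(self, rng):
        # seeded sample whose Grubbs statistic stays below the .01 cutoff
        x = np.random.default_rng(12).normal(0.6, 0.05, 50)
        assert len(grubbs_trim(x)) == 50

    def test_single_gross_outlier_removed(self, rng):
        x = np.random.default_rng(12).normal(0.6, 0.05, 50)
        with_outlier = np.insert(x, 17, 10.0)
        trimmed = grubbs_trim(with_outlier)
        assert len(trimmed) == 50
        assert 10.0 not in trimmed
        # survivors keep their order
        assert np.array_equal(trimmed, x)

    def test_critical_value_oracle(self):
        # boundary behaviour around the published critical-value formula:
        # a point just beyond the two-sided .01 cutoff is removed, one just
        # inside is kept
        from scipy.stats import t as t_dist

        n, alpha = 30, 0.01
        tcrit = t_dist.ppf(1 - alpha / (2 * n), n - 2)
        gcrit = (n - 1) / np.sqrt(n) * np.sqrt(tcrit**2 / (n - 2 + tcrit**2))
        base = np.random.default_rng(5).normal(0, 1.0, n - 1)
        for factor, expect_removed in ((1.25, True), (0.5, False)):
            x = np.concatenate([base, [base.mean() + factor * gcrit * base.std(ddof=1) * 2.2]])
            g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
            removed = len(grubbs_trim(x, alpha)) < n
            assert removed == (g > gcrit)

    def test_idempotent(self, rng):
        x = rng.normal(0.5, 0.1, 60)
        x[5] = 4.0
        once = grubbs_trim(x)
        assert np.array_equal(grubbs_trim(once), once)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            grubbs_trim(np.array([1.0, 2.0]))


class TestStayShift:
    def test_constant_chooser_all_stays(self, session_behavior):
        behav = session_behavior.assign(choice=1)
        s = stay_shift_counts(behav)[0]
        assert s.win_shift == 0 and s.lose_shift == 0
        assert s.win_stay + s.lose_stay == 300

    def test_counts_conserved_and_phases_sum(self, session_behavior):
        s = stay_shift_counts(session_behavior)[0]
        assert s.total == 300
        for key in ("win_stay", "win_shift", "lose_stay", "lose_shift"):
            assert s.early[key] + s.late[key] == getattr(s, key)
        assert sum(s.early.values()) == 7 * 20
        assert sum(s.late.values()) == 8 * 20

    def test_incomplete_games_excluded(self, session_behavior):
        partial = session_behavior.iloc[:-6]  # last game truncated
        s = stay_shift_counts(partial)[0]
        assert s.n_complete_games == 19
        assert s.total == 15 * 19


class TestPrediction:
    def test_independent_outcome_small_r(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        row = predictive_correlation(x, y)
        assert abs(row["r"]) < 0.3
        assert row["bf10"] < 1

    def test_single_covariate_equals_partial_correlation_identity(self, rng):
        # residualizing both sides on one covariate gives the closed-form
        # partial correlation
        z = rng.standard_normal(80)
        x = 0.5 * z + rng.standard_normal(80)
        y = 0.4 * z + 0.3 * x + rng.standard_normal(80)
        row = predictive_correlation(x, y, covariates=z, partial_both=True)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        partial = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert row["r"] == pytest.approx(partial, abs=1e-10)

    def test_bonferroni_flags_use_printed_thresholds(self, rng):
        x = rng.standard_normal(200)
        y = 0.5 * x + rng.standard_normal(200)
        row = predictive_correlation(x, y)
        assert row["sig_bonferroni_6"] == (row["p"] < 0.05 / 6)
        assert row["sig_bonferroni_30"] == (row["p"] < 0.05 / 30)

    def test_planted_predictive_correlation_recovered(self):
        # plant r = .4 between baseline loss learning rate and follow-up
        # DAST in the stimulant stratum; recover the adjusted correlation
        # across replicates at roughly the published subsample size
        rs = []
        for rep in range(60):
            spec = CohortSpec(n_hc=2, n_sud=80, simulate_behavior=False, seed=900 + rep)
            spec = plant_effect(
                spec,
                {"kind": "symptom_corr", "param": "eta_loss", "r": 0.4, "stratum": "stimulant"},
            )
            study = generate_cohort(spec)
            clin = study.clinical
            truth = study.truth
            base = truth[truth.session == "baseline"].set_index("subject_id")
            sub = clin[(clin.group == "sud") & clin.stimulant]
            x = base.loc[sub.subject_id, "eta_loss_est"].to_numpy()
            y = sub.dast_followup.to_numpy(dtype=float)
            cov = sub[["age", "sex_male", "wrat"]].to_numpy(dtype=float)
            rs.append(predictive_correlation(x, y, covariates=cov)["r"])
        assert np.mean(rs) == pytest.approx(0.4, abs=0.15)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            predictive_correlation(rng.standard_normal(4), rng.standard_normal(4))


class TestChangeScores:
    def test_constant_dast_change_is_error_not_nan(self, rng):
        n = 30
        pre = rng.standard_normal(n)
        post = pre + rng.standard_normal(n)
        dast = rng.integers(1, 10, n).astype(float)
        with pytest.raises(ValueError, match="constant"):
            change_score_analysis(pre, post, dast, dast)

    def test_floor_subjects_excluded_exactly(self, rng):
        n = 40
        pre = rng.standard_normal(n)
        post = pre + 0.3 * rng.standard_normal(n)
        dast_pre = rng.integers(1, 10, n).astype(float)
        dast_pre[:6] = 0.0
        dast_post = np.maximum(dast_pre - rng.integers(0, 4, n), 0).astype(float)
        dast_post[6:10] += 1
        row = change_score_analysis(pre, post, dast_pre, dast_post)
        assert row["n_floor_excluded"] == 6
        assert row["n"] == n - 6

    def test_planted_delta_correlation_recovered(self):
        # plant r = -.29 between parameter change and DAST change in an
        # opioid-like stratum and recover it across replicates
        rs = []
        for rep in range(60):
            spec = CohortSpec(n_hc=2, n_sud=120, simulate_behavior=False, seed=1300 + rep)
            spec = plant_effect(
                spec,
                {"kind": "delta_corr", "param": "alpha", "r": -0.29, "stratum": "opioid"},
            )
            study = generate_cohort(spec)
            clin = study.clinical
            truth = study.truth
            wide = truth.pivot_table(index="subject_id", columns="session", values="alpha_est")
            sub = clin[(clin.group == "sud") & clin.opioid & (clin.dast_baseline > 0)]
            ids = sub.subject_id
            row = change_score_analysis(
                wide.loc[ids, "baseline"].to_numpy(),
                wide.loc[ids, "followup"].to_numpy(),
                sub.dast_baseline.to_numpy(dtype=float),
                sub.dast_followup.to_numpy(dtype=float),
                covariates=sub[["age", "sex_male", "wrat"]].to_numpy(dtype=float),
            )
            rs.append(row["r"])
        assert np.mean(rs) == pytest.approx(-0.29, abs=0.15)
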