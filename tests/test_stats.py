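import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from hapticdyad import stats as hs
from conftest import make_lme_dataset

IMP_BETA = (0.1, 0.2, 0.08, -0.05, 0.15, 0.02)
EFF_BETA = (-0.05, -0.12, 0.07, -0.15)


class TestLmeFits:
    def test_improvement_coefficient_recovery(self):
        df = make_lme_dataset(IMP_BETA, seed=1)
        fit = hs.fit_improvement_lme(df)
        se = fit.result.bse_fe
        names = ["Intercept", "delta_p", "kappa", "delta_p2",
                 "delta_p_kappa", "delta_p2_kappa"]
        for name, true in zip(names, IMP_BETA):
            assert abs(fit.coef(name) - true) < 2.5 * se[name]

    def test_effort_coefficient_recovery(self):
        df = make_lme_dataset(EFF_BETA, seed=2, effort_model=True)
        fit = hs.fit_effort_lme(df)
        se = fit.result.bse_fe
        names = ["Intercept", "delta_p", "kappa", "delta_p_kappa"]
        for name, true in zip(names, EFF_BETA):
            assert abs(fit.coef(name) - true) < 2.5 * se[name]

    def test_reduced_model_term_counts(self):
        df = make_lme_dataset(IMP_BETA, seed=3)
        full = hs.fit_improvement_lme(df)
        red = hs.fit_improvement_lme(df, include_stiffness=False)
        assert full.n_params - red.n_params == 3
        full_e = hs.fit_effort_lme(df)
        red_e = hs.fit_effort_lme(df, include_stiffness=False)
        assert full_e.n_params - red_e.n_params == 2

    def test_single_stiffness_degenerate(self):
        df = make_lme_dataset(IMP_BETA, seed=4)
        df["kappa"] = 0.23
        with pytest.raises(ValueError):
            hs.fit_improvement_lme(df, include_stiffness=True)

    def test_ml_not_reml_for_lrt_fits(self):
        df = make_lme_dataset(IMP_BETA, seed=5)
        ml = hs.fit_improvement_lme(df, reml=False)
        reml = hs.fit_improvement_lme(df, reml=True)
        assert ml.loglik != pytest.approx(reml.loglik)


class TestLrt:
    def test_identical_models_statistic_zero(self):
        df = make_lme_dataset(IMP_BETA, seed=6)
        fit = hs.fit_improvement_lme(df)
        rep = hs.likelihood_ratio_test(fit, fit)
        assert rep.statistic == 0.0 and rep.p_value == 1.0

    def test_matches_brute_force_refit(self):
        """The statistic must equal 2*(ll_full - ll_reduced) from models
        refit directly with the underlying mixed-model API."""
        df = make_lme_dataset(IMP_BETA, seed=7)
        full = hs.fit_improvement_lme(df)
        red = hs.fit_improvement_lme(df, include_stiffness=False)
        rep = hs.likelihood_ratio_test(full, red)
        d = df.copy()
        d["delta_p2"] = d.delta_p ** 2
        d["delta_p_kappa"] = d.delta_p * d.kappa
        d["delta_p2_kappa"] = d.delta_p ** 2 * d.kappa
        r1 = smf.mixedlm("delta_c ~ delta_p + kappa + delta_p2 + "
                         "delta_p_kappa + delta_p2_kappa", d,
                         groups=d.dyad).fit(reml=False)
        r0 = smf.mixedlm("delta_c ~ delta_p + delta_p2", d,
                         groups=d.dyad).fit(reml=False)
        assert rep.statistic == pytest.approx(2 * (r1.llf - r0.llf), abs=1e-4)

    def test_detects_planted_stiffness_effect(self):
        df = make_lme_dataset(IMP_BETA, seed=8)
        rep = hs.likelihood_ratio_test(
            hs.fit_improvement_lme(df),
            hs.fit_improvement_lme(df, include_stiffness=False))
        assert rep.p_value < 1e-6 and rep.df == (3,)

    def test_rejects_non_nested(self):
        df = make_lme_dataset(IMP_BETA, seed=9)
        imp_red = hs.fit_improvement_lme(df, include_stiffness=False)
        eff_full = hs.fit_effort_lme(df)
        with pytest.raises(ValueError):
            hs.likelihood_ratio_test(imp_red, eff_full)

    def test_type_one_error_near_nominal(self):
        """Under a null with no stiffness terms the 3-df LRT should reject
        at about the nominal 5% rate (quick 60-dataset check; the full
        calibration runs in the acceptance suite)."""
        null_beta = (0.1, 0.2, 0.0, -0.05, 0.0, 0.0)
        rejections = 0
        n = 60
        for s in range(n):
            df = make_lme_dataset(null_beta, n_dyads=10, pairs_per_dyad=12,
                                  seed=1000 + s)
            rep = hs.likelihood_ratio_test(
                hs.fit_improvement_lme(df),
                hs.fit_improvement_lme(df, include_stiffness=False))
            rejections += rep.p_value < 0.05
        assert rejections <= 10  # 99.9% binomial bound for p=0.05, n=60


def toy_means():
    """3-dyad toy table for the hand-computed ANOVA decomposition."""
    rows = []
    vals = {
        (1, "better"): [1.0, 2.0, 3.0], (1, "worse"): [2.0, 4.0, 6.0],
        (2, "better"): [1.5, 2.5, 3.5], (2, "worse"): [2.5, 4.5, 6.5],
        (3, "better"): [0.5, 1.5, 2.5], (3, "worse"): [1.5, 3.5, 5.5],
    }
    for (dyad, role), v in vals.items():
        for lev, x in zip(["soft", "medium", "hard"], v):
            rows.append({"dyad": dyad, "role": role, "block_level": lev,
                         "value": x})
    return pd.DataFrame(rows)


class TestAnova:
    def test_identical_cells_give_zero_f(self):
        rows = [{"dyad": d, "role": r, "block_level": lev, "value": 1.0}
                for d in (1, 2, 3) for r in ("better", "worse")
                for lev in ("soft", "medium", "hard")]
        df = pd.DataFrame(rows)
        reports = hs.rm_anova(df, "value")
        for rep in reports:
            assert rep.statistic == pytest.approx(0.0, abs=1e-10) or \
                np.isnan(rep.statistic)

    def test_interaction_f_matches_hand_decomposition(self):
        """Two-factor repeated-measures decomposition computed by hand on
        the toy table (role x stiffness, 3 dyads)."""
        df = toy_means()
        y = df.pivot_table(index="dyad", columns=["role", "block_level"],
                           values="value")
        arr = np.stack([
            y[("better", "soft")], y[("better", "medium")],
            y[("better", "hard")],
            y[("worse", "soft")], y[("worse", "medium")],
            y[("worse", "hard")]]).T  # (3 dyads, 6 cells)
        n, a, b = 3, 2, 3
        cells = arr.reshape(n, a, b)
        grand = cells.mean()
        m_ab = cells.mean(axis=0)
        m_a = cells.mean(axis=(0, 2))
        m_b = cells.mean(axis=(0, 1))
        ss_inter = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
        m_sab = cells  # per-subject cell values
        m_s = cells.mean(axis=(1, 2))
        # error term for the interaction: subject x A x B residual
        resid = (m_sab - m_ab[None] - cells.mean(axis=2)[:, :, None]
                 - cells.mean(axis=1)[:, None, :] + m_a[None, :, None]
                 + m_b[None, None, :] + m_s[:, None, None] - grand)
        ss_err = np.sum(resid ** 2)
        df_inter = (a - 1) * (b - 1)
        df_err = (n - 1) * (a - 1) * (b - 1)
        f_hand = (ss_inter / df_inter) / (ss_err / df_err)
        reports = hs.rm_anova(df, "value")
        inter = [r for r in reports if "*" in r.name or
                 ("role" in r.name and "block_level" in r.name)]
        assert inter, f"no interaction row in {[r.name for r in reports]}"
        assert inter[0].statistic == pytest.approx(f_hand, rel=1e-6)

    def test_mauchly_reports_chi2_with_2_df(self, populations):
        means = hs.dyad_means(populations["neuromechanical"], "E")
        rep = hs.mauchly_sphericity(means, "E")
        assert rep.df == (2,)
        assert np.isfinite(rep.statistic)


class TestPosthoc:
    def test_all_zero_efforts_give_zero_t(self):
        rows = [{"dyad": d, "role": r, "block_level": lev, "E": 0.0}
                for d in range(1, 6) for r in ("better", "worse")
                for lev in ("soft", "medium", "hard")]
        reports = hs.posthoc_and_ttests(pd.DataFrame(rows), "E")
        ts = [r for r in reports if r.name.startswith("ttest")]
        assert all(r.statistic == 0.0 or np.isnan(r.statistic) for r in ts)

    def test_t_statistic_equals_mean_over_se(self):
        rng = np.random.default_rng(0)
        rows = []
        for d in range(1, 9):
            for r in ("better", "worse"):
                for lev in ("soft", "medium", "hard"):
                    rows.append({"dyad": d, "role": r, "block_level": lev,
                                 "E": rng.normal(0.2, 0.1)})
        df = pd.DataFrame(rows)
        reports = hs.posthoc_and_ttests(df, "E")
        rep = [r for r in reports
               if r.name == "ttest[E] better hard vs 0"][0]
        cell = df[(df.role == "better") & (df.block_level == "hard")]["E"]
        t_hand = cell.mean() / (cell.std(ddof=1) / np.sqrt(len(cell)))
        assert rep.statistic == pytest.approx(t_hand, rel=1e-10)
        assert rep.df == (len(cell) - 1,)

    def test_refuses_tiny_cells(self):
        rows = [{"dyad": d, "role": r, "block_level": lev, "E": 0.1}
                for d in (1, 2) for r in ("better", "worse")
                for lev in ("soft", "medium", "hard")]
        with pytest.raises(ValueError):
            hs.posthoc_and_ttests(pd.DataFrame(rows), "E")


class TestRolesAndCurves:
    def test_roles_are_dyad_level_and_exclusive(self, populations):
        d = hs.assign_roles(populations["neuromechanical"])
        per_dyad = d.groupby("dyad")["role"].nunique()
        assert (per_dyad == 2).all()
        per_subj = d.groupby(["dyad", "subject"])["role"].nunique()
        assert (per_subj == 1).all()

    def test_predicted_curves_match_coefficients(self):
        df = make_lme_dataset(IMP_BETA, seed=11)
        fit = hs.fit_improvement_lme(df)
        grid = np.linspace(-0.5, 0.5, 7)
        kappa = np.log10(1.7)
        manual = (fit.coef("Intercept") + fit.coef("delta_p") * grid
                  + fit.coef("kappa") * kappa
                  + fit.coef("delta_p2") * grid ** 2
                  + fit.coef("delta_p_kappa") * grid * kappa
                  + fit.coef("delta_p2_kappa") * grid ** 2 * kappa)
        assert np.allclose(hs.predict_curves(fit, grid, kappa), manual)
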