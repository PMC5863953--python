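"""The statistical pipeline: mixed-effects fits of the improvement and
effort models, likelihood-ratio model comparisons, repeated-measures ANOVA
with sphericity handling, Tukey-Kramer post-hocs and Bonferroni one-sample
t-tests.

Model definitions (kappa = log10 of the coupling stiffness, dyad-level
random intercept rho):

  improvement:  Dc ~ 1 + Dp + kappa + Dp^2 + Dp:kappa + Dp^2:kappa + (1|dyad)
  effort:       E  ~ 1 + Dp + kappa + Dp:kappa                     + (1|dyad)

Fits entering a likelihood-ratio test are always by maximum likelihood
(never REML).  The full random-slope structure the beta-subscripts suggest
is not estimable on 14 dyads; a random intercept (optionally plus a Dp
slope) is used and recorded on the fit object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "LmeFit",
    "TestReport",
    "fit_improvement_lme",
    "fit_effort_lme",
    "likelihood_ratio_test",
    "rm_anova",
    "mauchly_sphericity",
    "posthoc_and_ttests",
    "predict_curves",
]

IMPROVEMENT_TERMS = ("delta_p", "kappa", "delta_p2", "delta_p_kappa",
                     "delta_p2_kappa")
EFFORT_TERMS = ("delta_p", "kappa", "delta_p_kappa")


@dataclass
class LmeFit:
    """A fitted mixed-effects model plus everything an LRT needs."""

    outcome: str
    terms: tuple
    params: pd.Series
    loglik: float
    n_params: int
    n_obs: int
    random_structure: str
    converged: bool
    result: object = field(repr=False, default=None)

    def coef(self, name: str) -> float:
        return float(self.params[name])


@dataclass(frozen=True)
class TestReport:
    name: str
    statistic: float
    df: tuple
    p_value: float
    correction: str = "none"

    def to_dict(self) -> dict:
        return {"name": self.name, "statistic": float(self.statistic),
                "df": list(self.df), "p": float(self.p_value),
                "correction": self.correction}


def _design(df: pd.DataFrame) -> pd.DataFrame:
    d = df.copy()
    d["delta_p2"] = d["delta_p"] ** 2
    d["delta_p_kappa"] = d["delta_p"] * d["kappa"]
    d["delta_p2_kappa"] = d["delta_p"] ** 2 * d["kappa"]
    return d


def _fit_lme(df: pd.DataFrame, outcome: str, terms: tuple,
             random_slope: bool = False, reml: bool = False) -> LmeFit:
    d = _design(df)
    needed = {outcome, "dyad", *terms}
    missing = needed - set(d.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for t in terms:
        if d[t].nunique() <= 1:
            raise ValueError(f"degenerate predictor {t!r}: constant column")
    rank = np.linalg.matrix_rank(np.column_stack(
        [np.ones(len(d))] + [d[t].to_numpy() for t in terms]))
    if rank < len(terms) + 1:
        raise ValueError(f"rank-deficient design over terms {terms}")
    formula = f"{outcome} ~ " + " + ".join(terms) if terms else f"{outcome} ~ 1"
    kwargs = {"groups": d["dyad"]}
    if random_slope:
        kwargs["re_formula"] = "~delta_p"
    model = smf.mixedlm(formula, d, **kwargs)
    import warnings as _w
    with _w.catch_warnings():
        # boundary/singular random-effects warnings are routine for
        # small-variance intercepts; the LRT only needs the ML log-likelihood
        _w.simplefilter("ignore")
        res = None
        last = None
        for method in (None, "powell", "nm"):
            try:
                kw = {} if method is None else {"method": method}
                res = model.fit(reml=reml, maxiter=300, disp=False, **kw)
                break
            except np.linalg.LinAlgError as e:
                # singular Hessian at a variance boundary; retry with a
                # derivative-free optimizer
                last = e
        if res is None:
            raise RuntimeError(f"mixed-model fit failed: {last}")
    n_fe = len(res.fe_params)
    n_re = res.cov_re.shape[0] * (res.cov_re.shape[0] + 1) // 2 + 1
    return LmeFit(outcome=outcome, terms=terms, params=res.fe_params,
                  loglik=float(res.llf), n_params=n_fe + n_re,
                  n_obs=int(res.nobs),
                  random_structure=("intercept+delta_p slope" if random_slope
                                    else "intercept"),
                  converged=bool(res.converged), result=res)


def fit_improvement_lme(df: pd.DataFrame, include_stiffness: bool = True,
                        drop_delta_p: bool = False,
                        random_slope: bool = False,
                        reml: bool = False) -> LmeFit:
    """Fit the improvement model; without ``include_stiffness`` all three
    kappa-containing terms are dropped (the reduced model of the 3-df LRT)."""
    terms = IMPROVEMENT_TERMS
    if not include_stiffness:
        terms = tuple(t for t in terms if "kappa" not in t)
    if drop_delta_p:
        terms = tuple(t for t in terms if t != "delta_p")
    return _fit_lme(df, "delta_c", terms, random_slope, reml)


def fit_effort_lme(df: pd.DataFrame, include_stiffness: bool = True,
                   drop_delta_p: bool = False,
                   random_slope: bool = False, reml: bool = False) -> LmeFit:
    """Fit the effort model; without ``include_stiffness`` both
    kappa-containing terms are dropped (the 2-df LRT)."""
    terms = EFFORT_TERMS
    if not include_stiffness:
        terms = tuple(t for t in terms if "kappa" not in t)
    if drop_delta_p:
        terms = tuple(t for t in terms if t != "delta_p")
    return _fit_lme(df, "E", terms, random_slope, reml)


def fit_order_effect_lme(df: pd.DataFrame, outcome: str = "delta_c") -> tuple:
    """Order-effect control: replace kappa by the categorical block order.

    Returns (full fit with order terms, reduced fit without) for the LRT.
    """
    d = _design(df)
    if "order" not in d.columns:
        raise ValueError("order column required for the order-effect test")
    d["order_c"] = d["order"].astype(float)
    if outcome == "delta_c":
        terms_f = ("delta_p", "order_c", "delta_p2", "delta_p_order",
                   "delta_p2_order")
        d["delta_p_order"] = d["delta_p"] * d["order_c"]
        d["delta_p2_order"] = d["delta_p2"] * d["order_c"]
        terms_r = ("delta_p", "delta_p2")
    else:
        terms_f = ("delta_p", "order_c", "delta_p_order")
        d["delta_p_order"] = d["delta_p"] * d["order_c"]
        terms_r = ("delta_p",)
    full = _fit_lme(d, outcome, terms_f)
    red = _fit_lme(d, outcome, terms_r)
    return full, red


def likelihood_ratio_test(full: LmeFit, reduced: LmeFit,
                          name: str = "LRT") -> TestReport:
    """2 (ll_full - ll_reduced) against the chi^2 with df = parameter
    difference.  The reduced model must be nested in the full one."""
    if not set(reduced.terms).issubset(set(full.terms)):
        raise ValueError(f"models are not nested: {reduced.terms} vs "
                         f"{full.terms}")
    if reduced.n_obs != full.n_obs:
        raise ValueError("models were fitted on different rows")
    df = full.n_params - reduced.n_params
    if df == 0 and set(reduced.terms) == set(full.terms):
        return TestReport(name=name, statistic=0.0, df=(0,), p_value=1.0)
    if df <= 0:
        raise ValueError("full model has no extra parameters")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(sps.chi2.sf(stat, df))
    return TestReport(name=name, statistic=stat, df=(df,), p_value=p)


def assign_roles(df: pd.DataFrame) -> pd.DataFrame:
    """Label each subject better/worse within its dyad.

    The worse partner is the subject with the larger mean relative error
    across the whole session (Dp > 0 identifies the worse partner of a
    pair); the label is constant within a dyad, as in the dyad-level
    analyses."""
    d = df.copy()
    mean_dp = d.groupby(["dyad", "subject"])["delta_p"].transform("mean")
    d["role"] = np.where(mean_dp > 0, "worse", "better")
    # guard: both subjects of a dyad must not share a role
    chk = d.groupby("dyad")["role"].nunique()
    bad = chk[chk < 2].index
    if len(bad):
        # exactly-tied dyads: break the tie by subject id
        m = d["dyad"].isin(bad)
        d.loc[m, "role"] = np.where(d.loc[m, "subject"]
                                    == d.loc[m, "subject"].min(),
                                    "better", "worse")
    return d


def dyad_means(df: pd.DataFrame, value: str = "delta_c") -> pd.DataFrame:
    """Mean of ``value`` per dyad x role (better/worse partner) x stiffness,
    with dyad-level role assignment."""
    d = assign_roles(df)
    g = (d.groupby(["dyad", "role", "block_level"])[value]
          .mean().reset_index())
    return g


def rm_anova(means: pd.DataFrame, value: str) -> list[TestReport]:
    """Two-way repeated-measures ANOVA (role x stiffness within dyad).

    Dyads with missing cells are excluded listwise.  Sphericity of the
    stiffness factor is assessed with Mauchly's test; the stiffness effects
    carry a Greenhouse-Geisser correction when it rejects.
    """
    wide = means.pivot_table(index="dyad", columns=["role", "block_level"],
                             values=value)
    complete = wide.dropna()
    if len(complete) < 3:
        raise ValueError("fewer than 3 complete dyads")
    keep = complete.index
    d = means[means["dyad"].isin(keep)]
    aov = pg.rm_anova(data=d, dv=value, within=["role", "block_level"],
                      subject="dyad", correction=True, detailed=True)
    p_unc = "p_unc" if "p_unc" in aov.columns else "p-unc"
    p_gg = "p_GG_corr" if "p_GG_corr" in aov.columns else "p-GG-corr"
    reports = []
    for _, row in aov.iterrows():
        label = str(row["Source"])
        use_gg = ("block_level" in label and p_gg in aov.columns
                  and np.isfinite(row.get(p_gg, np.nan)))
        p = float(row[p_gg]) if use_gg else float(row[p_unc])
        reports.append(TestReport(
            name=f"rm_anova[{value}] {label}",
            statistic=float(row["F"]),
            df=(float(row["ddof1"]), float(row["ddof2"])),
            p_value=p,
            correction="greenhouse-geisser" if use_gg else "none"))
    return reports


def mauchly_sphericity(means: pd.DataFrame, value: str) -> TestReport:
    """Mauchly's test of sphericity over the three stiffness levels
    (dyad means pooled over roles)."""
    pooled = (means.groupby(["dyad", "block_level"])[value]
                   .mean().reset_index())
    sph = pg.sphericity(data=pooled, dv=value, within="block_level",
                        subject="dyad")
    return TestReport(name=f"mauchly[{value}]", statistic=float(sph.chi2),
                      df=(2,), p_value=float(sph.pval),
                      correction="chi2 approximation")


def posthoc_and_ttests(means: pd.DataFrame, value: str = "E",
                       alpha: float = 0.05) -> list[TestReport]:
    """Tukey-Kramer pairwise stiffness comparisons within each role, plus
    the six Bonferroni-corrected one-sample t-tests of mean interaction
    effort against zero (2 roles x 3 stiffness levels, alpha/6)."""
    reports = []
    levels = ["soft", "medium", "hard"]
    for role, g in means.groupby("role"):
        cells = [g.loc[g["block_level"] == lev, value].to_numpy()
                 for lev in levels]
        if min(len(c) for c in cells) < 3:
            raise ValueError(f"fewer than 3 dyads in a cell for role {role}")
        tk = sps.tukey_hsd(*cells)
        for i in range(3):
            for j in range(i + 1, 3):
                reports.append(TestReport(
                    name=f"tukey[{value}] {role}: {levels[i]} vs {levels[j]}",
                    statistic=float(tk.statistic[i, j]),
                    df=(len(cells[i]) + len(cells[j]) - 2,),
                    p_value=float(tk.pvalue[i, j]),
                    correction="tukey-kramer"))
        for lev, cell in zip(levels, cells):
            t = sps.ttest_1samp(cell, 0.0)
            reports.append(TestReport(
                name=f"ttest[{value}] {role} {lev} vs 0",
                statistic=float(t.statistic), df=(len(cell) - 1,),
                p_value=float(t.pvalue),
                correction=f"bonferroni alpha={alpha}/6"))
    return reports


def predict_curves(fit: LmeFit, delta_p_grid: np.ndarray,
                   kappa: float) -> np.ndarray:
    """Fixed-effect prediction of the fitted curve at one stiffness level."""
    b = fit.params
    y = np.full_like(delta_p_grid, float(b.get("Intercept", 0.0)))
    term_values = {
        "delta_p": delta_p_grid,
        "kappa": np.full_like(delta_p_grid, kappa),
        "delta_p2": delta_p_grid ** 2,
        "delta_p_kappa": delta_p_grid * kappa,
        "delta_p2_kappa": delta_p_grid ** 2 * kappa,
    }
    for t in fit.terms:
        y = y + float(b[t]) * term_values[t]
    return y
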