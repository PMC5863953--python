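"""Orchestration: synthetic populations, the q x sigma_mu^2 sensitivity
grid, model-vs-reference deviation scores, qualitative trend summaries, and
the end-to-end reproduction manifest.

The *reference curves* stand in for the empirical mixed-effects fits when no
trial-pair data file is supplied.  They are SYNTHETIC stylized curves
encoding the experiment's reported pattern — worse-partner improvement
graded by the log-stiffness, better-partner improvement flat, better-partner
interaction effort positive and graded at medium/hard coupling — on the
published axis scales.  They are constants of this package, not measured
data.
"""

from __future__ import annotations

from dataclasses import dataclass
import hashlib
import json
import time

import numpy as np
import pandas as pd

from .config import STIFFNESS, SimConfig
from .metrics import outcomes_frame
from .protocol import generate_target
from .strategies import (AgentSpec, HapticNoiseModel, STRATEGIES,
                         calibrate_haptic_noise, run_solo)
from .synthetic_data import (generate_dyad_dataset, read_s1, read_s2,
                             s1_to_outcomes, _derive_seed)
from . import stats as hstats

__all__ = [
    "StylizedReference",
    "REFERENCE",
    "population_outcomes",
    "fit_population_curves",
    "deviation_scores",
    "run_sensitivity",
    "trend_summary",
    "reproduce",
]

KAPPAS = {lev: np.log10(k) for lev, k in STIFFNESS.items()}
DELTA_P_GRID = np.linspace(-0.6, 0.6, 25)


@dataclass(frozen=True)
class StylizedReference:
    """Synthetic stand-in for the empirical fitted curves (see module doc).

    improvement: Dc = b0 + b1 Dp + b2 k + b4 Dp k
    effort:      E  = c0 + c1 Dp + c2 k + c3 Dp k
    """

    improvement_beta: tuple = (0.13, 0.16, 0.085, 0.0, 0.17, 0.0)
    effort_beta: tuple = (-0.07, -0.14, 0.085, -0.17)

    def improvement_curve(self, dp: np.ndarray, kappa: float) -> np.ndarray:
        b = self.improvement_beta
        return (b[0] + b[1] * dp + b[2] * kappa + b[3] * dp ** 2
                + b[4] * dp * kappa + b[5] * dp ** 2 * kappa)

    def effort_curve(self, dp: np.ndarray, kappa: float) -> np.ndarray:
        c = self.effort_beta
        return c[0] + c[1] * dp + c[2] * kappa + c[3] * dp * kappa


REFERENCE = StylizedReference()


def population_outcomes(strategy: str, n_dyads: int, seed: int,
                        cfg: SimConfig | None = None,
                        haptic_noise: HapticNoiseModel | None = None,
                        n_per_block: int = 15) -> pd.DataFrame:
    """Simulate a synthetic population and return the analysis frame."""
    table = generate_dyad_dataset(n_dyads, strategy, seed, cfg=cfg,
                                  haptic_noise=haptic_noise,
                                  n_per_block=n_per_block)
    return s1_to_outcomes(table)


def _ols(df: pd.DataFrame, outcome: str, quadratic: bool) -> np.ndarray:
    dp = df["delta_p"].to_numpy()
    k = df["kappa"].to_numpy()
    cols = [np.ones_like(dp), dp, k]
    if quadratic:
        cols += [dp ** 2, dp * k, dp ** 2 * k]
    else:
        cols += [dp * k]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, df[outcome].to_numpy(), rcond=None)
    return beta


def fit_population_curves(df: pd.DataFrame) -> dict:
    """Population-level (fixed-effect) curve fits of the improvement and
    effort models, by least squares.  The formal mixed-effects fits live in
    :mod:`hapticdyad.stats`; for deviation scoring of balanced synthetic
    populations the pooled fit is equivalent and unconditionally stable."""
    return {"improvement": _ols(df, "delta_c", quadratic=True),
            "effort": _ols(df, "E", quadratic=False)}


def _eval_curves(beta: np.ndarray, dp: np.ndarray, kappa: float,
                 quadratic: bool) -> np.ndarray:
    if quadratic:
        return (beta[0] + beta[1] * dp + beta[2] * kappa + beta[3] * dp ** 2
                + beta[4] * dp * kappa + beta[5] * dp ** 2 * kappa)
    return beta[0] + beta[1] * dp + beta[2] * kappa + beta[3] * dp * kappa


def deviation_scores(df: pd.DataFrame,
                     reference: StylizedReference = REFERENCE) -> dict:
    """MAE and RMSE between the population's fitted improvement/effort
    curves and the reference curves, on a common Dp grid across the three
    stiffness levels."""
    fits = fit_population_curves(df)
    devs = []
    for kappa in KAPPAS.values():
        mi = _eval_curves(fits["improvement"], DELTA_P_GRID, kappa, True)
        me = _eval_curves(fits["effort"], DELTA_P_GRID, kappa, False)
        devs.append(mi - reference.improvement_curve(DELTA_P_GRID, kappa))
        devs.append(me - reference.effort_curve(DELTA_P_GRID, kappa))
    d = np.concatenate(devs)
    return {"mae": float(np.mean(np.abs(d))),
            "rmse": float(np.sqrt(np.mean(d ** 2)))}


def rms_jerk(cfg: SimConfig, seed: int = 0) -> float:
    """RMS jerk (rad/s^3) of a solo wrist trajectory under ``cfg`` — the
    smoothness guard of the sensitivity sweep."""
    agent = AgentSpec(subject_id=0, visual_noise_deg=2.0, config=cfg)
    traj = generate_target(cfg.duration, cfg.dt, seed=seed)
    r = run_solo(agent, traj, seed)
    acc = np.gradient(np.gradient(r.wrist, cfg.dt), cfg.dt)
    jerk = np.gradient(acc, cfg.dt)
    return float(np.sqrt(np.mean(jerk ** 2)))


def run_sensitivity(strategies=STRATEGIES,
                    q_values=(0.25, 1.0, 4.0),
                    sigma_mu2_values=(0.005, 0.02, 0.08),
                    n_dyads: int = 8, seeds=(0, 1, 2, 3),
                    cfg: SimConfig | None = None,
                    reference: StylizedReference = REFERENCE,
                    n_per_block: int = 5,
                    jerk_ceiling: float = 3.0) -> pd.DataFrame:
    """Deviation scores over the (q, sigma_mu^2) grid for each strategy.

    Per cell and seed, a small synthetic population is simulated with the
    SAME seeds across strategies (paired comparison), its curves fitted and
    scored against the reference.  Cells whose solo trajectories exceed the
    jerk ceiling, or whose controller is unstable, are marked unscored.
    """
    base = cfg or SimConfig()
    rows = []
    for q in q_values:
        for s2 in sigma_mu2_values:
            cell_cfg = SimConfig(**{**base.__dict__, "q": float(q),
                                    "sigma_mu2": float(s2)})
            try:
                jerk = rms_jerk(cell_cfg)
                ok = jerk <= jerk_ceiling
            except ValueError:
                jerk, ok = np.nan, False
            if not ok:
                for strat in strategies:
                    rows.append({"strategy": strat, "q": q, "sigma_mu2": s2,
                                 "mae": np.nan, "rmse": np.nan,
                                 "rms_jerk": jerk, "scored": False})
                continue
            table = calibrate_haptic_noise(cell_cfg, n_seeds=3, seed=11)
            hn = HapticNoiseModel(partner_visual_var=0.0,
                                  stiffness_noise=table)
            for strat in strategies:
                maes, rmses = [], []
                for seed in seeds:
                    df = population_outcomes(strat, n_dyads, int(seed),
                                             cfg=cell_cfg, haptic_noise=hn,
                                             n_per_block=n_per_block)
                    sc = deviation_scores(df, reference)
                    maes.append(sc["mae"])
                    rmses.append(sc["rmse"])
                rows.append({"strategy": strat, "q": q, "sigma_mu2": s2,
                             "mae": float(np.mean(maes)),
                             "rmse": float(np.mean(rmses)),
                             "rms_jerk": jerk, "scored": True})
    return pd.DataFrame(rows)


def trend_summary(df: pd.DataFrame, raw_effort: pd.DataFrame | None = None
                  ) -> dict:
    """Qualitative trend metrics of a population frame.

    Medians of the worse/better partner's improvement per stiffness level,
    the better-partner improvement-vs-kappa slope with a bootstrap CI, and
    the better partner's interaction effort per level.
    """
    d = hstats.assign_roles(df)
    out: dict = {"improvement": {}, "effort": {}}
    for role in ("worse", "better"):
        for lev in ("soft", "medium", "hard"):
            sel = d[(d["role"] == role) & (d["block_level"] == lev)]
            out["improvement"][f"{role}_{lev}"] = float(
                sel["delta_c"].median())
            out["effort"][f"{role}_{lev}"] = float(sel["E"].median())
    # better-partner slope of improvement on kappa, bootstrap CI over dyads
    bet = d[d["role"] == "better"]
    rng = np.random.default_rng(1234)
    dyads = bet["dyad"].unique()
    slopes = []
    for _ in range(400):
        pick = rng.choice(dyads, size=len(dyads), replace=True)
        sub = pd.concat([bet[bet["dyad"] == p] for p in pick])
        k = sub["kappa"].to_numpy()
        y = sub["delta_c"].to_numpy()
        slopes.append(np.polyfit(k, y, 1)[0])
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    k = bet["kappa"].to_numpy()
    out["better_slope"] = float(np.polyfit(k, bet["delta_c"].to_numpy(), 1)[0])
    out["better_slope_ci"] = [float(lo), float(hi)]
    return out


def _config_hash(cfg: SimConfig) -> str:
    return hashlib.sha256(cfg.to_json().encode()).hexdigest()[:12]


def reproduce(seed: int = 1, cfg: SimConfig | None = None,
              s1_path=None, s2_path=None, n_dyads: int = 14,
              n_per_block: int = 15, quick: bool = False) -> dict:
    """End-to-end run: haptic calibration, three-strategy populations,
    trends, statistics, reduced sensitivity grid — one manifest.

    With a trial-pair data file (``s1_path``) the empirical statistics are
    computed as well; otherwise those entries are marked skipped.
    """
    cfg = cfg or SimConfig()
    t0 = time.time()
    manifest = {"schema": 1, "seed": int(seed), "config_hash": _config_hash(cfg),
                "config": json.loads(cfg.to_json()), "entries": []}

    def entry(name, value, passed=None, note=""):
        manifest["entries"].append(
            {"name": name, "value": value, "pass": passed, "note": note,
             "t_elapsed_s": round(time.time() - t0, 1)})

    # 1. haptic-noise calibration
    if s2_path is not None:
        errors = read_s2(s2_path).mean_error_by_stiffness()
        table = calibrate_haptic_noise(cfg, errors_deg=errors)
        note = "from haptic-tracking data file"
    else:
        table = calibrate_haptic_noise(cfg, seed=_derive_seed(seed, 31))
        note = "simulated calibration"
    hn = HapticNoiseModel(partner_visual_var=0.0, stiffness_noise=table)
    ordered = [table[k] for k in sorted(table)]
    entry("sigma_s2_deg2", {str(k): v for k, v in table.items()},
          passed=ordered[0] >= ordered[1] >= ordered[2], note=note)

    # 2. per-strategy populations and trends
    nb = 5 if quick else n_per_block
    nd = max(4, n_dyads // 2) if quick else n_dyads
    frames = {}
    for strat in STRATEGIES:
        frames[strat] = population_outcomes(strat, nd, seed, cfg=cfg,
                                            haptic_noise=hn, n_per_block=nb)
    tr = trend_summary(frames["neuromechanical"])
    imp = tr["improvement"]
    entry("nm_worse_improvement_by_level",
          {k: imp[k] for k in ("worse_soft", "worse_medium", "worse_hard")},
          passed=imp["worse_soft"] <= imp["worse_medium"] <= imp["worse_hard"])
    entry("nm_better_slope_ci", tr["better_slope_ci"],
          passed=tr["better_slope_ci"][0] <= 0.0 <= tr["better_slope_ci"][1])
    eff = tr["effort"]
    entry("nm_better_effort_hard_medium",
          {"hard": eff["better_hard"], "medium": eff["better_medium"]},
          passed=eff["better_hard"] > 0 and eff["better_medium"] > 0)
    gi = trend_summary(frames["goal_integration"])["improvement"]
    nm_span = imp["worse_hard"] - imp["worse_soft"]
    gi_span = gi["worse_hard"] - gi["worse_soft"]
    entry("gi_vs_nm_worse_grading_span",
          {"goal_integration": gi_span, "neuromechanical": nm_span},
          passed=abs(gi_span) < 0.5 * abs(nm_span))
    fl = trend_summary(frames["follow_leader"])
    fl_mean = float(frames["follow_leader"]
                    .loc[frames["follow_leader"]["block_level"] == "hard",
                         "delta_c"].mean())
    entry("fl_hard_mean_improvement", fl_mean, passed=fl_mean < 0)

    # 3. statistics on the neuromechanical population
    df = frames["neuromechanical"]
    full = hstats.fit_improvement_lme(df, include_stiffness=True)
    red = hstats.fit_improvement_lme(df, include_stiffness=False)
    lrt = hstats.likelihood_ratio_test(full, red, "improvement kappa LRT")
    entry("nm_improvement_kappa_lrt_chi2", lrt.statistic,
          passed=lrt.p_value < 0.05, note=f"df={lrt.df}, p={lrt.p_value:.2g}")

    # 4. empirical statistics
    if s1_path is not None:
        emp = s1_to_outcomes(read_s1(s1_path))
        f = hstats.fit_improvement_lme(emp, include_stiffness=True)
        r = hstats.likelihood_ratio_test(
            f, hstats.fit_improvement_lme(emp, include_stiffness=False),
            "empirical improvement kappa LRT")
        entry("empirical_improvement_kappa_lrt_chi2", r.statistic)
        fe = hstats.fit_effort_lme(emp, include_stiffness=True)
        re_ = hstats.likelihood_ratio_test(
            fe, hstats.fit_effort_lme(emp, include_stiffness=False),
            "empirical effort kappa LRT")
        entry("empirical_effort_kappa_lrt_chi2", re_.statistic)
    else:
        entry("empirical_improvement_kappa_lrt_chi2", None,
              note="skipped (no data)")
        entry("empirical_effort_kappa_lrt_chi2", None,
              note="skipped (no data)")

    # 5. reduced sensitivity grid
    grid = run_sensitivity(cfg=cfg, n_dyads=4 if quick else 8,
                           seeds=tuple(seed % 1000 + i
                                       for i in range(2 if quick else 4)),
                           n_per_block=5)
    scored = grid[grid["scored"]]
    mins = scored.groupby("strategy")[["mae", "rmse"]].min().to_dict("index")
    order_ok = True
    for metric in ("mae", "rmse"):
        piv = scored.pivot_table(index=["q", "sigma_mu2"],
                                 columns="strategy", values=metric)
        order_ok &= bool((piv["neuromechanical"] < piv["goal_integration"]).all()
                         and (piv["goal_integration"] < piv["follow_leader"]).all())
    entry("sensitivity_min_scores", mins, passed=order_ok,
          note="per-cell ordering neuromechanical < goal_integration < "
               "follow_leader on mae and rmse")
    manifest["runtime_s"] = round(time.time() - t0, 1)
    return manifest
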