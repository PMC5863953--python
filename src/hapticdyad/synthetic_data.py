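"""Synthetic dyad datasets with the statistical structure of the experiment,
plus readers/writers for the two plain-text trial-data dialects.

The generator simulates full 45-trial sessions (3 stiffness blocks of 15,
medium first, hard/soft order seeded, ~50 % Bernoulli connected trials) for
pairs of agents whose visual-noise "skill" is drawn from the configured
band, runs the chosen interaction strategy on connected trials, pairs solo
and connected trials, and emits rows in the 19-column trial-pair layout:

  solo err 1, solo err 2, conn err 1, conn err 2,
  solo effort 1, solo effort 2, conn effort 1, conn effort 2,
  solo cocon 1, solo cocon 2, conn cocon 1, conn cocon 2,
  solo recip 1, solo recip 2, conn recip 1, conn recip 2,
  stiffness (Nm/deg), dyad, block order (1 = medium-hard-soft)

Errors are degrees, efforts Nm-equivalent activations (mean |u| plus the
tonic baseline), stiffness Nm/deg.  Co-contraction columns carry a constant
placeholder and reciprocal-activation columns the raw |u| mean; the
headline analysis uses neither.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd

from .config import DEG, RAD2DEG, STIFFNESS, SimConfig
from .dynamics import CouplingSpec
from .metrics import TrialMetrics, pair_trials, outcomes_frame
from .protocol import build_schedule, generate_target
from .strategies import (AgentSpec, HapticNoiseModel, calibrate_haptic_noise,
                         run_dyad, run_solo, STRATEGIES)

__all__ = [
    "S1_COLUMNS",
    "HapticTrackingRecord",
    "generate_dyad_dataset",
    "simulate_dyad_session",
    "write_s1",
    "read_s1",
    "write_s2",
    "read_s2",
    "s1_to_outcomes",
]

S1_COLUMNS = [
    "solo_error_1", "solo_error_2", "conn_error_1", "conn_error_2",
    "solo_effort_1", "solo_effort_2", "conn_effort_1", "conn_effort_2",
    "solo_cocon_1", "solo_cocon_2", "conn_cocon_1", "conn_cocon_2",
    "solo_recip_1", "solo_recip_2", "conn_recip_1", "conn_recip_2",
    "stiffness_nm_deg", "dyad", "order",
]

COCONTRACTION_PLACEHOLDER = 0.5


@dataclass(frozen=True)
class HapticTrackingRecord:
    """The haptic-tracking control experiment's table: 15 error rows then
    15 stiffness rows (Nm/deg), one column per subject."""

    errors_deg: np.ndarray      # (15, n_subjects)
    stiffness_nm_deg: np.ndarray  # (15, n_subjects)

    def mean_error_by_stiffness(self) -> dict:
        """Mean tracking error (deg) per stiffness level in Nm/rad."""
        out: dict[float, float] = {}
        for k_deg in np.unique(np.round(self.stiffness_nm_deg, 4)):
            mask = np.isclose(self.stiffness_nm_deg, k_deg, atol=1e-4)
            k_rad = float(k_deg) * RAD2DEG
            # snap to the nominal levels
            k_rad = min(STIFFNESS.values(), key=lambda v: abs(v - k_rad))
            out[k_rad] = float(self.errors_deg[mask].mean())
        return out


def _derive_seed(master: int, *idx: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(master), *[int(i) for i in idx]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_dyad_session(a1: AgentSpec, a2: AgentSpec, strategy: str,
                          seed: int, haptic_noise: HapticNoiseModel,
                          n_per_block: int = 15):
    """Simulate one dyad's full session; returns (metrics list, schedule)."""
    cfg = a1.config
    schedule = build_schedule(seed=_derive_seed(seed, 0),
                              n_per_block=n_per_block,
                              trial_duration=cfg.duration)
    metrics: list[TrialMetrics] = []
    for t in range(schedule.n_trials):
        tseed = _derive_seed(seed, 1, t)
        traj = generate_target(cfg.duration, cfg.dt, seed=tseed)
        K = schedule.stiffness[t]
        if schedule.connected[t]:
            c = CouplingSpec(K, cfg.damping(K))
            r1, r2 = run_dyad(a1, a2, c, traj, strategy, tseed,
                              haptic_noise=haptic_noise)
        else:
            r1 = run_solo(a1, traj, tseed)
            r2 = run_solo(a2, traj, tseed)
        for agent, r in ((a1, r1), (a2, r2)):
            if r.failed:
                raise RuntimeError(
                    f"simulation failure: dyad seed {seed}, trial {t}, "
                    f"subject {agent.subject_id}")
            metrics.append(TrialMetrics(
                subject=agent.subject_id, trial=t,
                tracking_error=r.rms_error_deg,
                effort=r.effort + cfg.tonic_effort,
                connected=bool(schedule.connected[t]), stiffness=K))
    return metrics, schedule


def generate_dyad_dataset(n_dyads: int, strategy: str, seed: int,
                          cfg: SimConfig | None = None,
                          skill_band_deg: tuple | None = None,
                          haptic_noise: HapticNoiseModel | None = None,
                          n_per_block: int = 15) -> pd.DataFrame:
    """Simulate ``n_dyads`` full sessions and return the trial-pair table.

    Per dyad the two agents' visual noises are drawn uniformly from the
    skill band (so the solo-error span matches the empirical 1-6 degree
    range).  The block order (hard/soft after the first medium block)
    alternates deterministically with the dyad's seeded schedule.
    """
    if n_dyads < 2:
        raise ValueError("need at least 2 dyads")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    cfg = cfg or SimConfig()
    band = skill_band_deg or cfg.skill_band_deg
    if haptic_noise is None:
        table = calibrate_haptic_noise(cfg, seed=_derive_seed(seed, 99))
        haptic_noise = HapticNoiseModel(partner_visual_var=0.0,
                                        stiffness_noise=table)
    rng = np.random.default_rng(_derive_seed(seed, 7))
    rows = []
    for d in range(n_dyads):
        sv1, sv2 = rng.uniform(band[0], band[1], size=2)
        a1 = AgentSpec(subject_id=1, visual_noise_deg=float(sv1), config=cfg)
        a2 = AgentSpec(subject_id=2, visual_noise_deg=float(sv2), config=cfg)
        dseed = _derive_seed(seed, 2, d)
        metrics, schedule = simulate_dyad_session(
            a1, a2, strategy, dseed, haptic_noise, n_per_block)
        order = 1 if schedule.blocks[1][0] == "hard" else 0
        pairs = pair_trials(metrics, schedule, dyad=d + 1)
        # pair_trials emits one row per subject; collapse to pair rows
        sub1 = [p for p in pairs if p.subject == 1]
        sub2 = [p for p in pairs if p.subject == 2]
        for p1, p2 in zip(sub1, sub2):
            rows.append({
                "solo_error_1": p1.solo_error, "solo_error_2": p2.solo_error,
                "conn_error_1": p1.connected_error,
                "conn_error_2": p2.connected_error,
                "solo_effort_1": p1.solo_effort,
                "solo_effort_2": p2.solo_effort,
                "conn_effort_1": p1.connected_effort,
                "conn_effort_2": p2.connected_effort,
                "solo_cocon_1": COCONTRACTION_PLACEHOLDER,
                "solo_cocon_2": COCONTRACTION_PLACEHOLDER,
                "conn_cocon_1": COCONTRACTION_PLACEHOLDER,
                "conn_cocon_2": COCONTRACTION_PLACEHOLDER,
                "solo_recip_1": p1.solo_effort - cfg.tonic_effort,
                "solo_recip_2": p2.solo_effort - cfg.tonic_effort,
                "conn_recip_1": p1.connected_effort - cfg.tonic_effort,
                "conn_recip_2": p2.connected_effort - cfg.tonic_effort,
                "stiffness_nm_deg": p1.stiffness * DEG,
                "dyad": d + 1,
                "order": order,
            })
    return pd.DataFrame(rows, columns=S1_COLUMNS)


def write_s1(df: pd.DataFrame, path) -> None:
    """Write the 19-column trial-pair table, tab-delimited, no header."""
    if list(df.columns) != S1_COLUMNS:
        raise ValueError("frame does not have the 19-column layout")
    df.to_csv(path, sep="\t", header=False, index=False,
              float_format="%.10g")


def read_s1(path) -> pd.DataFrame:
    """Parse a trial-pair text file (whitespace-delimited, 19 columns).

    Validates the column count and the stiffness levels (Nm/deg,
    auto-converted downstream with the x180/pi rule).
    """
    try:
        raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except Exception as e:
        raise ValueError(f"cannot parse {path}: {e}") from e
    if raw.shape[1] != len(S1_COLUMNS):
        raise ValueError(f"{path}: expected {len(S1_COLUMNS)} columns, "
                         f"found {raw.shape[1]}")
    bad = [c for c in raw.columns
           if not np.issubdtype(raw[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric cells in columns {bad}")
    df = raw.set_axis(S1_COLUMNS, axis=1)
    k_rad = df["stiffness_nm_deg"] * RAD2DEG
    levels = np.array(sorted(STIFFNESS.values()))
    dist = np.min(np.abs(k_rad.to_numpy()[:, None] - levels[None, :]), axis=1)
    offender = np.argmax(dist)
    if dist[offender] > 0.2:
        raise ValueError(
            f"{path} row {offender}: stiffness {df['stiffness_nm_deg'][offender]}"
            f" Nm/deg is not consistent with the nominal levels "
            f"{levels.tolist()} Nm/rad (x180/pi rule)")
    for col in S1_COLUMNS[:4]:
        neg = df.index[df[col] <= 0]
        if len(neg):
            raise ValueError(f"{path} row {neg[0]}: non-positive error in {col}")
    order_per_dyad = df.groupby("dyad")["order"].nunique()
    if (order_per_dyad > 1).any():
        raise ValueError("block order is not constant within a dyad")
    return df


def write_s2(rec: HapticTrackingRecord, path) -> None:
    arr = np.vstack([rec.errors_deg, rec.stiffness_nm_deg])
    np.savetxt(path, arr, delimiter="\t", fmt="%.10g")


def read_s2(path) -> HapticTrackingRecord:
    """Parse the haptic-tracking table: 30 rows (15 errors + 15 stiffness),
    one column per subject, stiffness constant in blocks of 5."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[0] != 30:
        raise ValueError(f"{path}: expected 30 rows, got {arr.shape}")
    errors, stiff = arr[:15], arr[15:]
    for col in range(stiff.shape[1]):
        for b in range(3):
            block = stiff[5 * b:5 * (b + 1), col]
            if not np.allclose(block, block[0]):
                raise ValueError(
                    f"{path}: stiffness rows not constant in block {b}, "
                    f"subject column {col}")
    return HapticTrackingRecord(errors_deg=errors, stiffness_nm_deg=stiff)


def s1_to_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Expand the pair table to the per-subject analysis frame with
    delta_c, delta_p, E, kappa (stiffness converted to Nm/rad)."""
    rows = []
    for _, r in df.iterrows():
        K = float(r["stiffness_nm_deg"]) * RAD2DEG
        K = min(STIFFNESS.values(), key=lambda v: abs(v - K))
        level = {v: k for k, v in STIFFNESS.items()}[K]
        for subj, other in ((1, 2), (2, 1)):
            e_s = float(r[f"solo_error_{subj}"])
            e_c = float(r[f"conn_error_{subj}"])
            e_p = float(r[f"solo_error_{other}"])
            a_s = float(r[f"solo_effort_{subj}"])
            a_c = float(r[f"conn_effort_{subj}"])
            if e_s <= 0 or a_s <= 0:
                continue
            rows.append({
                "dyad": int(r["dyad"]), "subject": subj,
                "block_level": level, "stiffness": K,
                "kappa": np.log10(K),
                "delta_c": 1.0 - e_c / e_s,
                "delta_p": 1.0 - e_p / e_s,
                "E": a_c / a_s - 1.0,
                "order": int(r["order"]),
                "solo_error": e_s, "connected_error": e_c,
                "solo_effort": a_s, "connected_effort": a_c,
            })
    return pd.DataFrame(rows)
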