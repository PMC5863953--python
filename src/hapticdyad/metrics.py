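"""Trial and pair metrics: tracking error, improvement, relative error,
interaction effort.

Conventions (dimensionless):
  improvement      Dc = 1 - e_c / e   (positive: better when coupled)
  relative error   Dp = 1 - e_p / e   (positive: the worse partner)
  interaction eff. E  = a_c / a - 1   (positive: more effort when coupled)

The interaction-effort sign convention follows the results narrative
(elevated connected-trial effort plots positive); the reciprocal reading
a / a_c - 1 is available behind the ``reciprocal`` flag.  Pairing matches
each solo trial with the nearest preceding connected trial inside the same
stiffness block; the reverse reading (connected after solo) is behind
``pair_direction``.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import math

import numpy as np
import pandas as pd

from .config import DEG
from .protocol import TrialSchedule

__all__ = [
    "TrialMetrics",
    "PairedOutcome",
    "tracking_error",
    "improvement",
    "relative_error",
    "interaction_effort",
    "simulated_effort",
    "pair_trials",
    "outcomes_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialMetrics:
    subject: int
    trial: int
    tracking_error: float   # degrees RMS
    effort: float           # Nm-equivalent mean activation
    connected: bool
    stiffness: float        # Nm/rad

    def __post_init__(self):
        if self.tracking_error < 0 or self.effort < 0:
            raise ValueError("error and effort must be non-negative")


@dataclass(frozen=True)
class PairedOutcome:
    dyad: int
    subject: int
    block_level: str
    stiffness: float        # Nm/rad
    kappa: float            # log10(K)
    improvement: float      # Dc
    relative_error: float   # Dp
    interaction_effort: float
    solo_error: float
    connected_error: float
    solo_effort: float
    connected_effort: float


def tracking_error(cursor: np.ndarray, target: np.ndarray) -> float:
    """RMS pointwise distance between cursor and target (same units in/out)."""
    cursor = np.asarray(cursor, float)
    target = np.asarray(target, float)
    if cursor.shape != target.shape:
        raise ValueError(f"length mismatch: cursor {cursor.shape} "
                         f"vs target {target.shape}")
    return float(np.sqrt(np.mean((cursor - target) ** 2)))


def improvement(e_solo: float, e_connected: float) -> float:
    """Dc = 1 - e_c / e."""
    if e_solo <= 0:
        raise ValueError("solo error must be positive")
    return 1.0 - e_connected / e_solo


def relative_error(e_solo: float, e_partner: float) -> float:
    """Dp = 1 - e_p / e  (positive identifies the worse partner)."""
    if e_solo <= 0:
        raise ValueError("solo error must be positive")
    return 1.0 - e_partner / e_solo


def interaction_effort(alpha_solo: float, alpha_connected: float,
                       reciprocal: bool = False) -> float:
    """E = a_c / a - 1 (or a / a_c - 1 with ``reciprocal``)."""
    if alpha_solo <= 0:
        raise ValueError("zero solo effort: interaction effort undefined")
    if reciprocal:
        if alpha_connected <= 0:
            raise ValueError("zero connected effort: reciprocal form undefined")
        return alpha_solo / alpha_connected - 1.0
    return alpha_connected / alpha_solo - 1.0


def simulated_effort(u: np.ndarray) -> float:
    """Effort proxy of a simulated trial: mean |u| over the trial, Nm."""
    return float(np.mean(np.abs(np.asarray(u, float))))


def pair_trials(metrics: list[TrialMetrics], schedule: TrialSchedule,
                dyad: int = 0, pair_direction: str = "solo_after_connected",
                effort_reciprocal: bool = False) -> list[PairedOutcome]:
    """Pair each solo trial with the nearest preceding connected trial in the
    same stiffness block (or the reverse with ``pair_direction =
    'connected_after_solo'``) and compute the pair metrics.

    ``metrics`` holds both subjects' per-trial metrics; both partners of a
    pair are emitted.  Unpairable trials are dropped (count logged).
    """
    if pair_direction not in ("solo_after_connected", "connected_after_solo"):
        raise ValueError(f"unknown pairing direction {pair_direction!r}")
    by_subject: dict[int, dict[int, TrialMetrics]] = {}
    for m in metrics:
        by_subject.setdefault(m.subject, {})[m.trial] = m
    subjects = sorted(by_subject)
    if len(subjects) != 2:
        raise ValueError(f"expected metrics for exactly 2 subjects, "
                         f"got {subjects}")
    out: list[PairedOutcome] = []
    dropped = 0
    n_per_block = schedule.blocks[0][2]
    for bi, (level, K, nb) in enumerate(schedule.blocks):
        lo, hi = bi * n_per_block, (bi + 1) * n_per_block
        idx = range(lo, hi)
        conn = [i for i in idx if schedule.connected[i]]
        solo = [i for i in idx if not schedule.connected[i]]
        if pair_direction == "connected_after_solo":
            src, dst = conn, solo
        else:
            src, dst = solo, conn
        for i in src:
            prev = [j for j in dst if j < i]
            if not prev:
                dropped += 1
                continue
            j = max(prev)
            # orient so that (solo trial, connected trial) = (i_s, i_c)
            i_s, i_c = (i, j) if pair_direction == "solo_after_connected" else (j, i)
            for subj in subjects:
                partner = subjects[1] if subj == subjects[0] else subjects[0]
                ms = by_subject[subj].get(i_s)
                mc = by_subject[subj].get(i_c)
                mp = by_subject[partner].get(i_s)
                if ms is None or mc is None or mp is None:
                    dropped += 1
                    continue
                try:
                    eff = interaction_effort(ms.effort, mc.effort,
                                             effort_reciprocal)
                except ValueError:
                    dropped += 1
                    continue
                out.append(PairedOutcome(
                    dyad=dyad, subject=subj, block_level=level, stiffness=K,
                    kappa=math.log10(K),
                    improvement=improvement(ms.tracking_error,
                                            mc.tracking_error),
                    relative_error=relative_error(ms.tracking_error,
                                                  mp.tracking_error),
                    interaction_effort=eff,
                    solo_error=ms.tracking_error,
                    connected_error=mc.tracking_error,
                    solo_effort=ms.effort, connected_effort=mc.effort))
    if dropped:
        log.info("pair_trials: dropped %d unpairable trials", dropped)
    if not out:
        log.warning("pair_trials: no valid pairs in any block")
    return out


def outcomes_frame(outcomes: list[PairedOutcome]) -> pd.DataFrame:
    """PairedOutcome list as the analysis table (one row per subject-pair)."""
    df = pd.DataFrame([o.__dict__ for o in outcomes])
    if df.empty:
        return df
    df = df.rename(columns={"improvement": "delta_c",
                            "relative_error": "delta_p",
                            "interaction_effort": "E"})
    df["K_nm_deg"] = df["stiffness"] * DEG
    return df
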