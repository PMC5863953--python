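"""Simulation constants and the shared configuration object.

All internal computation is in SI units (radians, seconds, Nm); degrees
appear only at I/O boundaries.  The three coupling stiffness levels of the
experiment are 17.2 (hard), 1.7 (medium) and 0.3 Nm/rad (soft); data files
store stiffness in Nm/deg, converted with the factor pi/180.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math

import numpy as np

DEG = math.pi / 180.0
RAD2DEG = 180.0 / math.pi

#: Stiffness of the virtual elastic band per condition, Nm/rad.
STIFFNESS = {"hard": 17.2, "medium": 1.7, "soft": 0.3}

#: Multi-sine target: (amplitude deg, angular frequency rad/s) per term.
TARGET_TERMS = ((-7.8, 0.12), (1.6, 0.28), (9.4, 0.37), (-10.6, 0.64))

#: Sum of |amplitudes|, the hard bound on target excursion (degrees).
TARGET_AMP_BOUND = sum(abs(a) for a, _ in TARGET_TERMS)


@dataclass
class SimConfig:
    """All tunable constants of the simulated tracking task.

    The two parameters swept in the sensitivity analysis are ``q`` (state-cost
    multiplier of the LQR) and ``sigma_mu2`` (variance of the internal-model
    acceleration noise of the target).  Everything else is held fixed across
    the experiment.
    """

    dt: float = 0.005            # integration step, s
    duration: float = 40.0       # trial length, s
    inertia: float = 1.0         # effective wrist inertia, kg m^2
    q: float = 1.0               # state-cost multiplier (sensitivity axis 1)
    sigma_mu2: float = 0.02      # target accel. noise variance, (rad/s^2)^2 (axis 2)
    Q_pos: float = 1.0           # base state cost, position
    Q_vel: float = 0.1           # base state cost, velocity
    R: float = 0.03              # control cost
    damping_ratio: float = 0.1   # D = damping_ratio * sqrt(K * I)
    vel_noise_factor: float = 3.0    # visual velocity noise = factor * sigma_v, (rad/s)/rad
    proprio_noise: float = 0.005     # proprioceptive position noise, rad
    force_noise_haptic: float = 0.05  # torque-sensing noise, haptic-tracking task, Nm
    goal_fusion_interval: float = 0.005  # s between haptic goal-fusion updates (= dt)
    burn_in: float = 5.0         # s of own-target substitution before goal fusion
    ou_lambda_v: float = 1.0     # goal-model velocity leak, 1/s
    ou_lambda_p: float = 0.2     # goal-model position leak, 1/s
    fl_pos_noise: float = 0.005  # follow-the-leader lock, claimed position noise, rad
    fl_vel_noise: float = 0.01   # follow-the-leader lock, claimed velocity noise, rad/s
    tonic_effort: float = 1.0    # tonic activation baseline added to recorded efforts, Nm-eq.
    skill_band_deg: tuple = (0.5, 8.0)   # per-subject visual noise range (degrees)
    delay: float = 0.0           # compensated sensory delay, s (multiple of dt)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def damping(self, stiffness: float) -> float:
        """Damping D of the elastic band for a given stiffness K (Nm s/rad)."""
        return self.damping_ratio * math.sqrt(max(stiffness, 0.0) * self.inertia)

    def state_cost(self) -> np.ndarray:
        return self.q * np.diag([self.Q_pos, self.Q_vel])

    def to_json(self) -> str:
        """Config echo for provenance sidecars."""
        d = asdict(self)
        d["skill_band_deg"] = list(d["skill_band_deg"])
        return json.dumps(d, indent=2, sort_keys=True)


DEFAULT = SimConfig()


def stiffness_nm_per_deg(k_nm_per_rad: float) -> float:
    """Convert Nm/rad to the Nm/deg convention of the trial data files."""
    return k_nm_per_rad * DEG


def stiffness_nm_per_rad(k_nm_per_deg: float) -> float:
    """Convert Nm/deg (data-file convention) to Nm/rad (x 180/pi)."""
    return k_nm_per_deg * RAD2DEG


# the factor written out, used by the parser's built-in consistency check
NM_PER_DEG_TO_NM_PER_RAD = RAD2DEG
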