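"""Target trajectory, visual display cloud, and the trial/block schedule.

The target is a deterministic multi-sine; the only randomness in a trial's
stimulus is the uniformly drawn phase offset ("initial time") and the visual
cloud of spots rendered around the true position.  The schedule of the main
experiment is 45 trials of 40 s in three stiffness blocks of 15, medium
block first, hard/soft order permuted, with each trial connected or solo by
a fair coin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEG, STIFFNESS, TARGET_TERMS, TARGET_AMP_BOUND, SimConfig

__all__ = [
    "TargetTrajectory",
    "VisualCloud",
    "TrialSchedule",
    "generate_target",
    "render_cloud",
    "build_schedule",
]

CLOUD_SPOTS = 10
CLOUD_REFRESH = 0.4  # s
PHASE_MAX = 30.0     # s, upper bound of the uniform phase-offset draw


@dataclass(frozen=True)
class TargetTrajectory:
    """Deterministic multi-sine target sampled on a regular grid.

    Positions/velocities are stored in degrees (the display unit); the
    simulation engine converts to radians internally.
    """

    times: np.ndarray        # s
    position: np.ndarray     # deg
    velocity: np.ndarray     # deg/s
    phase_offset: float      # s
    dt: float                # s

    def __post_init__(self):
        if len(self.times) != len(self.position):
            raise ValueError("times and position length mismatch")

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.position, self.velocity])
        np.savetxt(path, arr, delimiter=",", comments="",
                   header="time_s,target_deg,target_vel_deg_s")


@dataclass(frozen=True)
class VisualCloud:
    """Spot cloud rendered around the target, refreshed every 400 ms."""

    spot_count: int
    spread: float            # deg, per-subject constant sigma_t
    refresh_interval: float  # s
    frame_times: np.ndarray  # s, one entry per refresh frame
    spots: np.ndarray        # (n_frames, spot_count) deg


@dataclass(frozen=True)
class TrialSchedule:
    n_trials: int
    trial_duration: float
    blocks: tuple            # ((level_name, stiffness Nm/rad, n_trials), ...)
    connected: np.ndarray    # bool per trial
    stiffness: np.ndarray    # Nm/rad per trial
    level: tuple             # level name per trial

    def to_json_dict(self) -> dict:
        return {
            "n_trials": int(self.n_trials),
            "trial_duration": float(self.trial_duration),
            "blocks": [[b[0], float(b[1]), int(b[2])] for b in self.blocks],
            "connected": [bool(c) for c in self.connected],
            "stiffness_nm_rad": [float(k) for k in self.stiffness],
        }


def generate_target(duration: float, dt: float, phase_offset: float = 0.0,
                    seed: int | None = None) -> TargetTrajectory:
    """Evaluate the four-term multi-sine target and its analytic derivative.

    If ``seed`` is given the phase offset is drawn uniformly from
    [0, 30] s and the ``phase_offset`` argument is ignored.  Display noise is
    never baked into the returned trajectory; it lives in the cloud.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError(f"duration and dt must be positive, got {duration}, {dt}")
    if seed is not None:
        phase_offset = float(np.random.default_rng(seed).uniform(0.0, PHASE_MAX))
    if not 0.0 <= phase_offset <= PHASE_MAX:
        raise ValueError(f"phase offset must lie in [0, {PHASE_MAX}] s")
    n = int(round(duration / dt))
    times = np.arange(n) * dt
    tau = times + phase_offset
    pos = np.zeros(n)
    vel = np.zeros(n)
    for amp, om in TARGET_TERMS:
        pos += amp * np.sin(om * tau)
        vel += amp * om * np.cos(om * tau)
    assert np.max(np.abs(pos)) <= TARGET_AMP_BOUND + 1e-9
    return TargetTrajectory(times=times, position=pos, velocity=vel,
                            phase_offset=phase_offset, dt=dt)


def render_cloud(traj: TargetTrajectory, spread: float, seed: int,
                 spot_count: int = CLOUD_SPOTS) -> VisualCloud:
    """Render the spot cloud: ``spot_count`` i.i.d. Normal(target, spread^2)
    samples per 400 ms frame."""
    if spread <= 0:
        raise ValueError("cloud spread must be positive")
    rng = np.random.default_rng(seed)
    step = max(int(round(CLOUD_REFRESH / traj.dt)), 1)
    idx = np.arange(0, len(traj.times), step)
    centers = traj.position[idx]
    spots = centers[:, None] + rng.normal(0.0, spread, size=(len(idx), spot_count))
    return VisualCloud(spot_count=spot_count, spread=spread,
                       refresh_interval=CLOUD_REFRESH,
                       frame_times=traj.times[idx], spots=spots)


def build_schedule(order: str = "medium-hard-soft", seed: int | None = None,
                   n_per_block: int = 15, trial_duration: float = 40.0,
                   p_connected: float = 0.5) -> TrialSchedule:
    """Build the 3-block trial schedule.

    ``order`` is one of ``medium-hard-soft`` / ``medium-soft-hard``; when a
    ``seed`` is given the hard/soft order is a seeded permutation instead and
    ``order`` is ignored.  Connected flags are i.i.d. Bernoulli(p_connected).
    """
    rng = np.random.default_rng(seed)
    if seed is not None:
        tail = ["hard", "soft"] if rng.integers(2) == 0 else ["soft", "hard"]
        levels = ["medium"] + tail
    else:
        levels = order.split("-")
        if sorted(levels) != ["hard", "medium", "soft"] or levels[0] != "medium":
            raise ValueError(f"invalid block order {order!r}")
    blocks = tuple((lev, STIFFNESS[lev], n_per_block) for lev in levels)
    n_trials = 3 * n_per_block
    connected = rng.random(n_trials) < p_connected
    stiffness = np.repeat([STIFFNESS[lev] for lev in levels], n_per_block)
    level = tuple(np.repeat(levels, n_per_block))
    return TrialSchedule(n_trials=n_trials, trial_duration=trial_duration,
                         blocks=blocks, connected=connected,
                         stiffness=stiffness, level=level)
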