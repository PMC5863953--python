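"""Interaction strategies: solo vision, follow-the-leader, interpersonal goal
integration, neuromechanical goal sharing, and the haptic-tracking condition
used to calibrate the stiffness-dependent haptic noise sigma_s^2(K).

Architecture of a connected goal-sharing trial, per agent:

* a visual error-state Kalman filter (position + velocity channels, per-step
  noisy observations of theta - t);
* a linear 4-state *goal filter* over [partner's internal error estimate,
  target state] that watches the partner's wrist acceleration — exactly
  known through the noiseless interaction force and the agents' force
  cancellation — and uses the known homogeneous filter/controller structure
  of the population plus an Ornstein-Uhlenbeck goal prior;
* every 50 ms after a 5 s burn-in, the inferred partner goal is fused into
  the error-state filter at the claimed haptic-channel variance
  sigma_v~^2 + sigma_s^2(K).  Goal integration sets sigma_s^2 = 0;
  neuromechanical goal sharing uses the calibrated table.

The command is the certainty-equivalent LQG law with cancellation of the
felt spring force, u = -L x_hat - F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_are

from . import _engine
from .config import DEG, RAD2DEG, STIFFNESS, SimConfig, DEFAULT
from .dynamics import CouplingSpec, transition_matrix, input_matrix
from .lqg import controller_for, kalman_steady_gain
from .protocol import TargetTrajectory, generate_target

__all__ = [
    "AgentSpec",
    "TrialResult",
    "PartnerModel",
    "HapticNoiseModel",
    "STRATEGIES",
    "run_solo",
    "run_dyad",
    "run_haptic_tracking",
    "calibrate_haptic_noise",
    "observe_follow_leader",
    "integrate_goals",
    "identify_partner_policy",
    "infer_partner_target",
    "invert_coupling",
]

STRATEGIES = ("follow_leader", "goal_integration", "neuromechanical")

COV_DIVERGENCE_TRACE = 10.0  # rad^2; a filter above this flags the trial


@dataclass(frozen=True)
class AgentSpec:
    """One simulated subject.

    ``visual_noise_deg`` is the skill knob: the std of the per-step visual
    position observation.  Velocity-observation noise is tied to it by the
    configuration's ``vel_noise_factor``.
    """

    subject_id: int
    visual_noise_deg: float
    config: SimConfig = field(default_factory=SimConfig)

    @property
    def sigma_v(self) -> float:
        return self.visual_noise_deg * DEG

    @property
    def sigma_vel(self) -> float:
        return self.config.vel_noise_factor * self.sigma_v


@dataclass
class TrialResult:
    """Time series and scalar summaries for one simulated trial."""

    times: np.ndarray
    wrist: np.ndarray        # rad
    target: np.ndarray       # rad
    force: np.ndarray        # Nm (felt by this agent)
    command: np.ndarray      # Nm
    rms_error_deg: float
    effort: float            # mean |u|, Nm
    connected: bool
    stiffness: float         # Nm/rad
    failed: bool = False

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.wrist, self.target,
                               self.force, self.command])
        np.savetxt(path, arr, delimiter=",", comments="",
                   header="time_s,theta_rad,target_rad,force_Nm,u_Nm")


@dataclass
class PartnerModel:
    """Identified representation of the partner."""

    gains: np.ndarray            # [L~_p, L~_v]
    gain_history: np.ndarray     # (n, 2)
    wrist_estimate: np.ndarray   # (n, 2) [theta~, theta~']
    target_estimate: np.ndarray | None = None  # (n, 2) once inferred
    converged: bool = False
    gain_cov: np.ndarray | None = None  # final 2x2 gain covariance


@dataclass(frozen=True)
class HapticNoiseModel:
    """Stiffness-dependent haptic-channel noise, degrees^2 per level."""

    partner_visual_var: float              # sigma_v~^2, deg^2 (set per dyad)
    stiffness_noise: dict                  # K (Nm/rad) -> sigma_s^2, deg^2

    def channel_var_deg2(self, stiffness: float) -> float:
        return self.partner_visual_var + self.stiffness_noise.get(stiffness, 0.0)


def _target_arrays(traj: TargetTrajectory) -> tuple[np.ndarray, np.ndarray]:
    return traj.position * DEG, traj.velocity * DEG


def _agent_noise(agent: AgentSpec, seed: int, n: int) -> np.ndarray:
    """Per-agent visual observation noise, seeded by (trial seed, subject)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, agent.subject_id]))
    out = np.empty((n, 2))
    out[:, 0] = rng.normal(0.0, agent.sigma_v, n)
    out[:, 1] = rng.normal(0.0, agent.sigma_vel, n)
    return out


def _result(cfg, tp, err, us, connected, stiffness, force) -> TrialResult:
    rms = float(np.sqrt(np.mean(err ** 2))) * RAD2DEG
    return TrialResult(times=np.arange(len(tp)) * cfg.dt, wrist=tp + err,
                       target=tp, force=force, command=us,
                       rms_error_deg=rms, effort=float(np.mean(np.abs(us))),
                       connected=connected, stiffness=stiffness,
                       failed=not np.isfinite(rms) or rms > 360.0)


def run_solo(agent: AgentSpec, traj: TargetTrajectory, seed: int) -> TrialResult:
    """Closed-loop solo tracking of the multi-sine target (F = 0)."""
    cfg = agent.config
    ctl = controller_for(cfg)
    tp, tv = _target_arrays(traj)
    n = len(tp)
    noise = _agent_noise(agent, seed, n)
    err = np.empty(n)
    us = np.empty(n)
    _engine.solo_trial(tp, tv, noise, ctl.L_p, ctl.L_v, cfg.dt, cfg.inertia,
                       agent.sigma_v, agent.sigma_vel, cfg.sigma_mu2, err, us)
    return _result(cfg, tp, err, us, False, 0.0, np.zeros(n))


def _ou_matrix(cfg: SimConfig) -> np.ndarray:
    dt = cfg.dt
    return np.array([[1.0, dt],
                     [-cfg.ou_lambda_p * dt, 1.0 - cfg.ou_lambda_v * dt]])


def _goal_filter_matrices(cfg: SimConfig, partner: AgentSpec):
    """Build the goal-filter system matrices for observing ``partner``.

    The filter assumes the partner runs the population's visual filter at
    steady state (gain G) and the shared LQR gain L; its state is
    [x~_hat (2), t (2)] with dynamics driven by the partner's observed wrist
    d = (theta~, theta~') and observation c = partner wrist acceleration.
    """
    A = transition_matrix(cfg.dt)
    ctl = controller_for(cfg)
    L = ctl.L.reshape(1, 2)
    B = input_matrix(cfg.dt, cfg.inertia)
    M = A - B @ L
    Sv = np.diag([partner.sigma_v ** 2, partner.sigma_vel ** 2])
    W2 = np.diag([1e-12, cfg.dt ** 2 * cfg.sigma_mu2])
    G = kalman_steady_gain(A, W2, np.eye(2), Sv)
    MIG = M @ (np.eye(2) - G)
    MG = M @ G
    Phi = np.zeros((4, 4))
    Phi[:2, :2] = MIG
    Phi[:2, 2:] = -MG
    Phi[2:, 2:] = _ou_matrix(cfg)
    Gin = MG
    LG = (L @ G).ravel()
    Hobs = np.concatenate([(-L @ (np.eye(2) - G)).ravel(), LG])
    Robs = float(LG @ Sv @ LG) + 1e-14
    Wn = np.zeros((4, 4))
    Wn[:2, :2] = MG @ Sv @ MG.T
    Wn[2, 2] = 1e-12
    Wn[3, 3] = cfg.dt ** 2 * cfg.sigma_mu2
    return Phi, Gin, Hobs, Robs, Wn, LG


def run_dyad(a1: AgentSpec, a2: AgentSpec, c: CouplingSpec,
             traj: TargetTrajectory, strategy: str, seed: int,
             haptic_noise: HapticNoiseModel | None = None
             ) -> tuple[TrialResult, TrialResult]:
    """Symmetric co-simulation of a connected trial under ``strategy``.

    With zero coupling every strategy's haptic channel carries no force and
    the trial reduces to two independent solo runs on the same noise draws.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    cfg = a1.config
    if c.solo:
        return run_solo(a1, traj, seed), run_solo(a2, traj, seed)
    ctl = controller_for(cfg)
    tp, tv = _target_arrays(traj)
    n = len(tp)
    noise1 = _agent_noise(a1, seed, n)
    noise2 = _agent_noise(a2, seed, n)
    err = np.empty((2, n))
    us = np.empty((2, n))
    if strategy == "follow_leader":
        follow = np.empty((2, n))
        _engine.fl_trial(tp, tv, noise1, noise2, c.stiffness, c.damping,
                         ctl.L_p, ctl.L_v, cfg.dt, cfg.inertia,
                         a1.sigma_v, a2.sigma_v, a1.sigma_vel, a2.sigma_vel,
                         cfg.sigma_mu2, cfg.fl_pos_noise ** 2,
                         cfg.fl_vel_noise ** 2, err, us, follow)
    else:
        if strategy == "neuromechanical":
            if haptic_noise is None:
                raise ValueError("neuromechanical goal sharing requires a "
                                 "calibrated HapticNoiseModel")
            ss2 = haptic_noise.stiffness_noise.get(c.stiffness, 0.0) * DEG ** 2
        else:
            ss2 = 0.0
        mats1 = _goal_filter_matrices(cfg, a2)   # agent 1 observes agent 2
        mats2 = _goal_filter_matrices(cfg, a1)
        vf2 = cfg.vel_noise_factor ** 2
        rg = []
        for own, other in ((a1, a2), (a2, a1)):
            rg.append((other.sigma_v ** 2 + ss2,
                       other.sigma_vel ** 2 + vf2 * ss2))
        t_inf = np.empty((2, n))
        w0 = np.array([tp[0], tv[0]])
        _engine.goal_trial(tp, tv, noise1, noise2, c.stiffness, c.damping,
                           ctl.L_p, ctl.L_v, cfg.dt, cfg.inertia,
                           a1.sigma_v, a2.sigma_v, a1.sigma_vel, a2.sigma_vel,
                           cfg.sigma_mu2,
                           rg[0][0], rg[0][1], rg[1][0], rg[1][1],
                           int(round(cfg.goal_fusion_interval / cfg.dt)),
                           int(round(cfg.burn_in / cfg.dt)),
                           mats1[0], mats2[0], mats1[1], mats2[1],
                           mats1[2], mats2[2], mats1[3], mats2[3],
                           mats1[4], mats2[4], mats1[5], mats2[5], w0,
                           err, us, t_inf)
    F1 = c.stiffness * (err[1] - err[0]) + c.damping * np.gradient(
        err[1] - err[0], cfg.dt)
    r1 = _result(cfg, tp, err[0], us[0], True, c.stiffness, F1)
    r2 = _result(cfg, tp, err[1], us[1], True, c.stiffness, -F1)
    return r1, r2


def run_haptic_tracking(agent: AgentSpec, c: CouplingSpec,
                        traj: TargetTrajectory, seed: int) -> TrialResult:
    """Track the invisible target through the elastic band alone."""
    if c.stiffness <= 0:
        raise ValueError("haptic tracking requires positive stiffness "
                         "(the force channel is otherwise uninformative)")
    cfg = agent.config
    ctl = controller_for(cfg)
    tp, tv = _target_arrays(traj)
    n = len(tp)
    rng = np.random.default_rng(np.random.SeedSequence([seed, agent.subject_id]))
    fnoise = rng.normal(0.0, cfg.force_noise_haptic, n)
    err = np.empty(n)
    us = np.empty(n)
    _engine.haptic_trial(tp, tv, fnoise, c.stiffness, c.damping,
                         cfg.force_noise_haptic ** 2, ctl.L_p, ctl.L_v,
                         cfg.dt, cfg.inertia, cfg.sigma_mu2, err, us)
    return _result(cfg, tp, err, us, True, c.stiffness, np.zeros(n))


def calibrate_haptic_noise(cfg: SimConfig = DEFAULT, n_seeds: int = 5,
                           seed: int = 0,
                           errors_deg: dict | None = None) -> dict:
    """Stiffness noise sigma_s^2(K) in deg^2 from haptic-tracking errors.

    sigma_s^2(K) = e(K)^2 - e(K_hard)^2, clipped at zero — the hardest
    coupling transmits the target faithfully and defines the floor.  If
    ``errors_deg`` (mean haptic tracking error per stiffness, e.g. parsed
    from the control experiment's data file) is supplied it overrides the
    simulated calibration.
    """
    levels = sorted(STIFFNESS.values())
    if errors_deg is None:
        agent = AgentSpec(subject_id=0, visual_noise_deg=1.0, config=cfg)
        errors_deg = {}
        for K in levels:
            c = CouplingSpec(K, cfg.damping(K))
            es = []
            for s in range(n_seeds):
                traj = generate_target(cfg.duration, cfg.dt, seed=seed * 1000 + s)
                es.append(run_haptic_tracking(agent, c, traj,
                                              seed * 1000 + 17 * s).rms_error_deg)
            errors_deg[K] = float(np.median(es))
    floor = errors_deg[max(levels)]
    table = {K: max(errors_deg[K] ** 2 - floor ** 2, 0.0) for K in levels}
    # soft coupling must be at least as noisy as hard
    ks = sorted(table)
    for lo, hi in zip(ks[:-1], ks[1:]):
        if table[lo] < table[hi]:
            raise RuntimeError("calibrated sigma_s^2 is not non-increasing in K")
    return table


def observe_follow_leader(own_theta: float, own_target: float,
                          partner_theta: float) -> tuple[str, float]:
    """The switched observation: track the target while own wrist is at
    least as close to it (inclusive tie), otherwise observe the offset to
    the partner's wrist."""
    if abs(own_theta - own_target) <= abs(partner_theta - own_target):
        return "target", own_theta - own_target
    return "partner", own_theta - partner_theta


def integrate_goals(visual_var: float, haptic_var: float,
                    z_visual: float, z_haptic: float,
                    prior_mean: float = 0.0, prior_var: float = np.inf
                    ) -> tuple[float, float]:
    """Inverse-variance fusion of the visual and haptic goal channels.

    Returns (fused mean, fused variance).  With infinite haptic variance the
    result reduces to the visual channel alone; information never increases
    the posterior variance.
    """
    if visual_var <= 0 or haptic_var <= 0:
        raise ValueError("channel variances must be positive")
    w = 0.0 if not np.isfinite(prior_var) else 1.0 / prior_var
    num = prior_mean * w
    for z, v in ((z_visual, visual_var), (z_haptic, haptic_var)):
        if np.isfinite(v):
            num += z / v
            w += 1.0 / v
    return num / w, 1.0 / w


def invert_coupling(force: np.ndarray, own_theta: np.ndarray,
                    own_vel: np.ndarray, c: CouplingSpec, dt: float
                    ) -> np.ndarray:
    """Reconstruct the partner's wrist angle from the force record.

    Solves F = K (th~ - th) + D (th~' - th') with a backward-difference
    velocity, i.e. the damping term is handled recursively rather than
    dropped.  Exact up to O(dt) when the force record is noiseless.
    """
    if c.stiffness <= 0:
        raise ValueError("coupling force is uninformative at K = 0")
    K, D = c.stiffness, c.damping
    a = D / (K * dt)
    out = np.empty_like(force)
    prev = own_theta[0] + force[0] / K
    for i in range(len(force)):
        rhs = own_theta[i] + (force[i] + D * own_vel[i]) / K
        prev = (rhs + a * prev) / (1.0 + a)
        out[i] = prev
    return out


def identify_partner_policy(force: np.ndarray, own_theta: np.ndarray,
                            own_target: np.ndarray, c: CouplingSpec,
                            cfg: SimConfig = DEFAULT,
                            own_vel: np.ndarray | None = None,
                            target_vel: np.ndarray | None = None,
                            own_command: np.ndarray | None = None,
                            obs_noise: tuple = None,
                            seed: int = 0) -> PartnerModel:
    """Identify the partner's feedback gains [L~_p, L~_v] from the recorded
    interaction force, own proprioception and own (visual) target.

    Runs the joint state-parameter extended Kalman filter over
    [own wrist (2), target (2), partner wrist (2), partner goal (2),
    gains (2)], with the own target substituted for the partner's goal (the
    identification-phase assumption).  The dynamics are nonlinear in the
    gain-times-state products, linearized per step.
    """
    if c.stiffness <= 0:
        raise ValueError("partner gains are unidentifiable at K = 0 "
                         "(force channel carries no information)")
    n = len(force)
    dt = cfg.dt
    K, D = c.stiffness, c.damping
    ctl = controller_for(cfg)
    if own_vel is None:
        own_vel = np.gradient(own_theta, dt)
    if target_vel is None:
        target_vel = np.gradient(own_target, dt)
    if own_command is None:
        own_command = np.zeros(n)
    sp = cfg.proprio_noise
    sv, svel, sF = obs_noise if obs_noise else (1.0 * DEG, 3.0 * DEG,
                                                cfg.force_noise_haptic)
    # identification-phase target model is the pure integrator (the goal
    # states are vision-anchored here; the Ornstein-Uhlenbeck leak is only a
    # regularizer for unanchored goals during inference)
    lam_p, lam_v = 0.0, 0.0
    s = np.array([own_theta[0], own_vel[0], own_target[0], target_vel[0],
                  own_theta[0], own_vel[0], own_target[0], target_vel[0],
                  ctl.L_p, ctl.L_v])
    P = np.diag([1e-4, 0.25, sv ** 2, 1.0, 1e-2, 0.25, sv ** 2, 1.0,
                 ctl.L_p ** 2, ctl.L_v ** 2])
    Wq = np.diag([1e-12, 1e-10, 1e-12, dt * dt * cfg.sigma_mu2,
                  1e-12, (1.0 * dt) ** 2, 1e-12, dt * dt * cfg.sigma_mu2,
                  (0.2 * dt) ** 2, (0.1 * dt) ** 2])
    H = np.zeros((4, 10))
    H[0, 0] = 1.0
    H[1, 2] = 1.0
    H[2, 3] = 1.0
    H[3, 0] = -K
    H[3, 1] = -D
    H[3, 4] = K
    H[3, 5] = D
    # conservative force-noise assumption damps the velocity-gain bias
    R = np.diag([sp ** 2, sv ** 2, svel ** 2, 9.0 * sF ** 2])
    I10 = np.eye(10)
    gains = np.empty((n, 2))
    wrist = np.empty((n, 2))
    for i in range(n):
        z = np.array([own_theta[i], own_target[i], target_vel[i], force[i]])
        S = H @ P @ H.T + R
        Kg = P @ H.T @ np.linalg.inv(S)
        s = s + Kg @ (z - H @ s)
        P = (I10 - Kg @ H) @ P
        gains[i] = s[8:]
        wrist[i] = s[4:6]
        # linearized predict; partner references the (substituted) own target
        gp, gv = s[8], s[9]
        J = I10.copy()
        J[0, 1] = dt
        J[2, 3] = dt
        J[4, 5] = dt
        J[6, 7] = dt
        J[3, 2] = -lam_p * dt
        J[3, 3] = 1.0 - lam_v * dt
        J[7, 6] = -lam_p * dt
        J[7, 7] = 1.0 - lam_v * dt
        J[5, 4] = -gp * dt
        J[5, 5] = 1.0 - gv * dt
        J[5, 2] = gp * dt
        J[5, 3] = gv * dt
        J[5, 8] = -(s[4] - s[2]) * dt
        J[5, 9] = -(s[5] - s[3]) * dt
        sn = s.copy()
        sn[0] += s[1] * dt
        sn[1] += (own_command[i] + force[i]) * dt / cfg.inertia
        sn[2] += s[3] * dt
        sn[3] = s[3] + (-lam_p * s[2] - lam_v * s[3]) * dt
        sn[4] += s[5] * dt
        sn[5] = s[5] + (-gp * (s[4] - s[2]) - gv * (s[5] - s[3])) * dt
        sn[6] += s[7] * dt
        sn[7] = s[7] + (-lam_p * s[6] - lam_v * s[7]) * dt
        s = sn
        P = J @ P @ J.T + Wq
    tail = gains[int(n * 0.75):]
    converged = bool(np.all(np.std(tail, axis=0) < 0.5))
    return PartnerModel(gains=gains[-1].copy(), gain_history=gains,
                        wrist_estimate=wrist, converged=converged,
                        gain_cov=P[8:, 8:].copy())


def identification_harness(stiffness: float, planted_gains: tuple,
                           seed: int, cfg: SimConfig = DEFAULT,
                           observer_noise_deg: float = 2.0,
                           force_noise: float = 0.02,
                           stationary_partner: bool = False):
    """Parameter-recovery harness for :func:`identify_partner_policy`.

    The partner applies the planted PD law on the true target (cancelling
    the spring reaction, like every agent in this framework); the observer
    tracks the target solo while recording proprioception, vision and the
    interaction force, and then identifies the partner's gains from those
    records.  With ``stationary_partner`` the partner is clamped to the
    (constant) target — the no-excitation case in which the gains are
    unidentifiable.

    Returns (PartnerModel, planted gain array).
    """
    gp, gv = planted_gains
    K = stiffness
    D = cfg.damping(K)
    dt = cfg.dt
    n = cfg.n_steps
    rng = np.random.default_rng(seed)
    if stationary_partner:
        tp = np.zeros(n)
        tv = np.zeros(n)
    else:
        traj = generate_target(cfg.duration, cfg.dt, seed=seed)
        tp, tv = traj.position * DEG, traj.velocity * DEG
    obs = AgentSpec(subject_id=0, visual_noise_deg=observer_noise_deg,
                    config=cfg)
    ctl = controller_for(cfg)
    sv, svel = obs.sigma_v, obs.sigma_vel
    th = thd = pth = pthd = 0.0
    x = np.zeros(2)
    A = transition_matrix(dt)
    B = input_matrix(dt, cfg.inertia).ravel()
    W2 = np.diag([1e-12, dt ** 2 * cfg.sigma_mu2])
    G = kalman_steady_gain(A, W2, np.eye(2), np.diag([sv ** 2, svel ** 2]))
    sF = force_noise
    F_rec = np.empty(n)
    th_rec = np.empty(n)
    t_obs = np.empty(n)
    tv_obs = np.empty(n)
    u_rec = np.empty(n)
    for i in range(n):
        F = K * (pth - th) + D * (pthd - thd)
        z = np.array([th - tp[i] + rng.normal(0, sv),
                      thd - tv[i] + rng.normal(0, svel)])
        x = x + G @ (z - x)
        u = -(ctl.L @ x) - F
        F_rec[i] = F + rng.normal(0, sF)
        th_rec[i] = th
        t_obs[i] = tp[i] + rng.normal(0, sv)
        tv_obs[i] = tv[i] + rng.normal(0, svel)
        u_rec[i] = u
        th += thd * dt
        thd += (u + F) * dt / cfg.inertia
        if not stationary_partner:
            up = -(gp * (pth - tp[i]) + gv * (pthd - tv[i])) + F  # cancels -F
            pth += pthd * dt
            pthd += (up - F) * dt / cfg.inertia
        x = A @ x + B * u
    pm = identify_partner_policy(F_rec, th_rec, t_obs,
                                 CouplingSpec(K, D), cfg=cfg,
                                 target_vel=tv_obs, own_command=u_rec,
                                 obs_noise=(sv, svel, sF))
    return pm, np.array([gp, gv])


def infer_partner_target(pm: PartnerModel, force: np.ndarray,
                         own_theta: np.ndarray, own_vel: np.ndarray,
                         c: CouplingSpec, partner_sigma_v: float,
                         cfg: SimConfig = DEFAULT,
                         force_noise: float = 0.0) -> PartnerModel:
    """Infer the partner's goal trajectory from proprioception and force.

    Requires identified (or assumed) gains; runs the linear goal filter on
    the partner wrist reconstructed from the force record.  Returns a new
    PartnerModel with ``target_estimate`` filled in.
    """
    if pm.gains is None or not np.all(np.isfinite(pm.gains)):
        raise ValueError("identify the partner's control policy first")
    dt = cfg.dt
    th_p = invert_coupling(force, own_theta, own_vel, c, dt)
    thd_p = np.gradient(th_p, dt)
    partner = AgentSpec(subject_id=-1,
                        visual_noise_deg=partner_sigma_v / DEG, config=cfg)
    Phi, Gin, Hobs, Robs, Wn, LG = _goal_filter_matrices(cfg, partner)
    if force_noise > 0:
        # sensing noise on the force record propagates into the wrist
        # reconstruction (sigma_F / K per sample) and, twice differenced,
        # into the acceleration observation
        Robs = Robs + (2.0 * force_noise / (c.stiffness * dt ** 2)) ** 2 \
            * dt ** 2  # one differentiation is absorbed by the filter lag

    n = len(force)
    w = np.array([0.0, 0.0, own_theta[0], 0.0])
    Pw = np.diag([partner.sigma_v ** 2, partner.sigma_vel ** 2, 0.05, 0.02])
    est = np.empty((n, 2))
    est[0] = w[2:]
    for i in range(1, n):
        c_acc = (thd_p[i] - thd_p[i - 1]) / dt
        d_prev = np.array([th_p[i - 1], thd_p[i - 1]])
        z = c_acc + LG @ d_prev
        S = float(Hobs @ Pw @ Hobs) + Robs
        Kg = Pw @ Hobs / S
        w = w + Kg * (z - float(Hobs @ w))
        Pw = Pw - np.outer(Kg, Hobs @ Pw)
        w = Phi @ w + np.concatenate([Gin @ d_prev, [0.0, 0.0]])
        Pw = Phi @ Pw @ Phi.T + Wn
        est[i] = w[2:]
    return PartnerModel(gains=pm.gains, gain_history=pm.gain_history,
                        wrist_estimate=np.column_stack([th_p, thd_p]),
                        target_estimate=est, converged=pm.converged)
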