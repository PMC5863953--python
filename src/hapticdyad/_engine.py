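"""Compiled per-trial simulation kernels.

Each kernel integrates one trial at dt resolution with explicit scalar
arithmetic (closed-form 2x2 Kalman updates, scalar-innovation updates for the
partner-goal filter), which keeps a full synthetic experiment of hundreds of
trials in the seconds range.  All randomness is pre-drawn in the wrappers and
passed in as per-agent noise arrays, so that swapping agent labels swaps the
outputs exactly.

State conventions (radians):
  main filter   xh = estimate of [theta - t, theta' - t'] (tracking error)
  goal filter   w  = [partner's internal error estimate (2), target state (2)]
"""

import numpy as np
from numba import njit

__all__ = ["solo_trial", "haptic_trial", "fl_trial", "goal_trial"]


@njit(cache=True)
def _upd2(x, P, z0, z1, r0, r1):
    """Kalman update with H = I2 and R = diag(r0, r1), in place."""
    s00 = P[0, 0] + r0
    s01 = P[0, 1]
    s10 = P[1, 0]
    s11 = P[1, 1] + r1
    det = s00 * s11 - s01 * s10
    i00 = s11 / det
    i01 = -s01 / det
    i10 = -s10 / det
    i11 = s00 / det
    k00 = P[0, 0] * i00 + P[0, 1] * i10
    k01 = P[0, 0] * i01 + P[0, 1] * i11
    k10 = P[1, 0] * i00 + P[1, 1] * i10
    k11 = P[1, 0] * i01 + P[1, 1] * i11
    y0 = z0 - x[0]
    y1 = z1 - x[1]
    x[0] += k00 * y0 + k01 * y1
    x[1] += k10 * y0 + k11 * y1
    a00 = 1.0 - k00
    a01 = -k01
    a10 = -k10
    a11 = 1.0 - k11
    p00 = a00 * P[0, 0] + a01 * P[1, 0]
    p01 = a00 * P[0, 1] + a01 * P[1, 1]
    p10 = a10 * P[0, 0] + a11 * P[1, 0]
    p11 = a10 * P[0, 1] + a11 * P[1, 1]
    P[0, 0] = p00
    P[0, 1] = p01
    P[1, 0] = p10
    P[1, 1] = p11


@njit(cache=True)
def _upd_row(x, P, h0, h1, z, r):
    """Scalar-row Kalman update with H = [h0, h1], in place (2-state)."""
    ph0 = P[0, 0] * h0 + P[0, 1] * h1
    ph1 = P[1, 0] * h0 + P[1, 1] * h1
    s = h0 * ph0 + h1 * ph1 + r
    k0 = ph0 / s
    k1 = ph1 / s
    y = z - (h0 * x[0] + h1 * x[1])
    x[0] += k0 * y
    x[1] += k1 * y
    p00 = P[0, 0] - k0 * ph0
    p01 = P[0, 1] - k0 * ph1
    p10 = P[1, 0] - k1 * ph0
    p11 = P[1, 1] - k1 * ph1
    P[0, 0] = p00
    P[0, 1] = p01
    P[1, 0] = p10
    P[1, 1] = p11


@njit(cache=True)
def _pred2(x, P, dt, u_over_I, w11):
    """Predict for the error-state filter: x <- A x + B u, P <- A P A' + W."""
    x[0] += x[1] * dt
    x[1] += u_over_I * dt
    p00 = P[0, 0] + dt * (P[1, 0] + P[0, 1]) + dt * dt * P[1, 1]
    p01 = P[0, 1] + dt * P[1, 1]
    p10 = P[1, 0] + dt * P[1, 1]
    p11 = P[1, 1] + w11
    P[0, 0] = p00 + 1e-12
    P[0, 1] = p01
    P[1, 0] = p10
    P[1, 1] = p11


@njit(cache=True)
def _upd4(w, Pw, h, z, r):
    """Scalar-innovation Kalman update of the 4-state goal filter."""
    ph = np.zeros(4)
    for i in range(4):
        acc = 0.0
        for j in range(4):
            acc += Pw[i, j] * h[j]
        ph[i] = acc
    s = r
    for i in range(4):
        s += h[i] * ph[i]
    y = z
    for i in range(4):
        y -= h[i] * w[i]
    for i in range(4):
        w[i] += ph[i] / s * y
    for i in range(4):
        for j in range(4):
            Pw[i, j] -= ph[i] * ph[j] / s


@njit(cache=True)
def _pred4(w, Pw, Phi, Wn, in0, in1):
    """Predict of the goal filter: w <- Phi w + [in0, in1, 0, 0]."""
    nw = np.zeros(4)
    for i in range(4):
        acc = 0.0
        for j in range(4):
            acc += Phi[i, j] * w[j]
        nw[i] = acc
    nw[0] += in0
    nw[1] += in1
    for i in range(4):
        w[i] = nw[i]
    tmp = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            acc = 0.0
            for k in range(4):
                acc += Phi[i, k] * Pw[k, j]
            tmp[i, j] = acc
    for i in range(4):
        for j in range(4):
            acc = 0.0
            for k in range(4):
                acc += tmp[i, k] * Phi[j, k]
            Pw[i, j] = acc + Wn[i, j]


@njit(cache=True)
def solo_trial(tp, tv, noise, Lp, Lv, dt, inertia, sv, svel, smu2,
               err, u_out):
    """Solo visual tracking; fills wrist-error and command time series."""
    n = tp.shape[0]
    th = 0.0
    thd = 0.0
    x = np.zeros(2)
    P = np.zeros((2, 2))
    P[0, 0] = sv * sv
    P[1, 1] = svel * svel
    w11 = dt * dt * smu2
    for i in range(n):
        _upd2(x, P, th - tp[i] + noise[i, 0], thd - tv[i] + noise[i, 1],
              sv * sv, svel * svel)
        u = -(Lp * x[0] + Lv * x[1])
        err[i] = th - tp[i]
        u_out[i] = u
        th += thd * dt
        thd += u * dt / inertia
        _pred2(x, P, dt, u / inertia, w11)


@njit(cache=True)
def haptic_trial(tp, tv, fnoise, K, D, r_force, Lp, Lv, dt, inertia, smu2,
                 err, u_out):
    """Haptic-only tracking: the wrist is coupled to the invisible target by
    the spring; the felt force is the only informative channel."""
    n = tp.shape[0]
    th = 0.0
    thd = 0.0
    x = np.zeros(2)
    P = np.zeros((2, 2))
    P[0, 0] = 0.05
    P[1, 1] = 0.02
    w11 = dt * dt * smu2
    for i in range(n):
        F = K * (tp[i] - th) + D * (tv[i] - thd)
        Fm = F + fnoise[i]
        # measurement model: F = -K x0 - D x1
        _upd_row(x, P, -K, -D, Fm, r_force)
        u = -(Lp * x[0] + Lv * x[1]) - Fm
        err[i] = th - tp[i]
        u_out[i] = u
        th += thd * dt
        thd += (u + F) * dt / inertia
        _pred2(x, P, dt, (u + F) / inertia, w11)


@njit(cache=True)
def fl_trial(tp, tv, noise1, noise2, K, D, Lp, Lv, dt, inertia,
             sv1, sv2, svel1, svel2, smu2, flp2, flv2,
             err, u_out, follow):
    """Follow-the-leader dyad.

    Per step each agent tracks the target visually if its own wrist is at
    least as close to the target as the partner's (inclusive tie), and
    otherwise locks onto the partner's wrist (known through the interaction
    force) as if it were the target.
    """
    n = tp.shape[0]
    th = np.zeros(2)
    thd = np.zeros(2)
    x = np.zeros((2, 2))
    P = np.zeros((2, 2, 2))
    sv = np.array([sv1, sv2])
    svel = np.array([svel1, svel2])
    for a in range(2):
        P[a, 0, 0] = sv[a] * sv[a]
        P[a, 1, 1] = svel[a] * svel[a]
    w11 = dt * dt * smu2
    u = np.zeros(2)
    for i in range(n):
        F1 = K * (th[1] - th[0]) + D * (thd[1] - thd[0])
        for a in range(2):
            b = 1 - a
            Fa = F1 if a == 0 else -F1
            nz = noise1 if a == 0 else noise2
            if abs(th[a] - tp[i]) <= abs(th[b] - tp[i]):
                _upd2(x[a], P[a], th[a] - tp[i] + nz[i, 0],
                      thd[a] - tv[i] + nz[i, 1], sv[a] * sv[a],
                      svel[a] * svel[a])
                follow[a, i] = 0.0
            else:
                _upd2(x[a], P[a], th[a] - th[b], thd[a] - thd[b], flp2, flv2)
                follow[a, i] = 1.0
            u[a] = -(Lp * x[a, 0] + Lv * x[a, 1]) - Fa
            err[a, i] = th[a] - tp[i]
            u_out[a, i] = u[a]
        for a in range(2):
            Fa = F1 if a == 0 else -F1
            th[a] += thd[a] * dt
            thd[a] += (u[a] + Fa) * dt / inertia
            _pred2(x[a], P[a], dt, (u[a] + Fa) / inertia, w11)


@njit(cache=True)
def goal_trial(tp, tv, noise1, noise2, K, D, Lp, Lv, dt, inertia,
               sv1, sv2, svel1, svel2, smu2,
               rg_pos1, rg_vel1, rg_pos2, rg_vel2,
               goal_every, burn_steps,
               Phi1, Phi2, Gin1, Gin2, Hobs1, Hobs2, Robs1, Robs2,
               Wn1, Wn2, LG1, LG2, w0,
               err, u_out, t_inf):
    """Goal-integration / neuromechanical goal-sharing dyad.

    Each agent runs (a) a visual error-state filter and (b) a 4-state linear
    goal filter over [partner's internal error estimate, target state],
    observed through the partner's wrist acceleration (exactly known through
    the noiseless interaction force and force cancellation).  After the
    burn-in the inferred partner goal is fused into the error-state filter
    every ``goal_every`` steps at the claimed haptic-channel variance
    rg_pos/rg_vel (= partner visual variance + stiffness noise sigma_s^2);
    the two strategies differ only in sigma_s^2.
    """
    n = tp.shape[0]
    th = np.zeros(2)
    thd = np.zeros(2)
    x = np.zeros((2, 2))
    P = np.zeros((2, 2, 2))
    sv = np.array([sv1, sv2])
    svel = np.array([svel1, svel2])
    for a in range(2):
        P[a, 0, 0] = sv[a] * sv[a]
        P[a, 1, 1] = svel[a] * svel[a]
    w = np.zeros((2, 4))
    Pw = np.zeros((2, 4, 4))
    for a in range(2):
        b = 1 - a
        w[a, 2] = w0[0]
        w[a, 3] = w0[1]
        Pw[a, 0, 0] = sv[b] * sv[b]
        Pw[a, 1, 1] = svel[b] * svel[b]
        Pw[a, 2, 2] = 0.05
        Pw[a, 3, 3] = 0.02
    w11 = dt * dt * smu2
    u = np.zeros(2)
    prev_thd = np.zeros(2)
    prev_d = np.zeros((2, 2))
    for i in range(n):
        F1 = K * (th[1] - th[0]) + D * (thd[1] - thd[0])
        for a in range(2):
            b = 1 - a
            Fa = F1 if a == 0 else -F1
            nz = noise1 if a == 0 else noise2
            Phi = Phi1 if a == 0 else Phi2
            Gin = Gin1 if a == 0 else Gin2
            Hob = Hobs1 if a == 0 else Hobs2
            Rob = Robs1 if a == 0 else Robs2
            Wn = Wn1 if a == 0 else Wn2
            LG = LG1 if a == 0 else LG2
            if i >= 1:
                c = (thd[b] - prev_thd[a]) / dt
                zeq = c + LG[0] * prev_d[a, 0] + LG[1] * prev_d[a, 1]
                _upd4(w[a], Pw[a], Hob, zeq, Rob)
                in0 = Gin[0, 0] * prev_d[a, 0] + Gin[0, 1] * prev_d[a, 1]
                in1 = Gin[1, 0] * prev_d[a, 0] + Gin[1, 1] * prev_d[a, 1]
                _pred4(w[a], Pw[a], Phi, Wn, in0, in1)
            _upd2(x[a], P[a], th[a] - tp[i] + nz[i, 0],
                  thd[a] - tv[i] + nz[i, 1], sv[a] * sv[a], svel[a] * svel[a])
            if i >= burn_steps and i % goal_every == 0:
                rg0 = rg_pos1 if a == 0 else rg_pos2
                rg1 = rg_vel1 if a == 0 else rg_vel2
                _upd2(x[a], P[a], th[a] - w[a, 2], thd[a] - w[a, 3], rg0, rg1)
            u[a] = -(Lp * x[a, 0] + Lv * x[a, 1]) - Fa
            err[a, i] = th[a] - tp[i]
            u_out[a, i] = u[a]
            t_inf[a, i] = w[a, 2] - tp[i]
        for a in range(2):
            b = 1 - a
            prev_thd[a] = thd[b]
            prev_d[a, 0] = th[b]
            prev_d[a, 1] = thd[b]
        for a in range(2):
            Fa = F1 if a == 0 else -F1
            th[a] += thd[a] * dt
            thd[a] += (u[a] + Fa) * dt / inertia
            _pred2(x[a], P[a], dt, (u[a] + Fa) / inertia, w11)
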