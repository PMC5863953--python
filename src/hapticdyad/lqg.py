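"""Shared estimation/control layer: infinite-horizon discrete LQR gains and
Kalman filtering over the tracking-error state.

The controller minimises J = sum x' (qQ) x + u' R u for the double-integrator
error dynamics; certainty equivalence puts the resulting gain [L_p, L_v] on
the estimated error state.  The filter utilities here are the generic
building blocks; the per-strategy observation models live in
:mod:`hapticdyad.strategies` and the compiled engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_are

from .config import SimConfig
from .dynamics import transition_matrix, input_matrix

__all__ = [
    "ControllerParams",
    "FilterState",
    "solve_lqr",
    "kalman_step",
    "kalman_steady_gain",
    "compensate_delay",
    "controller_for",
]


@dataclass(frozen=True)
class ControllerParams:
    """LQR solution for the 2-state error plant."""

    L: np.ndarray        # feedback gain [L_p, L_v]
    P: np.ndarray        # Riccati solution
    q: float
    R: float

    @property
    def L_p(self) -> float:
        return float(self.L[0])

    @property
    def L_v(self) -> float:
        return float(self.L[1])


@dataclass
class FilterState:
    """Mean/covariance pair of a Kalman filter, plus innovation diagnostics."""

    mean: np.ndarray
    cov: np.ndarray
    innovations: list = field(default_factory=list)

    def copy(self) -> "FilterState":
        return FilterState(self.mean.copy(), self.cov.copy(),
                           list(self.innovations))


def solve_lqr(A: np.ndarray, B: np.ndarray, q: float, Q: np.ndarray,
              R: float) -> ControllerParams:
    """Stationary discrete LQR gain via the algebraic Riccati equation.

    Raises a ValueError naming the offending matrix for indefinite costs or a
    non-stabilizable pair.
    """
    if q <= 0 or R <= 0:
        raise ValueError(f"q and R must be positive (q={q}, R={R})")
    Qq = q * np.asarray(Q, dtype=float)
    if np.any(np.linalg.eigvalsh(Qq) < -1e-12):
        raise ValueError("state cost Q is indefinite")
    try:
        P = solve_discrete_are(A, B, Qq, np.atleast_2d(R))
    except np.linalg.LinAlgError as e:  # pragma: no cover - scipy detail
        raise ValueError(f"(A, B) pair not stabilizable: {e}") from e
    L = np.linalg.solve(np.atleast_2d(R) + B.T @ P @ B, B.T @ P @ A)
    rho = np.max(np.abs(np.linalg.eigvals(A - B @ L)))
    if rho >= 1.0:
        raise ValueError(f"closed loop not stable (spectral radius {rho:.4f})")
    return ControllerParams(L=L.ravel(), P=P, q=q, R=R)


def controller_for(cfg: SimConfig) -> ControllerParams:
    """The configuration's controller."""
    A = transition_matrix(cfg.dt)
    B = input_matrix(cfg.dt, cfg.inertia)
    return solve_lqr(A, B, cfg.q, np.diag([cfg.Q_pos, cfg.Q_vel]), cfg.R)


def kalman_step(f: FilterState, A: np.ndarray, W: np.ndarray,
                H: np.ndarray, R: np.ndarray, z: np.ndarray,
                u_effect: np.ndarray | None = None) -> FilterState:
    """One predict/update cycle.  Non-finite observations (dropped display
    frames) skip the update and are flagged with a NaN innovation."""
    H = np.atleast_2d(H)
    R = np.atleast_2d(R)
    z = np.atleast_1d(z)
    # predict
    mean = A @ f.mean
    if u_effect is not None:
        mean = mean + u_effect
    cov = A @ f.cov @ A.T + W
    out = FilterState(mean, cov, list(f.innovations))
    if not np.all(np.isfinite(z)):
        out.innovations.append(np.full(len(z), np.nan))
        return out
    # update
    S = H @ cov @ H.T + R
    K = cov @ H.T @ np.linalg.inv(S)
    innov = z - H @ mean
    out.mean = mean + K @ innov
    out.cov = (np.eye(len(mean)) - K @ H) @ cov
    out.innovations.append(innov)
    return out


def kalman_steady_gain(A: np.ndarray, W: np.ndarray, H: np.ndarray,
                       R: np.ndarray) -> np.ndarray:
    """Stationary Kalman gain by solving the filter Riccati equation
    (duality with the control ARE)."""
    H = np.atleast_2d(H)
    R = np.atleast_2d(R)
    P = solve_discrete_are(A.T, H.T, W, R)
    return P @ H.T @ np.linalg.inv(H @ P @ H.T + R)


def compensate_delay(f: FilterState, delay: float, A: np.ndarray,
                     dt: float) -> np.ndarray:
    """Propagate the estimate forward through the noise-free state equation
    to compensate a known sensory delay (an integer multiple of dt)."""
    if delay < 0:
        raise ValueError("delay must be non-negative")
    k = int(round(delay / dt))
    if abs(k * dt - delay) > 1e-9:
        raise ValueError(f"delay {delay} is not a multiple of dt={dt}")
    return np.linalg.matrix_power(A, k) @ f.mean
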