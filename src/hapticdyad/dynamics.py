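"""Discrete-time state equations: target process model, wrist plant, elastic
coupling, and the combined tracking-error state.

The integration scheme is the explicit first-order one the model is defined
with — the discrete system IS the model, so no adaptive integrator is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TargetProcessModel",
    "WristPlant",
    "CouplingSpec",
    "coupling_force",
    "step_plant",
    "step_target_model",
    "simulate_error_state",
    "transition_matrix",
    "input_matrix",
]


def transition_matrix(dt: float) -> np.ndarray:
    """A = [[1, dt], [0, 1]] — shared by target, wrist and error state."""
    return np.array([[1.0, dt], [0.0, 1.0]])


def input_matrix(dt: float, inertia: float) -> np.ndarray:
    """B = [0, dt/I]^T."""
    return np.array([[0.0], [dt / inertia]])


@dataclass
class TargetProcessModel:
    """Internal model of the target: integrator driven by Gaussian
    acceleration noise mu ~ N(0, sigma_mu2)."""

    dt: float
    sigma_mu2: float

    @property
    def A(self) -> np.ndarray:
        return transition_matrix(self.dt)

    def process_cov(self) -> np.ndarray:
        """Per-step state covariance increment: velocity receives dt*mu."""
        return np.diag([0.0, self.dt ** 2 * self.sigma_mu2])


@dataclass
class WristPlant:
    """Rigid wrist of inertia I driven by muscle torque u plus spring force F."""

    inertia: float
    angle: float = 0.0       # rad
    velocity: float = 0.0    # rad/s

    def state(self) -> np.ndarray:
        return np.array([self.angle, self.velocity])


@dataclass(frozen=True)
class CouplingSpec:
    """Virtual elastic band between the two wrists (or wrist and target)."""

    stiffness: float  # K, Nm/rad
    damping: float    # D, Nm s/rad

    def __post_init__(self):
        if self.stiffness < 0 or self.damping < 0:
            raise ValueError("stiffness and damping must be non-negative")

    @property
    def solo(self) -> bool:
        return self.stiffness == 0.0 and self.damping == 0.0


SOLO = CouplingSpec(0.0, 0.0)


def coupling_force(own_angle: float, own_vel: float,
                   partner_angle: float, partner_vel: float,
                   c: CouplingSpec) -> float:
    """Elastic force on the own wrist: F = K (th~ - th) + D (th~' - th').

    Antisymmetric by construction — the partner feels the negated value.
    """
    return (c.stiffness * (partner_angle - own_angle)
            + c.damping * (partner_vel - own_vel))


def step_plant(plant: WristPlant, u: float, F: float, dt: float) -> WristPlant:
    """One explicit Euler step of the wrist: angle += vel dt, vel += (u+F) dt/I."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(u) and np.isfinite(F)):
        raise FloatingPointError(f"non-finite torque in plant step: u={u}, F={F}")
    return WristPlant(inertia=plant.inertia,
                      angle=plant.angle + plant.velocity * dt,
                      velocity=plant.velocity + (u + F) * dt / plant.inertia)


def step_target_model(model: TargetProcessModel, state: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """One step of the stochastic target model: position integrates velocity,
    velocity receives a dt-scaled Gaussian acceleration kick."""
    mu = rng.normal(0.0, np.sqrt(model.sigma_mu2)) if model.sigma_mu2 > 0 else 0.0
    return model.A @ state + np.array([0.0, model.dt * mu])


def simulate_error_state(n: int, dt: float, inertia: float,
                         u: np.ndarray, F: np.ndarray, mu: np.ndarray,
                         x0=(0.0, 0.0)) -> np.ndarray:
    """Directly integrate the combined error state
    x_{i+1} = A x_i + B (u_i + F_i) - [0, dt] mu_i.

    Equivalent, step for step, to simulating wrist and target separately on
    the same noise draws and subtracting — the property tests assert this.
    """
    A = transition_matrix(dt)
    B = input_matrix(dt, inertia).ravel()
    x = np.array(x0, dtype=float)
    out = np.empty((n, 2))
    for i in range(n):
        out[i] = x
        x = A @ x + B * (u[i] + F[i]) - np.array([0.0, dt * mu[i]])
    return out
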