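"""Synthetic generators with known ground truth.

Three processes cover what the estimators assume: stationary AR(1) energy
traces (closed-form SEM of the mean, so blocking has an analytic oracle), a
hidden two-state Markov loop process with a state-dependent energy offset and
wrapped dihedral emissions, and noisy experiment/prediction pairs for the
benchmark metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .io_formats import EnergySeries
from .loop_dynamics import DihedralSeries, StateTrace, ZA1, ZA2


@dataclass(frozen=True)
class LegGeneratorConfig:
    """AR(1) energy-trace generator settings for one leg."""

    mu: float
    sigma: float
    rho: float
    n_frames: int
    n_replicas: int = 20
    dt: float = 10.0  # ps
    leg: str = "complex"
    system_id: str = "SYNTH"
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1) for stationarity")
        if self.n_frames < 1 or self.n_replicas < 1:
            raise ValueError("n_frames and n_replicas must be >= 1")


def ar1_mean_sem(sigma: float, rho: float, n: int) -> float:
    """Closed-form SEM of the mean of a stationary AR(1) series.

    Var(x̄) ≈ sigma² (1+rho) / ((1-rho) n) for n ≫ correlation time.
    """
    return sigma * np.sqrt((1.0 + rho) / ((1.0 - rho) * n))


def _ar1_values(rng: np.random.Generator, mu: float, sigma: float, rho: float, n: int) -> np.ndarray:
    # eps[0] carries the full stationary sd so the chain starts in equilibrium
    eps = rng.normal(0.0, sigma * np.sqrt(1.0 - rho * rho), size=n)
    if n > 0 and sigma > 0:
        eps[0] = rng.normal(0.0, sigma)
    return mu + lfilter([1.0], [1.0, -rho], eps)


def generate_ar1_leg(config: LegGeneratorConfig) -> list[EnergySeries]:
    """One stationary AR(1) EnergySeries per replica.

    Replica streams are independent and reproducible: replica i uses seed
    ``config.seed + i``.
    """
    out = []
    for replica_id in range(config.n_replicas):
        rng = np.random.default_rng(config.seed + replica_id)
        values = _ar1_values(rng, config.mu, config.sigma, config.rho, config.n_frames)
        out.append(
            EnergySeries(
                values=values,
                dt=config.dt,
                leg=config.leg,
                replica_id=replica_id,
                system_id=config.system_id,
            )
        )
    return out


@dataclass(frozen=True)
class TwoStateConfig:
    """Hidden two-state Markov loop process with dihedral emissions."""

    k12: float = 0.01  # per-frame P(ZA1 -> ZA2)
    k21: float = 0.001  # per-frame P(ZA2 -> ZA1)
    delta_E: float = 0.0  # energy offset added while in ZA2, kcal/mol
    psi_means: tuple[float, float] = (50.0, -40.0)  # (ZA1, ZA2) degrees
    phi_means: tuple[float, float] = (-150.0, -60.0)
    kappa: float = 50.0  # von Mises concentration
    start_state: str = ZA1
    seed: int = 0

    def __post_init__(self):
        for k in (self.k12, self.k21):
            if not (0.0 <= k <= 1.0):
                raise ValueError("switching probabilities must lie in [0, 1]")
        for angle in (*self.psi_means, *self.phi_means):
            if not (-180.0 < angle <= 180.0):
                raise ValueError("emission centers must lie in (-180, 180]")
        if self.start_state not in (ZA1, ZA2):
            raise ValueError(f"start_state must be {ZA1!r} or {ZA2!r}")


def wrap_angle(angles):
    """Wrap angles (degrees) into (-180, 180]."""
    wrapped = np.mod(np.asarray(angles, float) + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def _markov_chain(rng: np.random.Generator, k12: float, k21: float, start: int, n: int) -> np.ndarray:
    u = rng.random(n)
    states = np.empty(n, dtype=np.int8)
    s = start
    states[0] = s  # frame 0 is the start state; switching begins at frame 1
    for t in range(1, n):
        if s == 0:
            if u[t] < k12:
                s = 1
        else:
            if u[t] < k21:
                s = 0
        states[t] = s
    return states


def generate_two_state_system(
    leg_config: LegGeneratorConfig, state_config: TwoStateConfig
) -> tuple[EnergySeries, StateTrace, DihedralSeries, DihedralSeries]:
    """Frame-aligned (energy, hidden states, psi, phi) for one replica.

    Energy is the AR(1) base plus ``delta_E`` while the hidden chain is in
    ZA2; dihedrals are von Mises draws around the per-state centers, wrapped
    into (-180, 180].
    """
    rng = np.random.default_rng(state_config.seed)
    n = leg_config.n_frames
    start = 0 if state_config.start_state == ZA1 else 1
    states = _markov_chain(rng, state_config.k12, state_config.k21, start, n)

    base = _ar1_values(rng, leg_config.mu, leg_config.sigma, leg_config.rho, n)
    energy = base + state_config.delta_E * states

    kappa = state_config.kappa
    psi_centers = np.radians(np.asarray(state_config.psi_means))[states]
    phi_centers = np.radians(np.asarray(state_config.phi_means))[states]
    psi = wrap_angle(np.degrees(rng.vonmises(psi_centers, kappa)))
    phi = wrap_angle(np.degrees(rng.vonmises(phi_centers, kappa)))

    labels = np.where(states == 0, ZA1, ZA2)
    dt = leg_config.dt
    return (
        EnergySeries(values=energy, dt=dt, leg=leg_config.leg, system_id=leg_config.system_id),
        StateTrace(labels=labels, dt=dt),
        DihedralSeries(angles=psi, definition="psi hinge (N-CA-C-N)", dt=dt),
        DihedralSeries(angles=phi, definition="phi hinge (C-N-CA-C)", dt=dt),
    )


def generate_benchmark_pairs(true_values, noise_sd: float, seed: int = 0):
    """(experimental, predicted) pairs: predicted = true + N(0, noise_sd)."""
    import pandas as pd

    true_values = np.asarray(true_values, dtype=float)
    if true_values.size == 0:
        raise ValueError("true_values must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    predicted = true_values + rng.normal(0.0, noise_sd, size=true_values.size) if noise_sd > 0 else true_values.copy()
    return pd.DataFrame({"experimental": true_values, "predicted": predicted})
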