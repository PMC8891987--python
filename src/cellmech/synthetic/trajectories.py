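"""Persistent-random-walk trajectory generator.

Cell paths are sampled from a 2D Ornstein–Uhlenbeck velocity process, the
continuum model whose ensemble mean-squared displacement is the Fürth form

    MSD(t) = 4 D [ t - tau (1 - exp(-t / tau)) ]

with diffusion coefficient D (µm²/min) and persistence time tau (min).
Each component of velocity is OU with stationary variance D/tau and
correlation time tau; positions are the exact time integral of velocity.

The update over one sampling interval dt uses the exact joint Gaussian
transition of (position increment, velocity) — not an Euler step — so the
Fürth form holds at the discrete sampling times for any dt, removing
step-size bias from downstream fits.
"""

from __future__ import annotations

import numpy as np

from ..migration import Trajectory

__all__ = ["generate_prw_trajectory", "generate_prw_ensemble", "furth_msd"]


def furth_msd(t, D: float, tau: float):
    """Closed-form 2D persistent-random-walk MSD, 4D[t − τ(1 − e^(−t/τ))]."""
    t = np.asarray(t, dtype=float)
    return 4.0 * D * (t - tau * (1.0 - np.exp(-t / tau)))


def _step_cholesky(D: float, tau: float, dt: float) -> np.ndarray:
    """Cholesky factor of the exact (dx, v) transition covariance per component.

    With theta = dt/tau, E = exp(-theta) and sigma^2 = D/tau:
        Var(dx) = sigma^2 tau^2 (2 theta - 3 + 4E - E^2)
        Var(v)  = sigma^2 (1 - E^2)
        Cov     = sigma^2 tau (1 - E)^2
    """
    theta = dt / tau
    E = np.exp(-theta)
    s2 = D / tau
    var_x = s2 * tau**2 * (2 * theta - 3 + 4 * E - E**2)
    var_v = s2 * (1 - E**2)
    cov = s2 * tau * (1 - E) ** 2
    c = np.array([[var_x, cov], [cov, var_v]])
    # D = 0 gives the zero matrix; cholesky of a PSD 2x2 by hand
    l11 = np.sqrt(max(var_x, 0.0))
    l21 = cov / l11 if l11 > 0 else 0.0
    l22 = np.sqrt(max(var_v - l21**2, 0.0))
    del c
    return np.array([[l11, 0.0], [l21, l22]])


def generate_prw_ensemble(
    n_tracks: int,
    D: float,
    tau: float,
    dt: float,
    n_steps: int,
    seed: int | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> list[Trajectory]:
    """Sample ``n_tracks`` independent persistent random walks.

    Velocities start in the stationary distribution, so increments are
    stationary and the ensemble MSD matches the Fürth form at every lag.

    Parameters are in the pipeline's native units: D in µm²/min, tau and dt
    in min. Each track has ``n_steps + 1`` samples at times 0, dt, ..., n_steps*dt.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    if not tau > 0:
        raise ValueError("tau must be positive")
    if not dt > 0:
        raise ValueError("dt must be positive")
    if n_steps < 1:
        raise ValueError("need at least one step")

    rng = np.random.default_rng(seed)
    E = np.exp(-dt / tau)
    decay_x = tau * (1.0 - E)  # deterministic position kick per unit velocity
    L = _step_cholesky(D, tau, dt)
    sigma_v = np.sqrt(D / tau)

    v = rng.normal(0.0, sigma_v, size=(n_tracks, 2)) if D > 0 else np.zeros((n_tracks, 2))
    pos = np.empty((n_tracks, n_steps + 1, 2))
    pos[:, 0, :] = origin
    noise = rng.standard_normal(size=(n_steps, n_tracks, 2, 2))
    for k in range(n_steps):
        eta = noise[k] @ L.T  # (..., [eta_x, eta_v]) per component
        pos[:, k + 1, :] = pos[:, k, :] + decay_x * v + eta[..., 0]
        v = E * v + eta[..., 1]

    t = np.arange(n_steps + 1) * dt
    return [
        Trajectory(track_id=i, t=t.copy(), x=pos[i, :, 0], y=pos[i, :, 1])
        for i in range(n_tracks)
    ]


def generate_prw_trajectory(
    D: float,
    tau: float,
    dt: float,
    n_steps: int,
    seed: int | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """A single persistent-random-walk track (see :func:`generate_prw_ensemble`)."""
    return generate_prw_ensemble(1, D, tau, dt, n_steps, seed=seed, origin=origin)[0]
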