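"""Synthetic AFM indentation curves following Hertzian spherical contact.

Force is zero on the approach before contact and follows
F = (4/3) (E / (1 - nu^2)) sqrt(r) delta^(3/2) beyond the contact point,
with optional additive Gaussian force noise. All quantities are SI
(metres, newtons, pascals), matching the CSV interchange format.
"""

from __future__ import annotations

import numpy as np

from ..afm import ForceCurve, ForceMap, hertz_force

__all__ = ["generate_hertz_curve", "generate_force_map"]


def generate_hertz_curve(
    E: float,
    nu: float,
    r: float,
    contact_point: float,
    z_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    baseline: float = 0.0,
) -> ForceCurve:
    """Hertzian approach curve on ``z_grid`` (m), contact at ``contact_point``.

    ``z`` increases into the sample, so indentation is delta = z - contact_point
    where positive. ``noise_sd`` is the SD of additive Gaussian force noise (N).
    """
    if not E > 0:
        raise ValueError("E must be positive")
    if not 0 <= nu < 0.5:
        raise ValueError("nu must be in [0, 0.5)")
    if not r > 0:
        raise ValueError("tip radius must be positive")
    z = np.asarray(z_grid, dtype=float)
    if z.ndim != 1 or len(z) < 2 or not np.all(np.diff(z) > 0):
        raise ValueError("z_grid must be strictly increasing 1D")
    delta = np.clip(z - contact_point, 0.0, None)
    force = baseline + hertz_force(E, nu, r, delta)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    return ForceCurve(z=z, force=force, contact_point=contact_point)


def generate_force_map(
    n_curves: int,
    E: float,
    nu: float,
    r: float,
    z_span: float = 2e-6,
    n_points: int = 400,
    contact_fraction: float = 0.4,
    noise_sd: float = 0.0,
    seed: int | None = None,
    cell_id: str = "cell",
) -> ForceMap:
    """A force map of ``n_curves`` curves on one cell with a common modulus.

    Emulates the acquisition geometry of a 100-curve map with a 2 µm force
    distance: each curve shares the z span but gets an independent noise
    realization and a slightly jittered contact point.
    """
    if n_curves < 1:
        raise ValueError("need at least one curve")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, z_span, n_points)
    curves = []
    for i in range(n_curves):
        cp = contact_fraction * z_span * (1.0 + 0.05 * rng.standard_normal())
        cp = float(np.clip(cp, 0.05 * z_span, 0.8 * z_span))
        curves.append(
            generate_hertz_curve(
                E, nu, r, cp, z, noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return ForceMap(curves=curves, cell_id=cell_id)
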