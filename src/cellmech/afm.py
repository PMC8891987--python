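"""Hertz-model analysis of AFM force curves and force maps.

The spherical-tip Hertz contact law

    F = (4/3) * (E / (1 - nu^2)) * sqrt(r) * delta^(3/2)

relates indentation delta to force for a tip of radius r on a sample of
Young's modulus E and Poisson's ratio nu (0.45 for cells here, tip radius
about 30 nm). Fitting treats the contact point z0 and a force baseline as
free parameters jointly with E: pre-detecting the contact by thresholding
biases E on soft samples, so the contact point is estimated, not detected.

A force map is a grid of curves acquired on one cell (100 curves over a
5 µm² region in the emulated acquisition); the map aggregates per-curve
moduli into a single per-cell value, by default the median, which is robust
to the occasional stiff outlier from glass-proximity or debris.
All quantities are SI: metres, newtons, pascals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateDataError, NoContactError

__all__ = [
    "ForceCurve",
    "ForceMap",
    "HertzParams",
    "HertzFit",
    "ForceMapResult",
    "hertz_force",
    "fit_hertz",
    "aggregate_force_map",
    "force_curve_from_deflection",
    "read_force_curve",
    "write_force_curve",
]


@dataclass
class ForceCurve:
    """An approach force curve: z-piezo positions (m, increasing into the
    sample) and measured force (N)."""

    z: np.ndarray
    force: np.ndarray
    contact_point: float | None = None  # known ground truth, if any

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.z) != len(self.force):
            raise ValueError("z and force must have equal length")
        if len(self.z) < 20:
            raise ValueError("force curve needs at least 20 samples")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing (approach)")

    @property
    def n_samples(self) -> int:
        return len(self.z)


@dataclass
class ForceMap:
    """A set of force curves acquired on a single cell."""

    curves: list[ForceCurve]
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if len(self.curves) < 1:
            raise ValueError("force map needs at least one curve")


@dataclass(frozen=True)
class HertzParams:
    """Fixed contact parameters: Poisson's ratio, tip radius, trigger force."""

    nu: float = 0.45
    r: float = 30e-9
    trigger_force: float = 1.35e-9

    def __post_init__(self) -> None:
        if not 0 <= self.nu < 0.5:
            raise ValueError("nu must be in [0, 0.5)")
        if not self.r > 0:
            raise ValueError("tip radius must be positive")


@dataclass
class HertzFit:
    """Fitted Young's modulus with contact point and diagnostics."""

    E: float  # Pa
    contact_point: float  # m
    baseline: float  # N
    rss: float
    converged: bool
    n_points: int
    E_stderr: float = field(default=float("nan"))

    def summary(self) -> str:
        return (
            "Hertz fit\n"
            f"  E            = {self.E:.4g} Pa  (se {self.E_stderr:.2g})\n"
            f"  contact z0   = {self.contact_point:.4g} m\n"
            f"  baseline     = {self.baseline:.3g} N\n"
            f"  RSS          = {self.rss:.4g} over {self.n_points} points\n"
            f"  converged: {self.converged}"
        )


@dataclass
class ForceMapResult:
    """Per-cell aggregate over the converged curve fits of a force map."""

    cell_id: str
    E: float  # Pa
    summary_stat: str
    n_curves: int
    n_converged: int
    fits: list[HertzFit]

    @property
    def fraction_nonconverged(self) -> float:
        return 1.0 - self.n_converged / self.n_curves


def hertz_force(E: float, nu: float, r: float, delta) -> np.ndarray | float:
    """Spherical-tip Hertz force (N) at indentation ``delta`` (m).

    Monotone increasing in both delta (as delta^(3/2)) and E. Negative
    indentation is a domain error.
    """
    if not E > 0:
        raise ValueError("E must be positive")
    if not 0 <= nu < 0.5:
        raise ValueError("nu must be in [0, 0.5)")
    if not r > 0:
        raise ValueError("tip radius must be positive")
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation must be non-negative")
    out = (4.0 / 3.0) * (E / (1.0 - nu**2)) * np.sqrt(r) * d**1.5
    return float(out) if np.isscalar(delta) else out


def force_curve_from_deflection(
    z_piezo: np.ndarray, deflection: np.ndarray, spring_constant: float
) -> ForceCurve:
    """Convert raw deflection-vs-piezo data to force vs tip-sample position.

    Force is k*d; the tip-sample coordinate is z_piezo - d, so that
    indentation relative to a fitted contact point is delta = (z - z0) - d
    in the original piezo frame. The converted curve is resampled-free and
    fits with the standard force-vs-z model.
    """
    z = np.asarray(z_piezo, dtype=float)
    d = np.asarray(deflection, dtype=float)
    if not spring_constant > 0:
        raise ValueError("spring constant must be positive")
    z_tip = z - d
    order = np.argsort(z_tip)
    return ForceCurve(z=z_tip[order], force=spring_constant * d[order])


def _initial_guess(curve: ForceCurve, params: HertzParams):
    """Baseline, noise scale and rough contact index for the optimizer start."""
    n = curve.n_samples
    nb = max(5, n // 5)
    baseline = float(np.median(curve.force[:nb]))
    resid = np.diff(curve.force[:nb])
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid)))) / np.sqrt(2)
    rise = curve.force - baseline
    max_rise = float(rise.max())
    if max_rise <= max(10 * noise, 0.0) or max_rise <= 0:
        raise NoContactError("no contact region detected: curve is flat")
    thresh = max(5 * noise, 0.02 * max_rise)
    above = np.nonzero(rise > thresh)[0]
    i0 = int(above[0]) if len(above) else n // 2
    z0 = float(curve.z[max(i0 - 1, 0)])
    delta_end = max(float(curve.z[-1] - z0), float(np.ptp(curve.z)) * 1e-3)
    pref = (4.0 / 3.0) / (1.0 - params.nu**2) * np.sqrt(params.r)
    E0 = max(max_rise / (pref * delta_end**1.5), 1.0)
    return baseline, noise, z0, E0


def fit_hertz(
    curve: ForceCurve,
    params: HertzParams = HertzParams(),
    max_force: float | None = None,
) -> HertzFit:
    """Joint least-squares estimation of (E, contact point, baseline).

    The model is F(z) = baseline + hertz_force(E, max(z - z0, 0)). E is fit
    in log space to enforce positivity across the kPa–GPa range. If
    ``max_force`` is given (e.g. the trigger force), points whose
    baseline-corrected force exceeds it are excluded, emulating a fit
    restricted to the triggered indentation range.

    Raises :class:`NoContactError` when no rise above the noise floor exists.
    """
    baseline0, _, z00, E0 = _initial_guess(curve, params)
    z, f = curve.z, curve.force
    if max_force is not None:
        keep = (f - baseline0) <= max_force
        # never drop pre-contact points; only truncate the deep-indentation tail
        if keep.sum() >= 20:
            z, f = z[keep], f[keep]
    pref = (4.0 / 3.0) / (1.0 - params.nu**2) * np.sqrt(params.r)
    zlo, zhi = float(z[0]), float(z[-1])

    def resid(p):
        logE, z0, b = p
        delta = np.clip(z - z0, 0.0, None)
        return b + pref * np.exp(logE) * delta**1.5 - f

    res = least_squares(
        resid,
        x0=[np.log(E0), np.clip(z00, zlo, zhi), baseline0],
        bounds=([np.log(1e-3), zlo, -np.inf], [np.log(1e12), zhi, np.inf]),
        method="trf",
        x_scale="jac",
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    converged = bool(res.success) and res.status > 0
    rss = float(np.sum(res.fun**2))
    E = float(np.exp(res.x[0]))
    E_se = float("nan")
    try:
        jtj = res.jac.T @ res.jac
        dof = max(len(f) - 3, 1)
        cov = np.linalg.inv(jtj) * rss / dof
        E_se = E * float(np.sqrt(cov[0, 0]))  # delta method from log E
    except np.linalg.LinAlgError:
        pass
    return HertzFit(
        E=E,
        contact_point=float(res.x[1]),
        baseline=float(res.x[2]),
        rss=rss,
        converged=converged,
        n_points=len(f),
        E_stderr=E_se,
    )


_SUMMARIES = {"median": np.median, "mean": np.mean}


def aggregate_force_map(
    fmap: ForceMap,
    params: HertzParams = HertzParams(),
    summary: str = "median",
    max_force: float | None = None,
) -> ForceMapResult:
    """Fit every curve in the map and aggregate converged moduli per cell.

    Curves that raise a no-contact error or fail to converge are excluded
    from the aggregate and counted in the non-convergence fraction. Raises
    :class:`DegenerateDataError` if no curve yields a converged fit.
    """
    if summary not in _SUMMARIES:
        raise ValueError(f"summary must be one of {sorted(_SUMMARIES)}")
    fits = []
    good = []
    for c in fmap.curves:
        try:
            fit = fit_hertz(c, params, max_force=max_force)
        except NoContactError:
            continue
        fits.append(fit)
        if fit.converged:
            good.append(fit.E)
    if not good:
        raise DegenerateDataError("no converged Hertz fit in the force map")
    return ForceMapResult(
        cell_id=fmap.cell_id,
        E=float(_SUMMARIES[summary](good)),
        summary_stat=summary,
        n_curves=len(fmap.curves),
        n_converged=len(good),
        fits=fits,
    )


def write_force_curve(curve: ForceCurve, path: str | Path) -> None:
    pd.DataFrame({"z_m": curve.z, "force_N": curve.force}).to_csv(path, index=False)


def read_force_curve(path: str | Path) -> ForceCurve:
    df = pd.read_csv(path)
    if {"z_m", "force_N"}.issubset(df.columns):
        return ForceCurve(df["z_m"].values, df["force_N"].values)
    raise ValueError("force-curve CSV must have columns z_m, force_N")
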