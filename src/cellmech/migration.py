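"""Cell-migration metrics: speed, time-averaged MSD, persistent-random-walk
fit, and chemotactic index.

The mean-squared displacement is computed over ALL overlapping ordered
pairs at each time lag (a time average), and fitted to the Fürth
persistent-random-walk form

    MSD(t) = 4 D [ t - tau (1 - exp(-t / tau)) ]

by weighted nonlinear least squares over the diffusion coefficient D
(µm²/min) and persistence time tau (min). Short lags are ballistic
(MSD → (2D/τ)t²) and long lags diffusive (MSD → 4Dt); the curvature of
the crossover carries the persistence information.

Speed is path-based: total path length over elapsed time at the native
sampling interval. The chemotactic index is the net displacement projected
on the gradient axis divided by the total path length, bounded in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateDataError

__all__ = [
    "Trajectory",
    "MSDCurve",
    "PRWFit",
    "compute_speed",
    "compute_msd",
    "ensemble_msd",
    "fit_prw",
    "chemotactic_index",
    "read_trajectories",
    "write_trajectories",
]


@dataclass
class Trajectory:
    """One tracked cell path: positions in µm at uniformly spaced times in min."""

    track_id: int | str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(dts) > 1e-6 * dts.mean() + 1e-9:
            raise ValueError("sampling interval must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class MSDCurve:
    """Lag-averaged MSD: lag times (min), MSD values (µm²), pair counts."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(self.lags) == len(self.msd) == len(self.n_pairs)):
            raise ValueError("lags, msd, n_pairs must have equal length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and increasing")
        if np.any(self.msd < 0) or np.any(self.n_pairs < 1):
            raise ValueError("msd must be non-negative and pair counts >= 1")


def _furth(t: np.ndarray, D: float, tau: float) -> np.ndarray:
    return 4.0 * D * (t - tau * (1.0 - np.exp(-t / tau)))


@dataclass
class PRWFit:
    """Fitted persistent-random-walk parameters with fit diagnostics."""

    D: float  # µm²/min
    tau: float  # min
    rss: float
    converged: bool
    n_lags: int
    D_stderr: float = field(default=float("nan"))
    tau_stderr: float = field(default=float("nan"))

    def predict(self, t) -> np.ndarray:
        return _furth(np.asarray(t, dtype=float), self.D, self.tau)

    def summary(self) -> str:
        lines = [
            "Persistent-random-walk fit (Furth MSD)",
            f"  D    = {self.D:.4g} um^2/min  (se {self.D_stderr:.2g})",
            f"  tau  = {self.tau:.4g} min     (se {self.tau_stderr:.2g})",
            f"  RSS  = {self.rss:.4g}  over {self.n_lags} lags",
            f"  converged: {self.converged}",
        ]
        return "\n".join(lines)


def compute_speed(traj: Trajectory) -> float:
    """Path-based speed: total frame-to-frame path length / elapsed time (µm/min)."""
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return float(steps.sum() / traj.duration)


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.5) -> MSDCurve:
    """Time-averaged MSD over all overlapping pairs, up to a fraction of the
    track duration (long lags average too few pairs to be informative)."""
    if traj.n_samples < 3:
        raise ValueError("MSD needs at least 3 samples")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    n = traj.n_samples
    kmax = max(int(np.floor((n - 1) * max_lag_fraction)), 1)
    pos = traj.positions
    lags = np.empty(kmax)
    msd = np.empty(kmax)
    n_pairs = np.empty(kmax, dtype=int)
    for k in range(1, kmax + 1):
        d = pos[k:] - pos[:-k]
        msd[k - 1] = np.mean(np.sum(d * d, axis=1))
        lags[k - 1] = k * traj.dt
        n_pairs[k - 1] = n - k
    return MSDCurve(lags, msd, n_pairs)


def ensemble_msd(trajs: list[Trajectory], max_lag_fraction: float = 0.5) -> MSDCurve:
    """Pair-weighted average of per-track MSD curves on their common lag grid."""
    if not trajs:
        raise ValueError("need at least one trajectory")
    curves = [compute_msd(tr, max_lag_fraction) for tr in trajs]
    kmax = min(len(c.lags) for c in curves)
    lags = curves[0].lags[:kmax]
    for c in curves[1:]:
        if not np.allclose(c.lags[:kmax], lags):
            raise ValueError("trajectories must share a common sampling interval")
    msd = np.zeros(kmax)
    n_pairs = np.zeros(kmax, dtype=int)
    for c in curves:
        msd += c.msd[:kmax] * c.n_pairs[:kmax]
        n_pairs += c.n_pairs[:kmax]
    return MSDCurve(lags, msd / n_pairs, n_pairs)


def fit_prw(msd: MSDCurve) -> PRWFit:
    """Weighted trust-region least squares of the Fürth form to an MSD curve.

    The sampling variance of a time-averaged MSD estimate scales like
    msd_k^2 / n_pairs_k — displacement-pair fluctuations are proportional
    to the mean they estimate — so residuals are taken relative
    ((model - msd)/msd) and weighted by sqrt(n_pairs). This keeps the
    noise-dominated long-lag tail from swamping the short-lag curvature
    that carries the persistence time. Initial D comes from the slope of
    the last quartile of lags (the diffusive regime) and initial tau from
    the sampling interval; both parameters are constrained positive.
    """
    if len(msd.lags) < 4:
        raise ValueError("PRW fit needs at least 4 lags")
    if np.all(msd.msd == 0):
        raise DegenerateDataError("all-zero MSD: no motion to fit")

    t, y = msd.lags, msd.msd
    w = np.sqrt(msd.n_pairs / msd.n_pairs.max())
    scale = np.where(y > 0, y, y[y > 0].min())
    q = max(len(t) // 4, 2)
    slope = np.polyfit(t[-q:], y[-q:], 1)[0]
    D0 = max(slope / 4.0, y[-1] / (4.0 * t[-1]), 1e-12)
    tau0 = t[0]

    def resid(p):
        return w * (_furth(t, p[0], p[1]) - y) / scale

    res = least_squares(
        resid,
        x0=[D0, tau0],
        bounds=([0.0, 1e-9], [np.inf, np.inf]),
        method="trf",
        x_scale="jac",
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
    )
    converged = bool(res.success) and res.status > 0
    rss = float(np.sum(res.fun**2))
    # asymptotic standard errors from the Jacobian at the optimum
    D_se = tau_se = float("nan")
    try:
        jtj = res.jac.T @ res.jac
        dof = max(len(t) - 2, 1)
        cov = np.linalg.inv(jtj) * rss / dof
        D_se, tau_se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        pass
    return PRWFit(
        D=float(res.x[0]),
        tau=float(res.x[1]),
        rss=rss,
        converged=converged,
        n_lags=len(t),
        D_stderr=float(D_se),
        tau_stderr=float(tau_se),
    )


def chemotactic_index(
    traj: Trajectory, gradient_axis: tuple[float, float] = (1.0, 0.0)
) -> float:
    """Net displacement along the gradient axis over total path length.

    +1 for a straight path up the gradient, 0 for no net on-axis motion,
    -1 straight down the gradient.
    """
    axis = np.asarray(gradient_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("gradient_axis must be a nonzero vector")
    axis = axis / norm
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    path = steps.sum()
    if path == 0:
        raise DegenerateDataError("zero path length: chemotactic index undefined")
    net = np.array([traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]])
    return float(np.clip(net @ axis / path, -1.0, 1.0))


def write_trajectories(trajs: list[Trajectory], path: str | Path) -> None:
    """Write tracks as long-format CSV (track_id, frame, t_min, x_um, y_um)."""
    frames = [
        pd.DataFrame(
            {
                "track_id": tr.track_id,
                "frame": np.arange(tr.n_samples),
                "t_min": tr.t,
                "x_um": tr.x,
                "y_um": tr.y,
            }
        )
        for tr in trajs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    required = {"track_id", "t_min", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    out = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("t_min")
        out.append(Trajectory(tid, g["t_min"].values, g["x_um"].values, g["y_um"].values))
    return out
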