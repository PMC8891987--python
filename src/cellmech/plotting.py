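"""Quick-look plots for the pipeline's intermediate quantities."""

from __future__ import annotations

import numpy as np

from .afm import ForceCurve, HertzFit, HertzParams, hertz_force
from .migration import MSDCurve, PRWFit

__all__ = ["plot_msd", "plot_force_curve"]


def plot_msd(msd: MSDCurve, fit: PRWFit | None = None, ax=None, loglog: bool = True):
    """MSD vs lag time, optionally with the fitted Fürth curve overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(msd.lags, msd.msd, "o", ms=4, label="measured MSD")
    if fit is not None:
        tt = np.linspace(msd.lags[0], msd.lags[-1], 200)
        ax.plot(tt, fit.predict(tt), "-", label=f"fit: D={fit.D:.3g}, tau={fit.tau:.3g}")
    if loglog:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("lag time (min)")
    ax.set_ylabel(r"MSD ($\mu m^2$)")
    ax.legend()
    return ax


def plot_force_curve(
    curve: ForceCurve, fit: HertzFit | None = None, params: HertzParams | None = None, ax=None
):
    """Force vs z, optionally with the fitted Hertz model overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.z * 1e6, curve.force * 1e9, ".", ms=3, label="data")
    if fit is not None:
        p = params or HertzParams()
        delta = np.clip(curve.z - fit.contact_point, 0.0, None)
        model = fit.baseline + hertz_force(fit.E, p.nu, p.r, delta)
        ax.plot(curve.z * 1e6, model * 1e9, "-", label=f"Hertz: E={fit.E:.3g} Pa")
    ax.set_xlabel(r"z ($\mu m$)")
    ax.set_ylabel("force (nN)")
    ax.legend()
    return ax
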