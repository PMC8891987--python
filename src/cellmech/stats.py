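"""The statistical decision tree used for group comparison of per-cell
measurements.

Normality of each group is assessed with the D'Agostino–Pearson omnibus K²
test. If the data follow or partially follow a normal distribution (i.e.
at least one group passes, under the default permissive rule), a one- or
two-way ANOVA with a Tukey follow-up is used; if no group is normal, a
Kruskal–Wallis H test (tie-corrected) with Dunn's pairwise z-tests and
Bonferroni adjustment. Significance is declared at p < 0.05. Outliers in
expression-type data are flagged — never silently deleted — with a
univariate ROUT-style procedure: a robust location/scale fit (median, MAD)
followed by FDR-controlled flagging of extreme residuals at rate Q
(default 1%). The documented order of operations is flag → exclude →
re-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError

__all__ = [
    "GroupedSample",
    "ComparisonReport",
    "RoutResult",
    "dagostino_pearson",
    "kruskal_wallis",
    "dunn_test",
    "compare_groups",
    "rout_outliers",
]

ALPHA = 0.05


def dagostino_pearson(sample) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus normality test.

    Combines skewness and kurtosis z-scores into K² ~ chi²(2). Undefined
    for n < 8 or for a zero-variance sample (both raise).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 8:
        raise ValueError("D'Agostino-Pearson test requires n >= 8")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero-variance sample: normality test undefined")
    with warnings.catch_warnings():
        # kurtosis z-score is approximate below n=20; accept, as field practice does
        warnings.simplefilter("ignore")
        k2, p = sps.normaltest(x)
    return float(k2), float(p)


@dataclass
class GroupedSample:
    """Named per-group observations, optionally with a second crossed factor."""

    groups: dict[str, np.ndarray]
    name: str = "measurement"
    units: str = ""
    factor2: dict[str, np.ndarray] | None = None  # group -> level per observation

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for k, v in self.groups.items():
            if len(v) < 3:
                raise ValueError(f"group {k!r} has fewer than 3 observations")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        value: str = "value",
        group: str = "group",
        factor2: str | None = None,
        name: str = "measurement",
        units: str = "",
    ) -> "GroupedSample":
        groups = {str(k): g[value].values for k, g in df.groupby(group, sort=False)}
        f2 = None
        if factor2 is not None:
            f2 = {
                str(k): g[factor2].astype(str).values
                for k, g in df.groupby(group, sort=False)
            }
        return cls(groups=groups, name=name, units=units, factor2=f2)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for k, v in self.groups.items():
            part = pd.DataFrame({"group": k, "value": v})
            if self.factor2 is not None:
                part["factor2"] = self.factor2[k]
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi² p-value.

    All-identical pooled data has no rank separation: H = 0, p = 1.
    """
    vals = list(groups.values())
    pooled = np.concatenate(vals)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*vals)
    return float(h), float(p)


def _adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    m = len(p_raw)
    if method == "bonferroni":
        return np.minimum(p_raw * m, 1.0)
    if method == "holm":
        order = np.argsort(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(running, 1.0)
        return adj
    if method == "none":
        return p_raw.copy()
    raise ValueError("adjust must be 'bonferroni', 'holm' or 'none'")


def dunn_test(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's post-hoc pairwise z-tests on pooled ranks, with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)]
    where T = sum(t^3 - t) / (12 (N - 1)) over tied-value groups. Raw
    two-sided normal p-values are adjusted over all k(k-1)/2 pairs
    (Bonferroni by default).
    """
    names = list(groups)
    vals = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(vals)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(v) for v in vals]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start : start + n].mean())
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": names[i], "group2": names[j], "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = _adjust(out["p_raw"].values, adjust)
    return out


@dataclass
class ComparisonReport:
    """Outcome of the normality-gated group comparison."""

    measurement: str
    design: str
    normality: pd.DataFrame  # group, n, k2, p, normal
    test_used: str  # 'kruskal-wallis+dunn' | 'one-way-anova+tukey' | 'two-way-anova+tukey'
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, statistic col, p_raw, p_adj, significant
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Comparison of {self.measurement!r} ({self.design})",
            "Normality (D'Agostino-Pearson):",
        ]
        for _, r in self.normality.iterrows():
            verdict = "n/a" if pd.isna(r["normal"]) else ("normal" if r["normal"] else "non-normal")
            ptxt = "n/a" if pd.isna(r["p"]) else f"{r['p']:.3g}"
            lines.append(f"  {r['group']}: n={int(r['n'])}, p={ptxt} -> {verdict}")
        lines.append(f"Omnibus: {self.test_used}, stat={self.statistic:.4g}, p={self.p_value:.3g}")
        lines.append(f"Pairwise (alpha={self.alpha}):")
        for _, r in self.pairwise.iterrows():
            star = "*" if r["significant"] else " "
            lines.append(
                f"  {r['group1']} vs {r['group2']}: p_adj={r['p_adj']:.3g} {star}"
            )
        return "\n".join(lines)


def _normality_table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for k, v in groups.items():
        try:
            k2, p = dagostino_pearson(v)
            rows.append({"group": k, "n": len(v), "k2": k2, "p": p, "normal": p > ALPHA})
        except (ValueError, DegenerateDataError):
            # too small or constant: cannot claim normality
            rows.append(
                {"group": k, "n": len(v), "k2": np.nan, "p": np.nan, "normal": None}
            )
    return pd.DataFrame(rows)


def _anova_oneway(sample: GroupedSample, alpha: float, adjust: str):
    vals = list(sample.groups.values())
    stat, p = sps.f_oneway(*vals)
    res = sps.tukey_hsd(*vals)
    names = list(sample.groups)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group1": names[i],
                "group2": names[j],
                "statistic": float(res.statistic[i, j]),
                "p_raw": float(res.pvalue[i, j]),
                "p_adj": float(res.pvalue[i, j]),  # Tukey is family-adjusted by construction
            }
        )
    return "one-way-anova+tukey", float(stat), float(p), pd.DataFrame(rows), {}


def _anova_twoway(sample: GroupedSample, alpha: float, adjust: str):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = sample.to_frame()
    if "factor2" not in df.columns:
        raise ValueError("two-way design requires a second factor")
    model = smf.ols("value ~ C(group) * C(factor2)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    stat = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    vals = list(sample.groups.values())
    res = sps.tukey_hsd(*vals)  # follow-up on the primary factor, pooled over factor2
    names = list(sample.groups)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group1": names[i],
                "group2": names[j],
                "statistic": float(res.statistic[i, j]),
                "p_raw": float(res.pvalue[i, j]),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    extra = {"anova_table": table}
    return "two-way-anova+tukey", stat, p, pd.DataFrame(rows), extra


def compare_groups(
    sample: GroupedSample,
    design: str = "one-way",
    alpha: float = ALPHA,
    normality_rule: str = "any",
    adjust: str = "bonferroni",
) -> ComparisonReport:
    """Normality-gated comparison of 2+ groups.

    ``normality_rule='any'`` (the permissive default) sends the data to the
    ANOVA branch when the groups follow or partially follow a normal
    distribution — i.e. at least one group passes D'Agostino–Pearson at
    alpha; ``'all'`` requires every group to pass. Groups too small or
    degenerate for the normality test count as non-normal. When no group is
    normal, the branch is Kruskal–Wallis with Dunn's adjusted pairwise tests.
    """
    if design not in {"one-way", "two-way"}:
        raise ValueError("design must be 'one-way' or 'two-way'")
    if normality_rule not in {"any", "all"}:
        raise ValueError("normality_rule must be 'any' or 'all'")
    norm_tab = _normality_table(sample.groups)
    verdicts = [bool(v) if v is not None and not pd.isna(v) else False
                for v in norm_tab["normal"]]
    go_anova = any(verdicts) if normality_rule == "any" else all(verdicts)

    if go_anova:
        branch = _anova_twoway if design == "two-way" else _anova_oneway
        test_used, stat, p, pairwise, extra = branch(sample, alpha, adjust)
    else:
        stat, p = kruskal_wallis(sample.groups)
        pairwise = dunn_test(sample.groups, adjust=adjust)
        pairwise = pairwise.rename(columns={"z": "statistic"})
        test_used, extra = "kruskal-wallis+dunn", {}
    pairwise = pairwise.copy()
    pairwise["significant"] = pairwise["p_adj"] < alpha
    return ComparisonReport(
        measurement=sample.name,
        design=design,
        normality=norm_tab,
        test_used=test_used,
        statistic=stat,
        p_value=p,
        pairwise=pairwise,
        alpha=alpha,
        extra=extra,
    )


@dataclass
class RoutResult:
    """ROUT-style outlier flags; the data themselves are never modified."""

    flags: np.ndarray  # boolean, True = outlier
    q_percent: float
    location: float
    scale: float
    scale_fallback: bool  # True when MAD was zero and IQR scale was used

    @property
    def n_outliers(self) -> int:
        return int(self.flags.sum())


def rout_outliers(sample, q_percent: float = 1.0) -> RoutResult:
    """Univariate ROUT-style outlier flagging.

    The general procedure fits a robust model and removes points whose
    residuals are implausible at a false-discovery rate Q; for a single
    sample the robust fit degenerates to the median with an MAD-based
    scale. Residual p-values come from a t distribution (n-1 df) and the
    flag set is chosen by a Benjamini–Hochberg step at rate Q over the
    most extreme residuals. Zero MAD with distinct values falls back to an
    IQR-based scale (recorded on the result); if that is zero too, every
    point off the median is flagged.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("ROUT flagging requires n >= 10")
    if not 0 < q_percent < 100:
        raise ValueError("Q must be a percentage in (0, 100)")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    scale = 1.4826 * mad
    fallback = False
    if scale == 0:
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        scale = iqr / 1.349
        fallback = True
        if scale == 0:
            flags = x != med
            if flags.any():
                warnings.warn("zero robust scale: flagging all points off the median")
            return RoutResult(flags, q_percent, med, 0.0, True)
    if fallback:
        warnings.warn("zero MAD with distinct values: falling back to IQR scale")
    t_res = np.abs(x - med) / scale
    p = 2.0 * sps.t.sf(t_res, df=n - 1)
    q = q_percent / 100.0
    order = np.argsort(p)
    thresh_rank = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / n:
            thresh_rank = rank
    flags = np.zeros(n, dtype=bool)
    flags[order[:thresh_rank]] = True
    return RoutResult(flags, q_percent, med, scale, fallback)
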