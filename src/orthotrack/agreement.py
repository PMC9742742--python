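"""Method-comparison statistics: Pearson/Fisher, regression, Bland-Altman.

Conventions:

* Differences are oriented **reference minus test** (system A minus system
  B), so a positive mean difference means the reference reads higher; a
  ``reverse_diff`` flag flips this.
* Limits of agreement use the factor 1.96 exactly:
  ``LoA = mean_diff +/- 1.96 * SD(diff)``; the *critical difference* is
  ``1.96 * SD(diff)``, i.e. half the LoA width. Some reports label the LoA
  interval a "95% CI" of the mean difference; the quantities tabulated here
  are limits of agreement (they equal mean +/- critical difference).
* The Pearson 95% CI comes from the Fisher z-transform with half-width
  ``1.96 / sqrt(n - 3)``; the p-value from the exact t-statistic
  ``r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.96  # quantile used throughout for 95% intervals

METRIC_COLUMNS = {
    "OA": ("sysA_oa_deg", "sysB_oa_deg"),
    "OI": ("sysA_oi_deg", "sysB_oi_deg"),
    "FNA": ("sysA_fna_deg", "sysB_fna_deg"),
    "FSA": ("sysA_fsa_deg", "sysB_fsa_deg"),
}


class StatisticsError(ValueError):
    """Undefined statistic (too few points, zero variance, ...)."""


@dataclass(frozen=True)
class AgreementSummary:
    """One summary row for a metric: correlation, regression, Bland-Altman."""

    metric: str
    n: int
    r: float
    r_ci_low: float
    r_ci_high: float
    p_value: float
    significant: bool
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    critical_diff: float
    intercept: float
    slope: float
    r2: float
    adj_r2: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _clean_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise StatisticsError(f"paired series lengths differ: {x.size} vs {y.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatisticsError("paired series contain non-finite values")
    if x.size < min_n:
        raise StatisticsError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def pearson(x, y) -> tuple[float, tuple[float, float], float]:
    """Pearson product-moment r with Fisher-z 95% CI and two-sided p-value."""
    x, y = _clean_pair(x, y, 4)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatisticsError("correlation undefined for a zero-variance series")
    n = x.size
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    ci = fisher_ci(r, n)
    if abs(r) >= 1.0 - 1e-12:  # numerically exact linear relation
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, ci, p


def fisher_ci(r: float, n: int, z: float = Z95) -> tuple[float, float]:
    """95% CI for a correlation from ``r`` and ``n`` alone (Fisher transform)."""
    if n < 4:
        raise StatisticsError("Fisher CI needs n >= 4")
    if abs(r) >= 1.0 - 1e-12:  # z-transform diverges at the boundary
        return (float(round(r)), float(round(r)))
    zr = np.arctanh(r)
    half = z / np.sqrt(n - 3)
    return float(np.tanh(zr - half)), float(np.tanh(zr + half))


def linear_fit(x, y) -> tuple[float, float, float, float]:
    """Simple least-squares regression of ``y`` on ``x``.

    Returns ``(intercept, slope, r2, adj_r2)`` with
    ``adj_r2 = 1 - (1 - r2)(n - 1)/(n - 2)`` for the single predictor.
    """
    x, y = _clean_pair(x, y, 3)
    if np.ptp(x) == 0:
        raise StatisticsError("regression undefined for zero-variance predictor")
    n = x.size
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    adj = adjusted_r2(r2, n)
    return float(res.intercept), float(res.slope), r2, adj


def adjusted_r2(r2: float, n: int) -> float:
    """Adjusted R^2 for a one-predictor regression with ``n`` observations."""
    if n < 3:
        raise StatisticsError("adjusted R^2 needs n >= 3")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))


def bland_altman(a, b) -> tuple[float, float, tuple[float, float], float]:
    """Bland-Altman agreement of reference ``a`` against test ``b``.

    Returns ``(mean_diff, sd_diff, (loa_low, loa_high), critical_diff)`` for
    differences ``a - b``, with the sample (n-1) SD and the exact 1.96
    factor.
    """
    a, b = _clean_pair(a, b, 2)
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    crit = Z95 * sd
    return mean, sd, (mean - crit, mean + crit), crit


def critical_difference_from_limits(low: float, high: float) -> float:
    """Half the limits-of-agreement width: ``(high - low) / 2``."""
    if high < low:
        raise StatisticsError("upper limit of agreement below lower limit")
    return 0.5 * (high - low)


def summarize(paired: pd.DataFrame, metric: str, alpha: float = 0.05,
              reverse_diff: bool = False) -> AgreementSummary:
    """One Table-style agreement row for a metric of a paired-readings table.

    Correlation and regression relate the test system's readings (x) to the
    reference system's (y); Bland-Altman differences are reference - test
    unless ``reverse_diff``.
    """
    metric = metric.upper()
    if metric not in METRIC_COLUMNS:
        raise StatisticsError(f"unknown metric {metric!r}; expected one of {sorted(METRIC_COLUMNS)}")
    col_a, col_b = METRIC_COLUMNS[metric]
    for c in (col_a, col_b):
        if c not in paired.columns:
            raise StatisticsError(f"paired table lacks column {c!r}")
    a = paired[col_a].to_numpy(dtype=float)
    b = paired[col_b].to_numpy(dtype=float)
    a, b = _clean_pair(a, b, 4)
    if reverse_diff:
        a, b = b, a
    r, (ci_lo, ci_hi), p = pearson(a, b)
    intercept, slope, r2, adj = linear_fit(b, a)
    mean, sd, (lo, hi), crit = bland_altman(a, b)
    return AgreementSummary(
        metric=metric, n=a.size, r=r, r_ci_low=ci_lo, r_ci_high=ci_hi,
        p_value=p, significant=p < alpha,
        mean_diff=mean, sd_diff=sd, loa_low=lo, loa_high=hi, critical_diff=crit,
        intercept=intercept, slope=slope, r2=r2, adj_r2=adj,
    )


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (report convention), not banker's."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summary_table(summaries: list[AgreementSummary], rounded: bool = False) -> pd.DataFrame:
    """Stack summaries into one report table (one row per metric).

    With ``rounded=True`` numeric columns are rounded to 2 decimals,
    half-up, for report output.
    """
    df = pd.DataFrame([s.to_dict() for s in summaries])
    if rounded:
        for c in df.columns:
            if df[c].dtype.kind == "f":
                df[c] = df[c].map(lambda v: round_half_up(v, 2))
    return df


def bland_altman_plot(paired: pd.DataFrame, metric: str, out_path,
                      reverse_diff: bool = False) -> None:
    """Write a Bland-Altman scatter (mean vs difference) with LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col_a, col_b = METRIC_COLUMNS[metric.upper()]
    a = paired[col_a].to_numpy(dtype=float)
    b = paired[col_b].to_numpy(dtype=float)
    if reverse_diff:
        a, b = b, a
    mean_ab = 0.5 * (a + b)
    diff = a - b
    md, _, (lo, hi), _ = bland_altman(a, b)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean_ab, diff, s=12, alpha=0.6, edgecolors="none")
    for y, style, label in ((md, "-", f"mean {md:.2f}"),
                            (lo, "--", f"LoA {lo:.2f}"),
                            (hi, "--", f"LoA {hi:.2f}")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
        ax.annotate(label, xy=(1.0, y), xycoords=("axes fraction", "data"),
                    xytext=(-4, 2), textcoords="offset points", ha="right", fontsize=8)
    ax.set_xlabel(f"mean of systems ({metric}, deg)")
    ax.set_ylabel("difference A - B (deg)")
    ax.set_title(f"Bland-Altman: {metric}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
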