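"""Post-hoc power analysis for two-sample comparisons.

Standardized effect sizes (Cohen's d with pooled SD) and the exact power
of the two-sided two-sample t-test via the noncentral t distribution,
plus the minimal per-group sample size reaching a target power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PowerResult:
    metabolite: str
    comparison: str
    d: float
    alpha: float
    n_per_group: int
    power: float


def cohens_d(treated, control) -> float:
    """|mean difference| / pooled SD (n-1 denominators)."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = len(treated), len(control)
    s2 = ((n1 - 1) * treated.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("zero pooled standard deviation")
    return float(abs(treated.mean() - control.mean()) / np.sqrt(s2))


def posthoc_power(d: float, n_per_group: int, alpha: float = 0.01) -> float:
    """Power of the two-sided two-sample t-test at effect size ``d``.

    T follows a noncentral t with 2n-2 degrees of freedom and
    noncentrality d*sqrt(n/2); power = P(|T| > t_{1-alpha/2}).
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = 1.0 - stats.nct.cdf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    if np.isnan(lower):  # astronomically small at large noncentrality
        lower = 0.0
    return float(min(1.0, max(0.0, upper + lower)))


def required_sample_size(d: float, alpha: float = 0.01, target_power: float = 0.8,
                         n_max: int = 10**6) -> int:
    """Smallest per-group n with posthoc_power(d, n, alpha) >= target."""
    if d <= 0:
        raise ValueError("d must be positive")
    lo, hi = 2, 2
    if posthoc_power(d, lo, alpha) >= target_power:
        return lo
    while posthoc_power(d, hi, alpha) < target_power:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"target power unreachable within n <= {n_max}")
    while hi - lo > 1:  # invariant: power(lo) < target <= power(hi)
        mid = (lo + hi) // 2
        if posthoc_power(d, mid, alpha) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def power_report(records: pd.DataFrame, quant: pd.DataFrame, groups,
                 alpha: float = 0.01, control_group: str = "control") -> pd.DataFrame:
    """One row per *selected* marker: Cohen's d and achieved power at the
    study's per-group n."""
    groups = np.asarray(groups)
    rows = []
    for _, rec in records[records["selected"]].iterrows():
        comparison_group = rec["comparison"].split("-vs-")[0]
        v = quant[rec["metabolite"]].to_numpy()
        treated = v[groups == comparison_group]
        control = v[groups == control_group]
        d = cohens_d(treated, control)
        n = min(len(treated), len(control))
        rows.append(
            {
                "metabolite": rec["metabolite"],
                "comparison": rec["comparison"],
                "d": d,
                "alpha": alpha,
                "n_per_group": n,
                "power": posthoc_power(d, n, alpha),
            }
        )
    return pd.DataFrame(
        rows, columns=["metabolite", "comparison", "d", "alpha", "n_per_group", "power"]
    )
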