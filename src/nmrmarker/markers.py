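"""Metabolite quantification and enhanced-volcano marker selection.

Metabolites are quantified as integrals over least-overlapping spectral
regions, expressed as a percentage of each sample's total bucket sum
(relative concentrations).  Candidate markers combine four coordinates:
-log10 of the Bonferroni-adjusted two-sample t-test p-value, log2
fold-change (treated over control mean), the OPLS-DA VIP quantile
category (circle size: top 5%, top 10%, top 20%, rest 80%) and the
absolute correlation loading |r| (circle colour).  A metabolite is
selected when |r| >= 0.6, its VIP falls in the top 20%, the adjusted p is
below the cut-off and the fold-change clears a minimal magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

VIP_CATEGORIES = ("top5", "top10", "top20", "rest80")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantRegion:
    """Integration intervals (half-open, ppm) for one metabolite."""

    metabolite: str
    sample_type: str
    intervals: tuple  # of (lo, hi)

    def __post_init__(self):
        for lo, hi in self.intervals:
            if not (lo < hi):
                raise ValueError(f"{self.metabolite}: bad interval [{lo}, {hi})")


@dataclass
class SelectionCriteria:
    """Cut-offs of the enhanced volcano plot.

    ``r_min`` and ``vip_top_fraction`` follow the published rule
    (|r| >= 0.6, VIP in the top 20%); the p and fold-change cut-offs are
    configurable with defaults that admit modest but systematic shifts
    (|log2 FC| >= 0.1 covers a 0.9-fold decrease).
    """

    r_min: float = 0.6
    vip_top_fraction: float = 0.20
    p_max: float = 0.05
    min_abs_log2fc: float = 0.1

    def __post_init__(self):
        if not (0 < self.vip_top_fraction < 1):
            raise ValueError("vip_top_fraction must be in (0, 1)")
        if not (0 <= self.r_min <= 1 and 0 < self.p_max <= 1 and self.min_abs_log2fc >= 0):
            raise ValueError("invalid selection criteria")


# ---------------------------------------------------------------------------
# Default quantification regions
# ---------------------------------------------------------------------------

def default_quant_regions(
    library,
    sample_type: str,
    exclusion_plan=None,
    min_halfwidth: float = 0.006,
    max_halfwidth: float = 0.02,
) -> dict:
    """Choose one least-overlapping peak per metabolite of a matrix.

    For every non-reference metabolite present in ``sample_type``, each of
    its peaks is scored by the distance from the multiplet span to the
    nearest line of any *other* metabolite in that matrix; the peak with
    the largest clearance wins.  The integration interval extends the
    multiplet span by half the clearance (clamped to
    [min_halfwidth, max_halfwidth]).  Peaks inside excluded regions or
    outside the retained range are not eligible.
    """
    from .preprocess import default_exclusion_plan

    plan = exclusion_plan or default_exclusion_plan()
    present = [m for m in library if sample_type in m.matrices and not m.is_reference]
    regions: dict = {}
    for met in present:
        foreign = [
            pos
            for other in present
            if other.name != met.name
            for pos in other.line_positions()
        ]
        best = None
        for peak in met.peaks:
            lines = peak.line_positions()
            span_lo, span_hi = min(lines), max(lines)
            if any(
                plan.is_excluded(sample_type, x)
                for x in (span_lo - min_halfwidth, span_lo, span_hi, span_hi + min_halfwidth)
            ):
                continue
            clearance = min(
                (max(0.0, span_lo - x, x - span_hi) for x in foreign),
                default=np.inf,
            )
            if best is None or clearance > best[0]:
                best = (clearance, span_lo, span_hi)
        if best is None:
            continue  # metabolite has no quantifiable resonance in this matrix
        clearance, span_lo, span_hi = best
        r = float(np.clip(clearance / 2.0, min_halfwidth, max_halfwidth))
        regions[met.name] = QuantRegion(
            metabolite=met.name,
            sample_type=sample_type,
            intervals=((span_lo - r, span_hi + r),),
        )
    return regions


# ---------------------------------------------------------------------------
# Quantification and univariate statistics
# ---------------------------------------------------------------------------

def _region_bucket_mask(edges: np.ndarray, width: float, region: QuantRegion) -> np.ndarray:
    mask = np.zeros(len(edges), dtype=bool)
    for lo, hi in region.intervals:
        mask |= (edges < hi) & (edges + width > lo)
    return mask


def quantify_metabolites(matrix, regions: Mapping[str, QuantRegion]) -> pd.DataFrame:
    """Integrate bucket values over each metabolite's region, as percent
    of the sample's total bucket sum (relative concentration)."""
    if matrix.state != "pqn":
        raise ValueError("quantification expects a PQN-normalized matrix")
    totals = matrix.values.sum(axis=1)
    out = {}
    for name, region in regions.items():
        if region.sample_type != matrix.sample_type:
            raise ValueError(
                f"region for {name!r} targets {region.sample_type!r}, "
                f"matrix is {matrix.sample_type!r}"
            )
        mask = _region_bucket_mask(matrix.edges, matrix.width, region)
        if not np.any(mask):
            raise ValueError(f"region for metabolite {name!r} covers no bucket")
        out[name] = 100.0 * matrix.values[:, mask].sum(axis=1) / totals
    return pd.DataFrame(out, index=matrix.sample_ids)


def fold_change(treated, control) -> tuple[float, float]:
    """fc = mean(treated)/mean(control); log2fc = log2(fc)."""
    mc = float(np.mean(control))
    if mc <= 0:
        raise ValueError("control mean must be positive")
    fc = float(np.mean(treated)) / mc
    return fc, float(np.log2(fc))


def student_t_bonferroni(treated, control, m_tests: int) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test with Bonferroni
    adjustment over ``m_tests`` metabolites; degenerate zero-variance
    equal-mean groups give p = 1."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(treated, control, equal_var=True)
    p_raw = float(res.pvalue)
    if np.isnan(p_raw):  # zero pooled variance
        p_raw = 1.0 if np.mean(treated) == np.mean(control) else 0.0
    p_bonf = min(1.0, p_raw * m_tests)
    return p_raw, p_bonf


def vip_categories(vip_values, names: Sequence[str] | None = None) -> list:
    """Bin VIPs at their empirical 0.95/0.90/0.80 quantiles (inclusive).

    A fully degenerate distribution (all values equal) is assigned
    entirely to ``rest80``.  Output order follows the input; for
    reporting, records are sorted by name so ties resolve
    deterministically.
    """
    v = np.asarray(vip_values, dtype=float)
    if len(v) < 5:
        raise ValueError("need at least 5 VIP values to form quantile categories")
    if np.all(v == v[0]):
        return ["rest80"] * len(v)
    q95, q90, q80 = np.quantile(v, [0.95, 0.90, 0.80])
    cats = []
    for x in v:
        if x >= q95:
            cats.append("top5")
        elif x >= q90:
            cats.append("top10")
        elif x >= q80:
            cats.append("top20")
        else:
            cats.append("rest80")
    return cats


# ---------------------------------------------------------------------------
# Volcano table and selection
# ---------------------------------------------------------------------------

def build_volcano_table(
    quant: pd.DataFrame,
    model,
    edges,
    width: float,
    regions: Mapping[str, QuantRegion],
    groups,
    comparison: str,
    criteria: SelectionCriteria | None = None,
    control_group: str = "control",
    sample_type: str = "",
) -> pd.DataFrame:
    """One record per metabolite with all enhanced-volcano coordinates.

    Metabolite-level VIP and |r| are the maxima over the buckets of the
    metabolite's quantification region (a metabolite is flagged if any of
    its resolved resonances is discriminating).  The Bonferroni family is
    the set of metabolites tested in this comparison and sample type.
    """
    criteria = criteria or SelectionCriteria()
    groups = np.asarray(groups)
    treated_rows = groups == comparison
    control_rows = groups == control_group
    if not treated_rows.any() or not control_rows.any():
        raise ValueError(f"comparison {comparison!r} vs {control_group!r} not in data")
    edges = np.asarray(edges, dtype=float)
    names = sorted(quant.columns)
    m_tests = len(names)
    rows = []
    for name in names:
        region = regions[name]
        mask = _region_bucket_mask(edges, width, region)
        if not np.any(mask):
            raise ValueError(f"metabolite {name!r} has no model variable")
        v = quant[name].to_numpy()
        treated, control = v[treated_rows], v[control_rows]
        fc, log2fc = fold_change(treated, control)
        p_raw, p_bonf = student_t_bonferroni(treated, control, m_tests)
        vip_met = float(np.max(model.vip_[mask]))
        abs_r = float(np.max(np.abs(model.r_loadings_[mask])))
        rows.append(
            {
                "metabolite": name,
                "sample_type": sample_type,
                "comparison": f"{comparison}-vs-{control_group}",
                "mean_treated": float(np.mean(treated)),
                "mean_control": float(np.mean(control)),
                "fold_change": fc,
                "log2fc": log2fc,
                "neg_log10_p": float(-np.log10(max(p_bonf, 1e-300))),
                "p_raw": p_raw,
                "p_bonf": p_bonf,
                "vip": vip_met,
                "abs_r": abs_r,
            }
        )
    records = pd.DataFrame(rows)
    records["vip_category"] = vip_categories(records["vip"].to_numpy())
    records["direction"] = np.where(
        records["log2fc"] > 0, "increase",
        np.where(records["log2fc"] < 0, "decrease", "none"),
    )
    return select_markers(records, criteria)


def select_markers(records: pd.DataFrame, criteria: SelectionCriteria | None = None
                   ) -> pd.DataFrame:
    """Apply the four-dimensional selection rule; adds/updates the
    ``selected`` flag column."""
    criteria = criteria or SelectionCriteria()
    top = _top_categories(criteria.vip_top_fraction)
    records = records.copy()
    records["selected"] = (
        (records["abs_r"] >= criteria.r_min)
        & records["vip_category"].isin(top)
        & (records["p_bonf"] <= criteria.p_max)
        & (records["log2fc"].abs() >= criteria.min_abs_log2fc)
    )
    return records


def _top_categories(top_fraction: float) -> tuple:
    if top_fraction >= 0.20:
        return ("top5", "top10", "top20")
    if top_fraction >= 0.10:
        return ("top5", "top10")
    return ("top5",)


def selected_markers(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["selected"]].reset_index(drop=True)


def write_marker_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def volcano_plot_data(records: pd.DataFrame) -> pd.DataFrame:
    """x/y/size/colour table for any plotting layer."""
    return pd.DataFrame(
        {
            "metabolite": records["metabolite"],
            "x_log2fc": records["log2fc"],
            "y_neg_log10_p": records["neg_log10_p"],
            "size_category": records["vip_category"],
            "colour_value": records["abs_r"],
            "selected": records["selected"],
        }
    )


def plot_volcano(records: pd.DataFrame, path, criteria: SelectionCriteria | None = None,
                 title: str = "") -> None:
    """Render the enhanced volcano scatter (size = VIP category,
    colour = |r|) to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    criteria = criteria or SelectionCriteria()
    sizes = {"top5": 140.0, "top10": 90.0, "top20": 50.0, "rest80": 18.0}
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(
        records["log2fc"],
        records["neg_log10_p"],
        s=[sizes[c] for c in records["vip_category"]],
        c=records["abs_r"],
        cmap="coolwarm",
        vmin=0,
        vmax=1,
        edgecolor="k",
        linewidth=0.3,
    )
    ax.axhline(-np.log10(criteria.p_max), ls="--", c="grey", lw=0.8)
    for x in (-criteria.min_abs_log2fc, criteria.min_abs_log2fc):
        ax.axvline(x, ls="--", c="grey", lw=0.8)
    fig.colorbar(sc, label="|r|")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
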