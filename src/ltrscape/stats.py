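"""Enrichment and divergence statistics of the insertion complement.

Chi-square tests follow the census conventions: goodness-of-fit
expectations proportional to region length in bp, Pearson 2x2 without
continuity correction, df = 1 throughout; divergence comparisons use a
two-sample t (pooled variance by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError


@dataclass(frozen=True)
class GofResult:
    observed: tuple
    expected: tuple
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple
    chi2: float
    df: int
    p: float


def chisq_gof_region(
    count_focal: int, count_rest: int, size_focal: float, size_rest: float
) -> GofResult:
    """Is a region over/under-represented given its share of the sequence?

    Expected counts are proportional to region length; df = 1, no
    continuity correction."""
    if min(count_focal, count_rest) < 0 or min(size_focal, size_rest) <= 0:
        raise ParameterError("counts must be >= 0 and sizes > 0")
    total = count_focal + count_rest
    p_focal = size_focal / (size_focal + size_rest)
    e1, e2 = total * p_focal, total * (1 - p_focal)
    if e1 == 0 or e2 == 0:
        raise ParameterError("zero expected cell")
    chi2 = (count_focal - e1) ** 2 / e1 + (count_rest - e2) ** 2 / e2
    return GofResult(
        observed=(count_focal, count_rest),
        expected=(e1, e2),
        chi2=float(chi2),
        df=1,
        p=float(sps.chi2.sf(chi2, 1)),
    )


def chisq_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Pearson chi-square of a 2x2 table, no Yates correction, df = 1."""
    if min(a, b, c, d) < 0:
        raise ParameterError("counts must be >= 0")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        raise ParameterError("zero marginal")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return ContingencyResult(
        table=(a, b, c, d), chi2=float(chi2), df=1, p=float(sps.chi2.sf(chi2, 1))
    )


def ttest_divergence(group_a, group_b, variant: str = "pooled"):
    """Two-sample two-tailed t on divergence values.

    ``variant='pooled'`` is the classic Student test; ``'welch'`` drops the
    equal-variance assumption.  Returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, len(a) + len(b) - 2, 1.0
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = (
        len(a) + len(b) - 2
        if variant == "pooled"
        else float(res.df) if hasattr(res, "df") else len(a) + len(b) - 2
    )
    return float(res.statistic), df, float(res.pvalue)


def divergence_histogram(
    copies, bin_width: float = 0.005, max_div: float = 0.10
) -> dict:
    """Divergence histogram per condition class plus the headline shares.

    Returns bin edges, per-condition counts, and for solo-LTRs and
    provirals the share of copies at <= 1% and >= 5% divergence."""
    if bin_width <= 0:
        raise ParameterError("bin width must be > 0")
    edges = np.arange(0, max_div + bin_width / 2, bin_width)
    if edges[-1] < max_div:
        edges = np.append(edges, max_div)
    out = {"bin_edges": edges.tolist(), "counts": {}, "headline": {}}
    for cond in ("proviral", "solo-LTR", "unknown"):
        vals = np.array(
            [
                min(c.divergence, max_div)
                for c in copies
                if c.condition == cond and c.divergence is not None
            ]
        )
        counts, _ = np.histogram(vals, bins=edges) if len(vals) else (np.zeros(len(edges) - 1, int), None)
        out["counts"][cond] = counts.astype(int).tolist()
        if cond in ("proviral", "solo-LTR") and len(vals):
            out["headline"][cond] = {
                "n": int(len(vals)),
                "frac_recent": float(np.mean(vals <= 0.01)),
                "frac_old": float(np.mean(vals >= 0.05)),
            }
    return out


def condition_ratio_by_age(
    copies, young_cutoff: float = 0.02, old_cutoff: float = 0.05
) -> dict:
    """Does the proviral:solo ratio drop between young and old insertions?

    2x2 of condition x age class (divergence < young_cutoff vs
    > old_cutoff), tested with the uncorrected Pearson chi-square."""
    young = [c for c in copies if c.divergence is not None and c.divergence < young_cutoff]
    old = [c for c in copies if c.divergence is not None and c.divergence > old_cutoff]
    a = sum(1 for c in young if c.condition == "proviral")
    b = sum(1 for c in young if c.condition == "solo-LTR")
    c_ = sum(1 for c in old if c.condition == "proviral")
    d = sum(1 for c in old if c.condition == "solo-LTR")
    if 0 in (a + b, c_ + d):
        raise ParameterError("empty age class")
    res = chisq_2x2(a, b, c_, d)
    return {
        "young": {"proviral": a, "solo-LTR": b},
        "old": {"proviral": c_, "solo-LTR": d},
        "chi2": res.chi2,
        "p": res.p,
    }


def summarize_tables(copies, cmap, genes=(), cluster_mode: str = "edge"):
    """Arm / heterochromatin / euchromatin census tables.

    Returns three DataFrames in the census layout: per arm, per
    heterochromatin type (H, PH, DIH, CIH per arm plus totals) and per
    euchromatin type (E, PE, NPE per arm plus totals)."""
    from .context import region_density

    het = ("PH", "DIH", "CIH")
    eu = ("PE", "NPE", "EU")

    def rows_for(groups):
        rows = []
        for label, regions in groups:
            if not regions:
                continue
            rows.append(
                region_density(
                    copies, regions, label, genes, cluster_mode=cluster_mode
                ).as_row()
            )
        return pd.DataFrame(rows)

    arms = sorted(cmap.arms)
    arm_groups = [(arm, [(arm, s, e) for s, e, _l in cmap.arms[arm]]) for arm in arms]
    arm_groups.append(("Total", [(a, s, e) for a, s, e, _l in cmap.intervals()]))

    het_groups = []
    for arm in arms:
        het_groups.append((f"{arm}_H", cmap.regions(het) and [
            (a, s, e) for a, s, e in cmap.regions(het) if a == arm
        ]))
        for t in het:
            het_groups.append(
                (f"{arm}_{t}", [(a, s, e) for a, s, e in cmap.regions(t) if a == arm])
            )
    het_groups.append(("Total_H", cmap.regions(het)))
    for t in het:
        het_groups.append((f"Total_{t}", cmap.regions(t)))

    eu_groups = []
    for arm in arms:
        eu_groups.append(
            (f"{arm}_E", [(a, s, e) for a, s, e in cmap.regions(("PE", "NPE", "EU")) if a == arm])
        )
        for t in ("PE", "NPE"):
            eu_groups.append(
                (f"{arm}_{t}", [(a, s, e) for a, s, e in cmap.regions(t) if a == arm])
            )
    eu_groups.append(("Total_E", cmap.regions(eu)))
    for t in ("PE", "NPE"):
        eu_groups.append((f"Total_{t}", cmap.regions(t)))

    return rows_for(arm_groups), rows_for(het_groups), rows_for(eu_groups)
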