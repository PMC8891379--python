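"""Group summarization, regulatory compliance, and one-way ANOVA.

Summaries are organized like the study's published tables: per product
type, the mean/SD/min/max of each congener plus two derived scores — the
sum over the full 16-congener panel (``Total``) and the EU regulatory
``PAH4`` sum (BaA + Ch + BbF + BaP).  The ``Overall`` row aggregates as
the *unweighted* mean of group means (extrema of group extrema), the
convention that reproduces the published study-level figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SampleDataset, ValidationError

__all__ = [
    "TOTAL_COL",
    "PAH4_COL",
    "GroupSummaryTable",
    "ComplianceReport",
    "congener_sum",
    "summarize_groups",
    "extreme_groups",
    "compliance",
    "oneway_anova",
    "anova_from_groups",
]

TOTAL_COL = "Total"   # sum over the 16-congener panel (aka sigma-PAH16)
PAH4_COL = "PAH4"

STATS = ("mean", "sd", "min", "max")


@dataclass(frozen=True)
class GroupSummaryTable:
    """Per-product-type summary statistics.

    ``table`` is indexed by ``(product_type, stat)`` with one column per
    congener plus ``Total`` and ``PAH4``; ``overall`` holds the
    unweighted across-group aggregate with the same columns, indexed by
    stat.  ``n_per_group`` records group sizes.
    """

    table: pd.DataFrame
    overall: pd.DataFrame
    n_per_group: Mapping[str, int]

    @property
    def groups(self) -> list[str]:
        return list(self.table.index.get_level_values(0).unique())

    def stat(self, stat: str) -> pd.DataFrame:
        """Group x column table of a single statistic."""
        return self.table.xs(stat, level=1)

    @property
    def means(self) -> pd.DataFrame:
        return self.stat("mean")


def congener_sum(values: Mapping[str, float], subset: Iterable[str]) -> float:
    """Arithmetic sum of per-congener concentrations over ``subset`` (ug/kg)."""
    subset = list(subset)
    missing = [a for a in subset if a not in values]
    if missing:
        raise ValidationError(f"missing congeners in sum: {missing}")
    return float(sum(values[a] for a in subset))


def summarize_groups(ds: SampleDataset) -> GroupSummaryTable:
    """Summarize an imputed dataset per product type and overall.

    Per-sample ``Total`` and ``PAH4`` sums are computed first, so their
    group SD/min/max reflect sample-level variation.  Single-sample
    groups report SD 0 by convention.
    """
    conc = ds.concentrations()
    conc[TOTAL_COL] = conc[list(ds.panel.abbrevs)].sum(axis=1)
    conc[PAH4_COL] = conc[list(ds.panel.pah4_members)].sum(axis=1)
    groups = ds.product_types

    blocks = []
    sizes: dict[str, int] = {}
    for g, sub in conc.groupby(groups, sort=False):
        if len(sub) == 0:  # pragma: no cover - groupby never yields empties
            warnings.warn(f"empty group {g!r} omitted")
            continue
        sizes[g] = len(sub)
        sd = sub.std(ddof=1).fillna(0.0) if len(sub) > 1 else sub.iloc[0] * 0.0
        block = pd.DataFrame(
            {
                "mean": sub.mean(),
                "sd": sd,
                "min": sub.min(),
                "max": sub.max(),
            }
        ).T
        block.index = pd.MultiIndex.from_product([[g], block.index])
        blocks.append(block)
    if not blocks:
        raise ValidationError("dataset contains no samples")
    table = pd.concat(blocks)

    overall = pd.DataFrame(
        {
            "mean": table.xs("mean", level=1).mean(),
            "sd": table.xs("mean", level=1).std(ddof=1).fillna(0.0),
            "min": table.xs("min", level=1).min(),
            "max": table.xs("max", level=1).max(),
        }
    ).T
    return GroupSummaryTable(table=table, overall=overall, n_per_group=sizes)


def extreme_groups(
    table: GroupSummaryTable, statistic: str
) -> tuple[str, float, str, float]:
    """(argmax group, max, argmin group, min) of a group-mean statistic.

    ``statistic`` is a congener abbreviation, ``Total`` or ``PAH4``;
    ties resolve to the first group in table order.
    """
    means = table.means
    if statistic not in means.columns:
        raise ValidationError(f"unknown statistic {statistic!r}")
    col = means[statistic]
    imax = int(np.argmax(col.to_numpy()))
    imin = int(np.argmin(col.to_numpy()))
    return (
        str(col.index[imax]), float(col.iloc[imax]),
        str(col.index[imin]), float(col.iloc[imin]),
    )


@dataclass(frozen=True)
class ComplianceReport:
    """Strict-inequality check of group means against regulatory limits."""

    limits: Mapping[str, float]
    flags: pd.DataFrame  # group x {bap_mean, bap_compliant, pah4_mean, pah4_compliant}

    @property
    def all_compliant(self) -> bool:
        return bool(
            self.flags[["bap_compliant", "pah4_compliant"]].all(axis=None)
        )


def compliance(
    table: GroupSummaryTable,
    limits: Mapping[str, float] | None = None,
) -> ComplianceReport:
    """Check group BaP and PAH4 means against limits (default 1 ug/kg each).

    A mean exactly equal to the limit is non-compliant (strict ``<``).
    """
    limits = dict(limits or {"BaP": 1.0, "PAH4": 1.0})
    if any(v <= 0 for v in limits.values()):
        raise ValidationError("limits must be positive")
    means = table.means
    flags = pd.DataFrame(
        {
            "bap_mean": means["BaP"],
            "bap_compliant": means["BaP"] < limits["BaP"],
            "pah4_mean": means[PAH4_COL],
            "pah4_compliant": means[PAH4_COL] < limits["PAH4"],
        }
    )
    return ComplianceReport(limits=limits, flags=flags)


def anova_from_groups(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects F test from its sums of squares.

    Degenerate inputs: if both between- and within-group sums of squares
    are zero (all observations identical) the test is uninformative and
    returns ``(0.0, 1.0)``; zero within-group variance with distinct
    means returns ``(inf, 0.0)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


def oneway_anova(ds: SampleDataset, statistic: str) -> tuple[float, float]:
    """One-way ANOVA of a congener (or ``Total``/``PAH4``) across product types.

    With two product types this is the two-sample equal-variance t test
    (F = t**2).
    """
    conc = ds.concentrations()
    conc[TOTAL_COL] = conc[list(ds.panel.abbrevs)].sum(axis=1)
    conc[PAH4_COL] = conc[list(ds.panel.pah4_members)].sum(axis=1)
    if statistic not in conc.columns:
        raise ValidationError(f"unknown statistic {statistic!r}")
    labels = ds.product_types
    arrays = [
        conc.loc[labels.index[labels == g], statistic].to_numpy()
        for g in labels.unique()
    ]
    return anova_from_groups(arrays)
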