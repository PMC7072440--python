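"""Marker-by-target stratified survival reporting.

Three views of a cohort:

* ``single_gene_prognosis`` — the classical per-gene analysis: median split
  on one gene's expression, Kaplan-Meier curves per group, log-rank test.
* ``two_stage_prognosis`` — mean split on a marker gene, then a median split
  on the target gene *within* each marker stratum, giving four disjoint
  patient groups and one log-rank (target-low vs target-high) per stratum.
  This is the analysis that exposes a marker-dependent reversal of the
  target's prognostic direction.
* ``target_by_marker_expression_contrast`` — ignores survival: splits
  patients at the target's median and compares the marker's expression
  between the two groups with Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import Cohort
from .survival import LogRankResult, dichotomize, km_curve, logrank

__all__ = [
    "GenePrognosis",
    "StratifiedReport",
    "ExpressionContrast",
    "single_gene_prognosis",
    "two_stage_prognosis",
    "target_by_marker_expression_contrast",
]


@dataclass(frozen=True)
class GenePrognosis:
    """Median-split survival comparison for one gene in one cohort."""

    cohort: str
    gene: str
    threshold: float
    test: LogRankResult
    km_low: pd.DataFrame
    km_high: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        row = {"cohort": self.cohort, "gene": self.gene, "threshold": self.threshold}
        row.update(self.test.summary_row())
        return pd.DataFrame([row])


@dataclass(frozen=True)
class StratifiedReport:
    """Two-stage marker/target analysis: four groups, one test per stratum."""

    cohort: str
    marker_gene: str
    target_gene: str
    marker_threshold: float
    target_thresholds: dict  # stratum -> median used inside it
    tests: dict  # stratum ("marker_low"/"marker_high") -> LogRankResult
    km: dict  # (stratum, "target_low"/"target_high") -> KM step table
    group_sizes: dict  # same keys as km -> int

    def summary(self) -> pd.DataFrame:
        rows = []
        for stratum, res in self.tests.items():
            row = {
                "cohort": self.cohort,
                "marker_gene": self.marker_gene,
                "target_gene": self.target_gene,
                "stratum": stratum,
                "target_threshold": self.target_thresholds[stratum],
            }
            row.update(res.summary_row())
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExpressionContrast:
    """Marker expression compared between target-low and target-high patients."""

    cohort: str
    target_gene: str
    marker_gene: str
    mean_low: float
    mean_high: float
    t_statistic: float
    p_value: float
    n_low: int
    n_high: int


def single_gene_prognosis(cohort: Cohort, gene: str) -> GenePrognosis:
    """Median-dichotomize one gene and log-rank the two groups."""
    expr = cohort.gene(gene)
    time, event = cohort.survival()
    split = dichotomize(expr, rule="median")
    lo, hi = ~split.high, split.high
    test = logrank(time[lo], event[lo], time[hi], event[hi])
    return GenePrognosis(
        cohort=cohort.name,
        gene=gene,
        threshold=split.threshold,
        test=test,
        km_low=km_curve(time[lo], event[lo]),
        km_high=km_curve(time[hi], event[hi]),
    )


def two_stage_prognosis(
    cohort: Cohort,
    marker_gene: str,
    target_gene: str,
    marker_rule: str = "mean",
) -> StratifiedReport:
    """Mean split on the marker, then median split on the target per stratum.

    The four groups partition the cohort; each stratum's log-rank compares
    target-low vs target-high among that stratum's patients only.  Raises if
    any of the four groups is empty (degenerate expression).
    """
    marker = cohort.gene(marker_gene)
    target = cohort.gene(target_gene)
    time, event = cohort.survival()

    m_split = dichotomize(marker, rule=marker_rule)
    tests, km, sizes, thresholds = {}, {}, {}, {}
    for stratum, mask in (("marker_low", ~m_split.high), ("marker_high", m_split.high)):
        try:
            t_split = dichotomize(target[mask], rule="median")
        except ValueError as exc:
            raise ValueError(f"{stratum}: target split degenerate ({exc})") from exc
        thresholds[stratum] = t_split.threshold
        for grp, gmask in (("target_low", ~t_split.high), ("target_high", t_split.high)):
            if not gmask.any():
                raise ValueError(f"empty group: {stratum}/{grp}")
            sizes[(stratum, grp)] = int(gmask.sum())
            km[(stratum, grp)] = km_curve(time[mask][gmask], event[mask][gmask])
        lo, hi = ~t_split.high, t_split.high
        tests[stratum] = logrank(
            time[mask][lo], event[mask][lo], time[mask][hi], event[mask][hi]
        )
    return StratifiedReport(
        cohort=cohort.name,
        marker_gene=marker_gene,
        target_gene=target_gene,
        marker_threshold=m_split.threshold,
        target_thresholds=thresholds,
        tests=tests,
        km=km,
        group_sizes=sizes,
    )


def target_by_marker_expression_contrast(
    cohort: Cohort, target_gene: str, marker_gene: str
) -> ExpressionContrast:
    """Welch t-test of marker expression between target-low/high patients."""
    target = cohort.gene(target_gene)
    marker = cohort.gene(marker_gene)
    split = dichotomize(target, rule="median")
    lo, hi = marker[~split.high], marker[split.high]
    t_stat, p = stats.ttest_ind(hi, lo, equal_var=False)
    return ExpressionContrast(
        cohort=cohort.name,
        target_gene=target_gene,
        marker_gene=marker_gene,
        mean_low=float(lo.mean()),
        mean_high=float(hi.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_low=lo.size,
        n_high=hi.size,
    )
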