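"""Iterative patient partitioning (IPP) and the companion-marker screen.

The conventional prognostic log-rank test fixes one patient partition (for
example the median split) and is therefore sensitive to where that single
cut falls.  The IPP score instead iterates over *every* admissible rank
cut-point of the target gene's expression: for each cut ``k`` from
``k_min`` to ``n - k_min`` the ``k`` lowest-expressing patients form the low
group, the signed log-rank z of low vs high is computed, and the IPP score
is the arithmetic mean of the valid z values.  It stays on the z scale (so
sqrt(n)-weighted Liptak combination across cohorts is coherent), inherits
the sign convention (negative = high target expression adverse), and
collapses to the classical median-split z when the cut range contains only
the median partition.

The companion-marker screen stratifies each cohort's patients by a candidate
marker gene (mean split by default), scores the target gene by IPP within
each stratum, trims the single largest and smallest per-dataset scores,
and Liptak-combines the retained scores per stratum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meta import MetaResult, liptak_combine
from .preprocessing import Cohort
from .survival import all_cut_logrank_z, dichotomize

log = logging.getLogger(__name__)

__all__ = [
    "IPPRecord",
    "ipp_score",
    "ipp_cut_range",
    "marker_conditional_ipp",
    "trimmed_aggregate",
    "screen_markers",
]

DEFAULT_MIN_GROUP_FRAC = 0.2
MIN_GROUP_FLOOR = 5


@dataclass(frozen=True)
class IPPRecord:
    """Per-cohort, per-stratum IPP evidence (one row of a screen table)."""

    dataset: str
    stratum: str  # marker_low | marker_high | unstratified
    n: int
    weight: float  # sqrt(n)
    ipp_score: float
    valid: bool = True
    note: str = ""


def ipp_cut_range(n: int, min_group_frac: float = DEFAULT_MIN_GROUP_FRAC) -> tuple[int, int]:
    """Admissible rank cut-points for a stratum of n patients.

    ``k_min = max(5, ceil(min_group_frac * n))`` keeps both groups above a
    floor so no partition rests on a handful of patients; cuts run from
    ``k_min`` to ``n - k_min`` inclusive.
    """
    if not 0 < min_group_frac <= 0.5:
        raise ValueError("min_group_frac must be in (0, 0.5]")
    k_min = max(MIN_GROUP_FLOOR, math.ceil(min_group_frac * n))
    return k_min, n - k_min


def ipp_score(
    target_expr,
    time,
    event,
    min_group_frac: float = DEFAULT_MIN_GROUP_FRAC,
) -> float:
    """IPP score of a gene against survival: mean signed log-rank z over cuts.

    Patients are ranked by ``target_expr`` (stable order on ties); partitions
    with a degenerate log-rank variance are skipped.  Raises when the cut
    range is empty (cohort too small) or no partition yields a defined z.
    """
    target_expr = np.asarray(target_expr, dtype=float)
    n = target_expr.size
    k_min, k_max = ipp_cut_range(n, min_group_frac)
    if k_min > k_max:
        raise ValueError(
            f"cohort too small for IPP: n={n} admits no cut with k_min={k_min}"
        )
    z = all_cut_logrank_z(target_expr, time, event, k_min, k_max)
    valid = z[np.isfinite(z)]
    if valid.size == 0:
        raise ValueError("no valid partition: every cut had degenerate variance")
    return float(valid.mean())


def marker_conditional_ipp(
    cohort: Cohort,
    target_gene: str,
    marker_gene: str,
    marker_rule: str = "mean",
    min_group_frac: float = DEFAULT_MIN_GROUP_FRAC,
    min_stratum_size: int = 10,
) -> tuple[IPPRecord, IPPRecord]:
    """IPP score of the target gene within each marker-defined stratum.

    Patients are split at the marker's mean (or median) expression; the
    target's IPP score is computed separately among marker-low and
    marker-high patients.  A stratum below ``min_stratum_size`` (or failing
    the IPP preconditions) yields a record flagged ``valid=False`` so it can
    be excluded downstream without being silently dropped.
    """
    marker = cohort.gene(marker_gene)
    target = cohort.gene(target_gene)
    time, event = cohort.survival()

    split = dichotomize(marker, rule=marker_rule)
    records = []
    for stratum, mask in (("marker_low", ~split.high), ("marker_high", split.high)):
        n = int(mask.sum())
        rec = dict(
            dataset=cohort.name,
            stratum=stratum,
            n=n,
            weight=float(np.sqrt(n)) if n else 0.0,
            ipp_score=float("nan"),
            valid=False,
            note="",
        )
        if n < min_stratum_size:
            rec["note"] = f"stratum size {n} < minimum {min_stratum_size}"
            log.warning("%s/%s/%s: %s", cohort.name, marker_gene, stratum, rec["note"])
        else:
            try:
                rec["ipp_score"] = ipp_score(
                    target[mask], time[mask], event[mask], min_group_frac
                )
                rec["valid"] = True
            except ValueError as exc:
                rec["note"] = str(exc)
                log.warning("%s/%s/%s: %s", cohort.name, marker_gene, stratum, exc)
        records.append(IPPRecord(**rec))
    return records[0], records[1]


def trimmed_aggregate(records: list[IPPRecord]) -> tuple[float, str, str]:
    """Mean IPP score after removing the single max and single min record.

    Requires >= 3 records.  Ties for the extreme are broken by removing the
    first dataset in name order (deterministic).  Returns the aggregate and
    the names of the excluded max and min datasets.
    """
    if len(records) < 3:
        raise ValueError(f"trimmed aggregation needs >= 3 records, got {len(records)}")
    scores = {r.dataset: r.ipp_score for r in records}
    if len(scores) != len(records):
        raise ValueError("duplicate dataset names in trimmed aggregation")
    hi = max(scores.values())
    excluded_max = min(d for d, s in scores.items() if s == hi)
    rest = {d: s for d, s in scores.items() if d != excluded_max}
    lo = min(rest.values())
    excluded_min = min(d for d, s in rest.items() if s == lo)
    kept = [s for d, s in rest.items() if d != excluded_min]
    return float(np.mean(kept)), excluded_max, excluded_min


def _stratum_summary(records: list[IPPRecord]) -> dict:
    """Trim + Liptak-combine one stratum's valid per-cohort records."""
    valid = [r for r in records if r.valid]
    out: dict = {
        "n_datasets_used": 0,
        "aggregate": float("nan"),
        "excluded_max": "",
        "excluded_min": "",
        "z_combined": float("nan"),
        "p_one_sided": float("nan"),
    }
    if len(valid) < 3:
        return out
    agg, ex_max, ex_min = trimmed_aggregate(valid)
    kept = [r for r in valid if r.dataset not in (ex_max, ex_min)]
    meta: MetaResult = liptak_combine(
        [r.ipp_score for r in kept], [r.weight for r in kept]
    )
    out.update(
        n_datasets_used=len(kept),
        aggregate=agg,
        excluded_max=ex_max,
        excluded_min=ex_min,
        z_combined=meta.z_combined,
        p_one_sided=meta.p_one_sided,
    )
    return out


def screen_markers(
    cohorts: list[Cohort],
    target_gene: str,
    candidate_markers: list[str],
    marker_rule: str = "mean",
    min_group_frac: float = DEFAULT_MIN_GROUP_FRAC,
    min_stratum_size: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank candidate marker genes by stratum-conditional IPP evidence.

    For every candidate marker: per-cohort marker-conditional IPP, max/min
    trimming per stratum, and Liptak combination of the retained scores.
    Returns ``(table, records)``: the ranked screen table (one row per
    marker, nothing filtered) and the flat per-cohort record table.  Rows are
    ranked by ascending high-stratum combined p, with the absolute
    high-vs-low aggregate contrast (descending) as tiebreak.  A marker absent
    from a cohort skips that cohort and notes it in the row.
    """
    if len(cohorts) < 3:
        raise ValueError("screen needs >= 3 cohorts")
    for c in cohorts:
        if target_gene not in c.expr.index:
            raise ValueError(f"target gene {target_gene!r} missing from cohort {c.name}")
    if not candidate_markers:
        raise ValueError("no candidate markers supplied")

    rows, flat = [], []
    for marker in sorted(set(candidate_markers)):
        low_recs, high_recs, skipped = [], [], []
        for c in cohorts:
            if marker not in c.expr.index:
                skipped.append(c.name)
                continue
            try:
                lo, hi = marker_conditional_ipp(
                    c, target_gene, marker,
                    marker_rule=marker_rule,
                    min_group_frac=min_group_frac,
                    min_stratum_size=min_stratum_size,
                )
            except ValueError as exc:
                log.warning("%s/%s: %s", c.name, marker, exc)
                skipped.append(c.name)
                continue
            low_recs.append(lo)
            high_recs.append(hi)
            flat.extend([lo, hi])

        low = _stratum_summary(low_recs)
        high = _stratum_summary(high_recs)
        contrast = abs(high["aggregate"] - low["aggregate"])
        rows.append(
            {
                "marker_gene": marker,
                "self_stratification": marker == target_gene,
                "low_aggregate": low["aggregate"],
                "high_aggregate": high["aggregate"],
                "aggregate_contrast": contrast,
                "low_z_combined": low["z_combined"],
                "low_p_one_sided": low["p_one_sided"],
                "high_z_combined": high["z_combined"],
                "high_p_one_sided": high["p_one_sided"],
                "n_datasets_used_low": low["n_datasets_used"],
                "n_datasets_used_high": high["n_datasets_used"],
                "excluded_max_low": low["excluded_max"],
                "excluded_min_low": low["excluded_min"],
                "excluded_max_high": high["excluded_max"],
                "excluded_min_high": high["excluded_min"],
                "cohorts_skipped": ";".join(skipped),
            }
        )

    table = pd.DataFrame(rows)
    # NaN combined p (too few cohorts) sorts last; contrast NaN likewise
    table = table.sort_values(
        by=["high_p_one_sided", "aggregate_contrast", "marker_gene"],
        ascending=[True, False, True],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))

    records = pd.DataFrame([r.__dict__ for r in flat])
    return table, records
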