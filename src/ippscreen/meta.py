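"""Liptak's weighted z-score meta-analysis over per-dataset stratum scores.

Independent z-scale statistics z_i with weights w_i combine as

    Z = sum(w_i * z_i) / sqrt(sum(w_i**2)),

which is again standard normal under the joint null.  Weights here are the
square root of the dataset (stratum) sample size, so larger cohorts carry
proportionally more evidence.  Under the package's sign convention
(negative = high target expression adverse) the one-sided p-value is the
lower normal tail Phi(Z): the probability of a combined score at least as
adverse under the null.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaResult",
    "liptak_combine",
    "weight_from_n",
    "read_stratum_table",
    "combine_stratum_table",
    "format_stratum_table",
]


@dataclass(frozen=True)
class MetaResult:
    z_combined: float
    p_one_sided: float
    weights_used: tuple
    scores_used: tuple

    def __post_init__(self):
        if len(self.weights_used) != len(self.scores_used) or not self.scores_used:
            raise ValueError("weights and scores must be equal-length and nonempty")


def weight_from_n(n: int) -> float:
    """Meta-analysis weight for a stratum of n patients: sqrt(n)."""
    if int(n) != n or n < 1:
        raise ValueError(f"sample size must be a positive integer, got {n!r}")
    return float(np.sqrt(n))


def liptak_combine(scores, weights) -> MetaResult:
    """Combine signed z-scale scores with positive weights.

    Scale-invariant in the weights; a single score passes through unchanged.
    """
    z = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if z.size == 0 or z.shape != w.shape or z.ndim != 1:
        raise ValueError("scores and weights must be nonempty 1-d arrays of equal length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)) or not np.all(np.isfinite(z)):
        raise ValueError("weights must be positive and finite, scores finite")
    z_comb = float((w * z).sum() / np.sqrt((w * w).sum()))
    return MetaResult(
        z_combined=z_comb,
        p_one_sided=float(stats.norm.cdf(z_comb)),
        weights_used=tuple(w.tolist()),
        scores_used=tuple(z.tolist()),
    )


_SQRT_N = re.compile(r"^\s*([-+0-9.eE]+)\s*\(\s*(\d+)\s*\)\s*$")


def _parse_sqrt_n(cell: str, where: str) -> tuple[float, int]:
    m = _SQRT_N.match(str(cell))
    if not m:
        raise ValueError(f"{where}: expected 'sqrt (N)' cell, got {cell!r}")
    return float(m.group(1)), int(m.group(2))


def read_stratum_table(source) -> pd.DataFrame:
    """Parse a per-dataset stratum score table.

    Expected tab-separated columns: dataset name, low-stratum ``sqrt (N)``,
    high-stratum ``sqrt (N)``, low-stratum score, high-stratum score — the
    layout used for published multi-cohort IPP summaries.  A header line is
    tolerated; summary rows (combined z / p lines) are ignored.  Returns a
    DataFrame with columns dataset, n_low, n_high, sqrt_low, sqrt_high,
    score_low, score_high.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    raw = pd.read_csv(source, sep="\t", header=None, dtype=str, skip_blank_lines=True)
    if raw.shape[1] < 5:
        raise ValueError("stratum table needs 5 tab-separated columns")
    rows = []
    for lineno, rec in enumerate(raw.itertuples(index=False), start=1):
        cells = [str(c) for c in rec[:5]]
        if not _SQRT_N.match(cells[1]):
            continue  # header or combined-summary row
        where = f"line {lineno}"
        s_lo, n_lo = _parse_sqrt_n(cells[1], where)
        s_hi, n_hi = _parse_sqrt_n(cells[2], where)
        try:
            z_lo, z_hi = float(cells[3]), float(cells[4])
        except ValueError as exc:
            raise ValueError(f"{where}: non-numeric score cell") from exc
        rows.append((cells[0], n_lo, n_hi, s_lo, s_hi, z_lo, z_hi))
    if not rows:
        raise ValueError("stratum table contained no data rows")
    return pd.DataFrame(
        rows,
        columns=[
            "dataset", "n_low", "n_high", "sqrt_low", "sqrt_high",
            "score_low", "score_high",
        ],
    )


def combine_stratum_table(table: pd.DataFrame) -> dict[str, MetaResult]:
    """Liptak-combine the low and high stratum columns of a parsed table.

    Weights are recomputed as exact sqrt(N) from the printed group sizes
    (the 4-decimal sqrt cells are display rounding).
    """
    out = {}
    for stratum in ("low", "high"):
        weights = [weight_from_n(n) for n in table[f"n_{stratum}"]]
        out[stratum] = liptak_combine(table[f"score_{stratum}"], weights)
    return out


def format_stratum_table(table: pd.DataFrame, combined: dict[str, MetaResult]) -> str:
    """Render a stratum table plus its combined rows in the published style."""
    lines = [
        "Data-Set\tSQRT Low Group (N)\tSQRT High Group (N)\t"
        "Low Group IPPScore\tHigh Group IPPScore"
    ]
    def _w(v: float) -> str:  # 4-dp display, bare integers unpadded
        return f"{v:.4f}".rstrip("0").rstrip(".")

    for rec in table.itertuples(index=False):
        lines.append(
            f"{rec.dataset}\t{_w(rec.sqrt_low)} ({rec.n_low})\t"
            f"{_w(rec.sqrt_high)} ({rec.n_high})\t{rec.score_low}\t{rec.score_high}"
        )
    lines.append(
        f"Liptak's z-value\t{combined['low'].z_combined:.9g}"
        f"\t{combined['high'].z_combined:.9g}"
    )
    lines.append(
        f"Liptak's p-value\t{combined['low'].p_one_sided:.9g}"
        f"\t{combined['high'].p_one_sided:.9g}"
    )
    return "\n".join(lines)
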