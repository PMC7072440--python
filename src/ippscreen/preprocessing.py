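"""Raw expression tables -> normalized gene-level cohorts with survival.

Input dialects (all tab-separated text, optionally gzip-compressed):

* expression matrix: first column probe/gene identifier, header row of
  sample ids, one row per probe (the common series-matrix tabular layout);
* probe-to-gene mapping: two columns (probe, gene), no header required;
* clinical table: columns ``sample_id``, ``time``, ``event``.

Expression values are assumed to already be on a roughly log/normalized
scale; no log transform is applied here.  Missing values are rejected at
load time rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "read_expression",
    "read_mapping",
    "read_clinical",
    "map_probes_to_genes",
    "quantile_normalize",
    "assemble_cohort",
    "load_cohort",
]


@dataclass
class Cohort:
    """One dataset: gene-by-patient expression joined to survival.

    ``expr`` is a genes x samples DataFrame with unique gene ids as index;
    ``time`` (positive, days or months per ``time_unit``) and ``event``
    (1 = death observed, 0 = censored) are Series indexed by the same sample
    ids, in the same column order as ``expr``.
    """

    name: str
    expr: pd.DataFrame
    time: pd.Series
    event: pd.Series
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            raise ValueError(f"{self.name}: duplicated gene ids")
        if self.expr.columns.has_duplicates:
            raise ValueError(f"{self.name}: duplicated sample ids")
        if not (
            list(self.expr.columns) == list(self.time.index) == list(self.event.index)
        ):
            raise ValueError(f"{self.name}: expression/clinical samples misaligned")
        if not np.all(np.isfinite(self.expr.to_numpy())):
            raise ValueError(f"{self.name}: non-finite expression values")
        if (self.time <= 0).any() or not np.all(np.isfinite(self.time)):
            raise ValueError(f"{self.name}: survival times must be finite and > 0")
        bad = sorted(set(self.event.unique()) - {0, 1})
        if bad:
            raise ValueError(f"{self.name}: non-binary event codes {bad}")

    @property
    def n(self) -> int:
        return self.expr.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across patients."""
        if gene_id not in self.expr.index:
            raise KeyError(f"{self.name}: gene {gene_id!r} not present")
        return self.expr.loc[gene_id].to_numpy(dtype=float)

    def survival(self) -> tuple[np.ndarray, np.ndarray]:
        return self.time.to_numpy(dtype=float), self.event.to_numpy(dtype=int)


def _read_tsv(path, **kw) -> pd.DataFrame:
    # pandas infers gzip from the .gz suffix
    return pd.read_csv(path, sep="\t", **kw)


def read_expression(path) -> pd.DataFrame:
    """Read a probe/gene x sample expression matrix."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample ids {dup}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: expression matrix contains missing/non-numeric values")
    return df


def read_mapping(path) -> pd.DataFrame:
    """Read a two-column probe -> gene mapping table."""
    df = _read_tsv(path, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mapping table needs two columns (probe, gene)")
    df = df.iloc[:, :2]
    df.columns = ["probe", "gene"]
    # tolerate an optional header line
    if df.iloc[0].str.lower().tolist() in (["probe", "gene"], ["probe_id", "gene_id"]):
        df = df.iloc[1:]
    return df.dropna().reset_index(drop=True)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table with sample_id, time, event columns."""
    df = _read_tsv(path)
    needed = {"sample_id", "time", "event"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def map_probes_to_genes(expr: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe rows to gene rows by averaging.

    Every probe contributes to every gene it maps to (multi-mapped probes are
    not dropped); probes without a mapping are dropped.  The output gene row
    is the arithmetic mean over its mapped probe rows.
    """
    mapping = mapping[mapping["probe"].isin(expr.index)]
    if mapping.empty:
        raise ValueError(
            "probe mapping shares no probes with the expression matrix "
            "(check the mapping file)"
        )
    multi = mapping["probe"].duplicated().sum()
    if multi:
        log.info("%d probe(s) map to multiple genes; contributing to each", multi)
    rows = expr.loc[mapping["probe"].to_numpy()]
    genes = rows.groupby(mapping["gene"].to_numpy()).mean()
    genes.index.name = expr.index.name
    return genes


def quantile_normalize(genes: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across sample columns.

    The reference distribution is the per-rank mean of the column-sorted
    values; tied values within a column receive the mean of the reference
    values over their tie block.  After normalization every column has the
    same sorted multiset (up to that tie-averaging).
    """
    if genes.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = genes.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("quantile normalization requires finite values")
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average reference values over blocks of tied input values
        tied = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = tied.to_numpy()
    return pd.DataFrame(out, index=genes.index, columns=genes.columns)


def quantile_normalize_pooled(matrices: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Quantile-normalize several cohorts against one pooled reference.

    Columns of all matrices are pooled (on the intersection of their gene
    sets) so every sample in every cohort is forced to the same reference
    distribution, then split back per cohort.  Use when batch effects across
    cohorts should be removed jointly; per-cohort normalization is
    ``quantile_normalize`` applied to each matrix separately.
    """
    if not matrices:
        raise ValueError("no matrices to normalize")
    shared = matrices[0].index
    for m in matrices[1:]:
        shared = shared.intersection(m.index)
    if shared.empty:
        raise ValueError("pooled normalization: no shared genes across cohorts")
    cols = [m.shape[1] for m in matrices]
    pooled = pd.concat(
        [m.loc[shared].add_suffix(f"::{i}") for i, m in enumerate(matrices)], axis=1
    )
    normed = quantile_normalize(pooled)
    out, start = [], 0
    for i, m in enumerate(matrices):
        block = normed.iloc[:, start : start + cols[i]]
        block.columns = m.columns
        out.append(block)
        start += cols[i]
    return out


def assemble_cohort(
    name: str,
    genes: pd.DataFrame,
    clinical: pd.DataFrame,
    time_unit: str = "months",
) -> Cohort:
    """Join a gene matrix to clinical annotations into a Cohort.

    Keeps the intersection of expression and clinical samples in sorted
    sample-id order (deterministic regardless of input row order); samples
    present on one side only are logged and dropped.
    """
    clinical = clinical.drop_duplicates(subset="sample_id")
    bad = sorted(set(clinical["event"].unique()) - {0, 1})
    if bad:
        raise ValueError(f"{name}: non-binary event codes {bad}")
    clin = clinical.set_index("sample_id")

    shared = sorted(set(genes.columns) & set(clin.index))
    if not shared:
        raise ValueError(f"{name}: no overlapping samples between expression and clinical")
    dropped = (set(genes.columns) | set(clin.index)) - set(shared)
    if dropped:
        log.warning("%s: dropping %d unmatched sample(s)", name, len(dropped))

    expr = genes.loc[:, shared]
    return Cohort(
        name=name,
        expr=expr,
        time=clin.loc[shared, "time"].astype(float),
        event=clin.loc[shared, "event"].astype(int),
        time_unit=time_unit,
    )


def load_cohort(
    name: str,
    expression_path,
    clinical_path,
    mapping_path=None,
    normalize: bool = True,
    time_unit: str = "months",
) -> Cohort:
    """Read, collapse, optionally quantile-normalize, and assemble one cohort."""
    expr = read_expression(expression_path)
    if mapping_path is not None:
        expr = map_probes_to_genes(expr, read_mapping(mapping_path))
    if normalize:
        expr = quantile_normalize(expr)
    return assemble_cohort(name, expr, read_clinical(clinical_path), time_unit=time_unit)
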