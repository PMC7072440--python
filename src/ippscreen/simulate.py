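"""Synthetic multi-cohort expression + survival data.

The generator emulates the statistical structure the screening pipeline
assumes: log-scale expression values, right-censored survival, a per-cohort
batch effect, and a marker-by-target *interaction* in which the target
gene's prognostic effect is active only in marker-high patients (so its
prognostic direction vanishes — or reverses, with ``beta_main`` of the
opposite sign — by marker stratum).

Model
-----
Gene expression is Gaussian on the log scale; the marker and target latent
values are correlated at ``expression_corr``, the remaining (decoy) genes
are independent.  Each cohort applies one affine batch perturbation
``value = latent * scale_c + shift_c`` to all genes — a monotone map, so
rank-based statistics are untouched and quantile normalization can remove
it.  Survival times are exponential with patient hazard

    h_i = baseline_hazard * exp(beta_main * x_t,i
                                + beta_interaction * x_t,i * 1[marker_i > mean marker])

where ``x_t`` is the standardized target expression.  Censoring is
administrative-uniform on ``(0, c_max)`` with ``c_max`` tuned by bisection
so the expected censored fraction equals ``censoring_rate``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import Cohort

__all__ = ["SimConfig", "SimTruth", "simulate_cohorts", "write_fixture"]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a pancreatic-cancer-like multi-cohort screen: five
    cohorts of 200 patients, 50 genes, survival times in months with a
    baseline hazard of 0.05/month (median survival ~14 months), 30%
    censoring, and a planted interaction of log-hazard 0.8 per SD of target
    expression confined to marker-high patients.
    """

    n_cohorts: int = 5
    n_per_cohort: int | list[int] = 200
    n_genes: int = 50
    marker_index: int = 0
    target_index: int = 1
    beta_interaction: float = 0.8
    beta_main: float = 0.0
    baseline_hazard: float = 0.05
    censoring_rate: float = 0.3
    expression_corr: float = 0.0
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes (marker and target)")
        idx = (self.marker_index, self.target_index)
        if self.marker_index == self.target_index or any(
            not 0 <= i < self.n_genes for i in idx
        ):
            raise ValueError("marker/target indices must be distinct and < n_genes")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if not -1 < self.expression_corr < 1:
            raise ValueError("expression_corr must be in (-1, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")

    @property
    def cohort_sizes(self) -> list[int]:
        if isinstance(self.n_per_cohort, int):
            sizes = [self.n_per_cohort] * self.n_cohorts
        else:
            sizes = list(self.n_per_cohort)
            if len(sizes) != self.n_cohorts:
                raise ValueError("n_per_cohort list length must equal n_cohorts")
        if any(s < 4 for s in sizes):
            raise ValueError("cohort sizes must be >= 4")
        return sizes

    @property
    def marker_gene(self) -> str:
        return _gene_name(self.marker_index, self.n_genes)

    @property
    def target_gene(self) -> str:
        return _gene_name(self.target_index, self.n_genes)


@dataclass
class SimTruth:
    """Ground truth aligned with the generated cohorts."""

    config: SimConfig
    marker_high: dict = field(default_factory=dict)  # cohort -> bool array
    hazards: dict = field(default_factory=dict)  # cohort -> per-patient hazard
    batch: dict = field(default_factory=dict)  # cohort -> {"shift","scale","c_max"}


def _gene_name(i: int, n_genes: int) -> str:
    width = max(4, len(str(n_genes)))
    return f"G{i:0{width}d}"


def _tune_censoring_cmax(hazards: np.ndarray, rate: float, tol: float = 1e-10) -> float:
    """c_max such that mean_i (1 - exp(-h_i c)) / (h_i c) == rate."""

    def frac_censored(c: float) -> float:
        x = hazards * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-12, 1.0
    for _ in range(200):
        if frac_censored(hi) <= rate:
            break
        hi *= 2.0
    else:
        raise ValueError(f"could not tune censoring to rate {rate}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_censored(mid) > rate:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def simulate_cohorts(config: SimConfig) -> tuple[list[Cohort], SimTruth]:
    """Generate the multi-cohort collection described by ``config``.

    Fully reproducible from ``config.seed`` (independent substreams per
    cohort).  Returns the cohorts (expression already on the observed,
    batch-perturbed scale) and the ground-truth sidecar.
    """
    sizes = config.cohort_sizes
    genes = [_gene_name(i, config.n_genes) for i in range(config.n_genes)]
    children = np.random.SeedSequence(config.seed).spawn(config.n_cohorts)

    truth = SimTruth(config=config)
    cohorts = []
    for c_idx, (n, ss) in enumerate(zip(sizes, children)):
        rng = np.random.default_rng(ss)
        name = f"SIM{c_idx + 1}"
        latent = rng.standard_normal((config.n_genes, n))
        rho = config.expression_corr
        latent[config.target_index] = rho * latent[config.marker_index] + np.sqrt(
            1.0 - rho * rho
        ) * latent[config.target_index]

        marker = latent[config.marker_index]
        target = latent[config.target_index]
        x_t = (target - target.mean()) / target.std(ddof=0)
        marker_high = marker > marker.mean()
        log_hr = config.beta_main * x_t + config.beta_interaction * x_t * marker_high
        hazards = config.baseline_hazard * np.exp(log_hr)

        t_event = rng.exponential(1.0 / hazards)
        if config.censoring_rate > 0:
            c_max = _tune_censoring_cmax(hazards, config.censoring_rate)
            t_cens = rng.uniform(0.0, c_max, size=n)
            time = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
        else:
            c_max = float("inf")
            time, event = t_event, np.ones(n, dtype=int)

        shift = float(rng.normal(0.0, config.batch_shift_sd))
        scale = float(np.exp(rng.normal(0.0, config.batch_scale_sd)))
        observed = latent * scale + shift

        samples = [f"{name}_S{i + 1:04d}" for i in range(n)]
        cohorts.append(
            Cohort(
                name=name,
                expr=pd.DataFrame(observed, index=genes, columns=samples),
                time=pd.Series(time, index=samples, name="time"),
                event=pd.Series(event, index=samples, name="event"),
            )
        )
        truth.marker_high[name] = marker_high
        truth.hazards[name] = hazards
        truth.batch[name] = {"shift": shift, "scale": scale, "c_max": c_max}
    return cohorts, truth


def write_fixture(cohorts: list[Cohort], truth: SimTruth, directory) -> list[Path]:
    """Write cohorts in the pipeline's input dialects plus a truth sidecar.

    Per cohort: ``<name>_expression.tsv`` (probe x sample, probe ids
    ``P_<gene>``), ``<name>_mapping.tsv`` (probe -> gene) and
    ``<name>_clinical.tsv`` (sample_id, time, event).  The YAML sidecar
    records the config and per-cohort ground truth.  Round-trips losslessly
    through the preprocessing readers.
    """
    if not cohorts:
        raise ValueError("no cohorts to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for c in cohorts:
        expr = c.expr.copy()
        expr.index = ["P_" + g for g in c.expr.index]
        expr.index.name = "probe_id"
        p_expr = directory / f"{c.name}_expression.tsv"
        expr.to_csv(p_expr, sep="\t")

        p_map = directory / f"{c.name}_mapping.tsv"
        pd.DataFrame(
            {"probe": ["P_" + g for g in c.expr.index], "gene": list(c.expr.index)}
        ).to_csv(p_map, sep="\t", header=False, index=False)

        p_clin = directory / f"{c.name}_clinical.tsv"
        pd.DataFrame(
            {"sample_id": c.expr.columns, "time": c.time.values, "event": c.event.values}
        ).to_csv(p_clin, sep="\t", index=False)
        written += [p_expr, p_map, p_clin]

    sidecar = {
        "config": dataclasses.asdict(truth.config),
        "cohorts": {
            name: {
                "marker_high": [bool(b) for b in truth.marker_high[name]],
                "batch": truth.batch[name],
            }
            for name in truth.marker_high
        },
    }
    p_truth = directory / "truth.yaml"
    with open(p_truth, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    written.append(p_truth)
    return written
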