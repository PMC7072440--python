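# Methods

## Problem setting

Given several independent cohorts, each a gene-by-patient expression matrix
joined to right-censored survival (time > 0, event ∈ {0,1}), the package asks:
*for a fixed target gene, which candidate marker gene best stratifies
patients into groups in which the target's prognostic effect differs?* The
motivating application is pancreatic cancer, where PTEN's prognostic
direction depends on PLK1 expression, but nothing in the code is specific to
those genes.

## Statistical machinery

### Signed log-rank

For a low/high split the Mantel–Cox statistic is accumulated over pooled
risk sets at each distinct event time `t_j`: with `n_j` at risk, `d_j`
events, and `n_hj`/`d_hj` the high-group counts,

- `O = Σ d_hj`, `E = Σ d_j·n_hj/n_j`,
- `V = Σ d_j·(n_hj/n_j)(1−n_hj/n_j)(n_j−d_j)/(n_j−1)` (terms with
  `n_j = 1` contribute zero),
- `z = (E − O)/√V`, `χ² = z²`, two-sided p from the χ²(1) upper tail.

Ties are handled by the pooled hypergeometric formula; no Efron correction.
The sign convention — `z < 0` when high expression is adverse — is fixed so
that the adverse, significant combined score of the bundled PLK1-high
stratum is negative. The statistic is rank-based in time, so any strictly
monotone transform of survival times leaves it unchanged (property-tested).
Degenerate inputs raise: zero events overall, or zero variance (all events
confined so that every risk-set term vanishes).

### IPP score

The exact partition functional of the originally described iterative
partitioning score is not published; this package defines the IPP score of a
gene as the **arithmetic mean of the signed log-rank z over all rank
cut-points** `k ∈ [k_min, n − k_min]`, `k_min = max(5, ⌈f·n⌉)` with cut
fraction `f = 0.2` by default. Rationale: it uses every admissible
partition (the stated point of iterating partitions), it stays on the z
scale so √n-weighted Liptak combination of per-cohort scores is
dimensionally coherent, and it reduces exactly to the classical
median-split z when the cut range collapses to the single median partition
(`f = 0.5`, even n — tested). Cuts whose variance degenerates are skipped;
if no cut is valid the score errors rather than returning a default.
Expression ties at a cut rank are broken by stable patient order, making the
score deterministic. Because group membership for consecutive cuts differs
by one patient, all cuts are evaluated in one vectorized pass (suffix
cumulative sums of the patient×event-time at-risk/event indicators), so a
screen over thousands of marker×cohort×stratum combinations runs in
seconds.

Alternative partition summaries (maximum |z|, median) would emphasize the
single best cut rather than the partition-averaged evidence; the mean was
chosen and is documented as this package's definition.

### Marker-conditional records, trimming, combination

For a candidate marker, each cohort's patients are split at the marker's
**mean** expression (the convention used for the motivating marker; median
available via config). The target's IPP score is computed inside each
stratum; a stratum under `min_stratum_size` (default 10, the smallest n the
default cut range admits) or failing the IPP preconditions yields a record
flagged invalid — excluded downstream but never silently dropped.

Per stratum, across cohorts:

1. **Trimmed aggregate** — the mean IPP score after removing exactly one
   maximum and one minimum record (ties broken by dataset-name order,
   deterministically). Requires ≥ 3 records.
2. **Liptak combination** of the retained records:
   `Z = Σ wᵢzᵢ/√(Σ wᵢ²)`, `wᵢ = √nᵢ` (stratum size), one-sided
   `p = Φ(Z)`. The lower tail is forced by the bundled worked example's
   arithmetic (Φ(−1.68977768) = 0.045535248) and by the sign convention:
   small p = high expression adverse. IPP scores are treated as z-scale
   quantities; no re-standardization is applied.

Trimming is applied per stratum, and the combination uses the post-trim
records, mirroring the bundled nine-row table where the overall maximum
(2.09) and minimum (−2.15) datasets were removed before combining.

The screen ranks markers by ascending high-stratum combined p, with the
absolute high-vs-low aggregate contrast as tiebreak. No published ranking
rule exists for this table; the raw per-stratum aggregates, combined z/p and
per-cohort records are always emitted so any alternative ranking can be
recomputed from the output files.

### Weights

`weight_from_n(n) = √n` exactly. The bundled table's 4-decimal sqrt cells
are truncated displays (√19 = 4.35890 prints as 4.3588); all arithmetic uses
the exact value recomputed from the integer group size.

## Preprocessing

- **Probe collapsing**: gene value = arithmetic mean over all probes mapped
  to it; multi-mapped probes contribute to every mapped gene (maximizes gene
  coverage; logged); unmapped probes are dropped.
- **Quantile normalization**: reference = per-rank mean of column-sorted
  values; ties within a column receive the mean of the reference values over
  their tie block. Idempotent, and every column ends with the same sorted
  multiset. Default scope is **pooled** across all cohorts loaded together
  (batch effects are a cross-cohort phenomenon; a per-cohort affine batch
  shift survives per-dataset normalization, which is why the pooled mode is
  the default), with `per_dataset` and `none` switches in the pipeline
  config.
- Expression values are assumed already log-scale; no transform is applied.
  Missing values are rejected at load, not imputed.
- Cohort assembly keeps the intersection of expression and clinical samples
  in sorted sample-id order; mismatches are logged and dropped; non-binary
  event codes error.

## Synthetic data generator

`SimConfig` defaults describe the screen's reference study: 5 cohorts × 200
patients, 50 genes, marker gene index 0 and target index 1,
`beta_interaction = 0.8`, `beta_main = 0`, baseline hazard 0.05/month
(median survival ≈ 14 months, pancreatic-cancer-like), 30% administrative
censoring, marker–target correlation 0 (so decoy genes and the marker-target
pair are exchangeable under the null).

Expression is Gaussian on the log scale; each cohort applies one affine
batch map `value = latent·scale + shift` (`scale = exp N(0, 0.1)`,
`shift ~ N(0, 0.5)`) — monotone, hence removable by pooled quantile
normalization and invisible to rank-based statistics. Survival is
exponential with hazard
`h = h₀·exp(β_main·x_t + β_int·x_t·1[marker > mean])`, `x_t` the
standardized target expression; the interaction enters through the marker's
mean-split indicator so planted effects align exactly with what the screen's
split rule can detect. Censoring times are uniform on `(0, c_max)` with
`c_max` solved by bisection so the expected censored fraction equals
`censoring_rate`. Everything is reproducible from the seed via per-cohort
substreams.

What the generator does **not** emulate: platform-specific noise,
non-proportional hazards, informative censoring, correlated decoy blocks,
or realistic GEO value distributions. Passing tests therefore demonstrate
the pipeline's statistical behavior under its own model assumptions, not
performance on real accessions.

## Numerical and design notes

- Variance tolerance 1e-12 distinguishes degenerate partitions.
- Threshold ties go to the low group (median/mean rules); deterministic.
- The exponential baseline is immaterial to the rank-based tests; the
  generator's `beta_main` knob produces stratum-independent effects for
  calibration runs.
- The expression contrast between target-low/high groups uses **Welch's**
  t-test (unequal variances) as the safer default form.
- Test problem sizes (e.g. 2,000 null replicates at n = 100; 50 screen seeds
  at the 5×200×50 reference condition) were chosen to give the stochastic
  checks comfortable power while keeping the default suite around half a
  minute.

## Known limitations

- The per-dataset IPP magnitudes of the bundled table cannot be reproduced
  without the original cohorts and the original partition functional; the
  package reproduces the combination arithmetic downstream of those scores
  exactly and validates the score itself by its properties (null mean zero,
  monotone invariance, median-split reduction, planted-effect recovery).
- Clinical-covariate subsetting (e.g. stage/grade filters) is a generic
  row-filter concern upstream of `assemble_cohort`; no disease-specific
  field encodings are built in.
- No Cox regression, hazard ratios or multivariate adjustment — the screen
  is deliberately nonparametric and univariate per stratum.
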