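# ippscreen

Companion-biomarker screening for multi-cohort gene-expression survival data.

A gene's prognostic effect can point in opposite directions in different
patient subsets: in pancreatic cancer, elevated *PTEN* predicts worse outcome
in some public cohorts and better outcome in others, and the discrepancy
resolves once patients are stratified by *PLK1* expression. `ippscreen` is a
tested re-implementation of the screening computation behind that kind of
finding, for biostatisticians and computational biologists who want to hunt
for companion markers of a target gene across many expression+survival
cohorts without ad-hoc spreadsheets.

## What it computes

**Signed log-rank z.** For a low/high patient split, the Mantel–Cox statistic
is reported as `z = (E_high − O_high)/√V`, so `z < 0` means high expression is
adverse, and `z²` is the usual chi-square.

**IPP score.** The conventional prognostic log-rank fixes one partition (the
median split) and is sensitive to where that cut falls. The iterative patient
partitioning (IPP) score instead ranks patients by the target gene's
expression and averages the signed log-rank z over *every* admissible cut
rank `k ∈ [k_min, n − k_min]`, with `k_min = max(5, ⌈0.2·n⌉)`. It stays on
the z scale and collapses to the classical median-split z when the cut range
contains a single partition.

**Marker-conditional screen.** For each candidate marker gene, patients in
each cohort are split at the marker's mean expression; the target's IPP score
is computed inside each stratum. Per stratum, the per-cohort scores are
aggregated after removing the single largest and smallest (trimmed mean) and
the retained scores are combined with Liptak's weighted z-score method,

    Z = Σᵢ wᵢ zᵢ / √(Σᵢ wᵢ²),    wᵢ = √nᵢ,

with the one-sided p = Φ(Z) (lower tail = adverse). Markers are ranked by the
high-stratum combined p.

A synthetic-cohort generator (`ippscreen.simulate`) produces multi-cohort
fixtures with log-scale expression, right-censored exponential survival, a
per-cohort batch effect, and a planted marker×target interaction, so the full
pipeline is testable without any downloads.

## Worked example

The package bundles a published nine-cohort summary of PTEN IPP scores within
PLK1 strata (`ippscreen.datasets`). Combining it:

```bash
python -c "from ippscreen.datasets import PLK1_PTEN_SCREEN_TSV as t; open('scores.tsv','w').write(t)"
ippscreen combine scores.tsv
```

prints the per-cohort rows and then

```
Liptak's z-value        -0.392674332    -1.68977768
Liptak's p-value        0.347280015     0.0455352477
```

i.e. elevated PTEN carries no significant prognostic effect among PLK1-low
patients (p = 0.347) but is significantly adverse among PLK1-high patients
(one-sided p = 0.0455) — PLK1 behaves as a companion marker for PTEN's
prognostic value. The weights are the exact √N of each stratum
(√49 = 7, √85 = 9.2195…), recomputed from the group sizes in parentheses.

The same machinery end-to-end on synthetic data:

```bash
ippscreen simulate -o fix --seed 7          # 5 cohorts x 200 patients, 50 genes,
                                            # planted marker G0000, target G0001
ippscreen screen --config screen.yaml       # cohorts + target + candidate list
```

```
 rank marker_gene  high_z_combined  high_p_one_sided
    1       G0000        -6.842103      3.901937e-12
    2       G0029        -5.119434      1.532270e-07
    ...
```

The planted companion marker G0000 ranks first: the target is strongly
adverse in G0000-high patients and null in G0000-low patients, which the
two-stage stratified report confirms on one cohort:

```bash
ippscreen prognosis --expression fix/SIM1_expression.tsv \
    --mapping fix/SIM1_mapping.tsv --clinical fix/SIM1_clinical.tsv \
    --marker G0000 --target G0001
```

```
     stratum         z  chi_square  p_two_sided
  marker_low -0.625509    0.391262     0.531637
 marker_high -4.473626   20.013328     0.000008
```

## Layout

- `ippscreen.preprocessing` — probe→gene collapsing (mean), quantile
  normalization (pooled or per-cohort), cohort assembly from TSV inputs
- `ippscreen.survival` — KM curves, signed log-rank, dichotomization rules
- `ippscreen.ipp` — IPP score, marker-conditional records, trimmed
  aggregation, the marker screen
- `ippscreen.meta` — Liptak combination, √n weights, score-table I/O
- `ippscreen.prognosis` — single-gene and two-stage stratified reports,
  expression contrasts (Welch t)
- `ippscreen.simulate` — synthetic multi-cohort generator + fixture writer
- `ippscreen.cli` — `simulate`, `preprocess`, `screen`, `prognosis`,
  `combine` subcommands

See `docs/methods.md` for the statistical model, parameter defaults and known
limitations.
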