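"""Bundled example data.

The worked example shipped with the package is a published nine-cohort
summary of PTEN IPP scores within PLK1-defined patient strata in pancreatic
cancer: for each public dataset, patients were split at the cohort-mean PLK1
expression, the PTEN IPP score was computed in each stratum, and the
per-stratum scores were combined across cohorts with sqrt(N) Liptak weights.
Two further cohorts (E-MTAB-6134, maximum score 2.09; GSE79668, minimum
score -2.15) were removed by the max/min trimming rule before combination.
"""

from __future__ import annotations

import pandas as pd

from .meta import read_stratum_table

__all__ = ["PLK1_PTEN_SCREEN_TSV", "load_plk1_pten_screen"]

# columns: dataset, sqrt(N) PLK1-low stratum, sqrt(N) PLK1-high stratum,
# PTEN IPP score in PLK1-low stratum, PTEN IPP score in PLK1-high stratum
PLK1_PTEN_SCREEN_TSV = """\
E-MEXP-2780\t4.3588 (19)\t3.3166 (11)\t-1.02099\t-1.1888
GSE17891\t3.6055 (13)\t3.7416 (14)\t-0.024019\t-1.8071
GSE62452\t7 (49)\t4.1231 (17)\t0.502234\t0.594234
GSE21501\t7.6157 (58)\t6.6332 (44)\t0.533184\t-0.247134
GSE57495\t5.6568 (32)\t5.5677 (31)\t-0.790192\t-0.710717
GSE71729\t8.3066 (69)\t7.4833 (56)\t-0.899932\t-0.188088
GSE84219\t4.1231 (17)\t3.6055 (13)\t1.29252\t0.809448
PAAD-US\t9.2195 (85)\t7.2801 (53)\t-1.09615\t-1.23564
PACA-AU\t6.9282 (48)\t5.5677 (31)\t0.85567\t-1.15497
"""


def load_plk1_pten_screen() -> pd.DataFrame:
    """The nine-cohort PLK1-stratified PTEN score table as a DataFrame."""
    return read_stratum_table(PLK1_PTEN_SCREEN_TSV)
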