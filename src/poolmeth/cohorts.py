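"""Bundled summary statistics for seven published 1240K-capture cohorts.

One row per ancient population: cohort size, mean autosomal SNP hits and
the effective coverage of the pooled cohort (mean coverage over CpGs
covered at least once). This small table is the worked example for the
effective-coverage planning regression and ships with the package so the
model can be refit without any download.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cohort_summary_table"]

_ROWS = [
    # population, num_samples, avg_snp_hits, effective_coverage
    ("Caribbean_CER", 142, 680_901, 35.69),
    ("Mongolia_BA_IA", 63, 788_240, 24.16),
    ("Eu_BellBeakers", 54, 671_619, 14.29),
    ("British_N", 47, 632_179, 12.79),
    ("British_BA", 51, 605_833, 12.00),
    ("Cuba_ARC_CER", 35, 656_432, 9.44),
    ("Baqah_BA", 21, 685_503, 6.99),
]


def cohort_summary_table() -> pd.DataFrame:
    """The seven-cohort summary table as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["population", "num_samples", "avg_snp_hits",
                 "effective_coverage"],
    )
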