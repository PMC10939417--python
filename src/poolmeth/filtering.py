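"""Sample- and site-level filters applied before reconstruction.

Three screens are supported:

* cohort screening — drop samples with too few autosomal SNP hits;
* PCR-duplicate control — per chromosome per sample, cap coverage at the
  first value whose smoothed coverage-histogram count drops to <= 1;
* mutation removal — drop pooled sites whose C->T ratio exceeds a cutoff
  (such sites reflect C>T SNPs, not deamination).

The coverage histogram starts at coverage 1; sites with no reads carry no
duplicates to remove. Smoothing is a centred moving average with edge
truncation. All filters are idempotent.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CpGCountTable, SampleRecord
from .errors import ValidationError

__all__ = [
    "filter_samples_by_snp_hits",
    "coverage_histogram",
    "smooth_histogram",
    "coverage_threshold",
    "apply_coverage_cap",
    "cap_sample_coverage",
    "mutation_filter",
]

DEFAULT_MIN_SNP_HITS = 30_000
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_MAX_CT_RATIO = 0.25


def filter_samples_by_snp_hits(
    manifest: Sequence[SampleRecord], min_hits: int = DEFAULT_MIN_SNP_HITS
) -> list[SampleRecord]:
    """Keep samples with ``autosomal_snp_hits >= min_hits``."""
    if min_hits < 0:
        raise ValidationError("min_hits must be >= 0")
    return [r for r in manifest if r.autosomal_snp_hits >= min_hits]


def coverage_histogram(table: CpGCountTable, chrom: str | None = None) -> np.ndarray:
    """Histogram of per-site coverage for one sample.

    Returns ``counts`` where ``counts[k-1]`` is the number of CpG positions
    with coverage exactly ``k`` (k = 1..max coverage). Zero-coverage sites,
    if present in the table, are ignored.
    """
    df = table.df if chrom is None else table.df[table.df["chrom"] == chrom]
    n = (df["c"] + df["t"]).to_numpy()
    n = n[n >= 1]
    if n.size == 0:
        raise ValidationError("empty coverage histogram")
    return np.bincount(n, minlength=n.max() + 1)[1:]


def smooth_histogram(counts: np.ndarray, window_len: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centred moving average of length ``window_len``, truncated at edges."""
    if window_len < 1 or window_len % 2 == 0:
        raise ValidationError("window_len must be a positive odd integer")
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValidationError("empty coverage histogram")
    half = window_len // 2
    cum = np.concatenate([[0.0], np.cumsum(counts)])
    k = np.arange(counts.size)
    lo = np.clip(k - half, 0, None)
    hi = np.clip(k + half + 1, None, counts.size)
    return (cum[hi] - cum[lo]) / (hi - lo)


def coverage_threshold(
    counts: np.ndarray, window_len: int = DEFAULT_SMOOTH_WINDOW
) -> int:
    """First coverage whose smoothed histogram count is <= 1.

    ``counts[k-1]`` holds the number of sites at coverage ``k``. If no
    smoothed count drops to one or less, returns ``K + 1`` (no cap).
    """
    counts = np.asarray(counts)
    smoothed = smooth_histogram(counts, window_len)
    below = np.nonzero(smoothed <= 1.0)[0]
    if below.size == 0:
        return counts.size + 1
    return int(below[0]) + 1


def apply_coverage_cap(table: CpGCountTable, threshold: int) -> CpGCountTable:
    """Remove sites with coverage >= ``threshold``."""
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    n = table.df["c"] + table.df["t"]
    return CpGCountTable(table.df[n < threshold])


def cap_sample_coverage(
    table: CpGCountTable, window_len: int = DEFAULT_SMOOTH_WINDOW
) -> tuple[CpGCountTable, dict[str, int]]:
    """Per-chromosome duplicate control for one sample.

    Computes the coverage threshold separately for each chromosome and caps
    that chromosome at it. Returns the filtered table and the thresholds.
    """
    thresholds: dict[str, int] = {}
    kept = []
    for chrom, sub in table.df.groupby("chrom", sort=False):
        n = (sub["c"] + sub["t"]).to_numpy()
        covered = n[n >= 1]
        if covered.size == 0:
            kept.append(sub)
            continue
        counts = np.bincount(covered, minlength=covered.max() + 1)[1:]
        thr = coverage_threshold(counts, window_len)
        thresholds[str(chrom)] = thr
        kept.append(sub[n < thr])
    df = pd.concat(kept) if kept else table.df.iloc[:0]
    return CpGCountTable(df), thresholds


def mutation_filter(
    table: CpGCountTable, max_ratio: float = DEFAULT_MAX_CT_RATIO
) -> CpGCountTable:
    """Remove sites whose C->T ratio strictly exceeds ``max_ratio``.

    Sites with zero coverage carry no ratio and pass through untouched.
    """
    if not 0 < max_ratio <= 1:
        raise ValidationError("max_ratio must be in (0, 1]")
    c = table.df["c"].to_numpy()
    t = table.df["t"].to_numpy()
    n = c + t
    with np.errstate(invalid="ignore"):
        ratio = np.where(n > 0, t / np.maximum(n, 1), 0.0)
    return CpGCountTable(table.df[ratio <= max_ratio])
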