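"""From pooled counts to a methylation map.

The reconstruction exploits the strong local correlation of methylation:
the C->T evidence for a CpG is aggregated over a window of ``W`` consecutive
CpG positions centred on it. ``W`` is set adaptively from the cohort's
effective coverage ``C`` (mean coverage of CpGs covered at least once) by
requiring that a window over a region methylated at some minimum level
``m0`` has probability below ``p0`` of showing zero thymines:

    W = ceil( (1/C) * ln(p0) / ln(1 - pi * m0) ),

capped at ``W_max`` (31 by default). Window C->T ratios are then calibrated
to methylation levels by histogram matching against a reference methylome
(WGBS of modern bone): a monotone transform maps each signal-histogram bin
value to the reference bin value whose cumulative histogram is closest.

The module also carries the cohort-planning regression (effective coverage
predicted from cohort size and mean autosomal SNP hits) and the QC
summaries used to judge whether a pooled cohort supports reconstruction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (CpGCountTable, GenomicIntervalSet, MethylationMap,
                      ReferenceMethylome)
from .errors import ValidationError
from .pooling import estimate_deamination_rate

__all__ = [
    "effective_coverage",
    "window_size",
    "sliding_window_ratio",
    "HistogramTransform",
    "fit_histogram_transform",
    "ReconstructionResult",
    "reconstruct_map",
    "EffectiveCoverageModel",
    "fit_effective_coverage_model",
    "predict_effective_coverage",
    "binned_ct_qc",
    "interval_mean_methylation",
    "coverage_vs_target_distance",
    "block_correlation",
]

DEFAULT_P0 = 0.01
DEFAULT_M0 = 0.2
DEFAULT_W_MAX = 31
RECONSTRUCTABLE_COVERAGE = 12.0


def effective_coverage(pooled_table: CpGCountTable) -> float:
    """Mean coverage over CpG positions covered at least once."""
    n = (pooled_table.df["c"] + pooled_table.df["t"]).to_numpy()
    n = n[n >= 1]
    if n.size == 0:
        raise ValidationError("no covered CpG positions")
    return float(n.mean())


def window_size(
    C: float,
    p0: float = DEFAULT_P0,
    m0: float = DEFAULT_M0,
    pi: float = 0.02,
    W_max: int = DEFAULT_W_MAX,
) -> int:
    """Adaptive window size from effective coverage and deamination rate."""
    if not 0 < p0 < 1:
        raise ValidationError("p0 must be in (0, 1)")
    if not 0 < m0 <= 1:
        raise ValidationError("m0 must be in (0, 1]")
    if not 0 < pi < 1 or pi * m0 >= 1:
        raise ValidationError("pi must be in (0, 1) with pi * m0 < 1")
    if C <= 0:
        raise ValidationError("effective coverage must be positive")
    raw = math.ceil(math.log(p0) / math.log(1.0 - pi * m0) / C)
    return int(min(W_max, max(1, raw)))


def _window_sums(values: np.ndarray, W: int) -> np.ndarray:
    """Centred sums over ``W`` consecutive rows, truncated at the edges.

    For even ``W`` the window takes ``ceil((W-1)/2)`` rows before and
    ``floor((W-1)/2)`` rows after the centre. Works on 1-D or 2-D input
    (windows run down axis 0).
    """
    left = math.ceil((W - 1) / 2)
    right = (W - 1) // 2
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    cum = np.vstack([np.zeros((1, arr.shape[1])), np.cumsum(arr, axis=0)])
    k = np.arange(arr.shape[0])
    lo = np.clip(k - left, 0, None)
    hi = np.clip(k + right + 1, None, arr.shape[0])
    out = cum[hi] - cum[lo]
    return out[:, 0] if squeeze else out


def sliding_window_ratio(pooled_table: CpGCountTable, W: int) -> pd.DataFrame:
    """Window-aggregated counts and C->T ratio per CpG.

    Sums ``t`` and ``n`` over the ``W`` consecutive table rows centred on
    each site (truncated at chromosome ends). The ratio is NaN where the
    window carries no reads.
    """
    if W < 1:
        raise ValidationError("window size must be >= 1")
    df = pooled_table.df
    sum_t = np.empty(len(df))
    sum_n = np.empty(len(df))
    n = (df["c"] + df["t"]).to_numpy(dtype=float)
    t = df["t"].to_numpy(dtype=float)
    start = 0
    for _, sub in df.groupby("chrom", sort=False):
        sl = slice(start, start + len(sub))
        sum_t[sl] = _window_sums(t[sl], W)
        sum_n[sl] = _window_sums(n[sl], W)
        start += len(sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(sum_n > 0, sum_t / np.where(sum_n > 0, sum_n, 1), np.nan)
    return pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"],
        "sum_t": sum_t, "sum_n": sum_n, "ratio": ratio,
    })


@dataclass(frozen=True)
class HistogramTransform:
    """Monotone histogram-matching transform from signal to reference scale.

    Built from cumulative histograms normalised to [0, 1]: each signal bin
    value ``b_j`` maps to the reference bin value ``B_{i0}`` whose cumulative
    count is closest to the signal's (``i0 = argmin_i |H_i - h_j|``, ties
    broken toward the smallest index). Cumulative counts are evaluated at
    the middle of each bin's own mass (continuity correction), so a clump
    of tied values — e.g. windows with zero thymines at low coverage — maps
    to the centre of its quantile range instead of its upper end, which
    would otherwise bias the matched distribution.
    """

    signal_edges: np.ndarray
    signal_bin_values: np.ndarray
    ref_bin_values: np.ndarray
    mapped_values: np.ndarray  # transform output per signal bin

    def __call__(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        out = np.full(values.shape, np.nan)
        ok = np.isfinite(values)
        idx = np.digitize(values[ok], self.signal_edges) - 1
        idx = np.clip(idx, 0, len(self.mapped_values) - 1)
        out[ok] = self.mapped_values[idx]
        return out


def fit_histogram_transform(
    signal_values: np.ndarray,
    reference_values: np.ndarray,
    n_ref_bins: int = 101,
    signal_resolution: float = 0.001,
) -> HistogramTransform:
    """Fit the histogram-matching transform.

    The reference is binned into ``n_ref_bins`` equal-width bins over [0, 1];
    the signal is binned at ``signal_resolution`` over its observed range.
    """
    signal = np.asarray(signal_values, dtype=float)
    signal = signal[np.isfinite(signal)]
    reference = np.asarray(reference_values, dtype=float)
    reference = reference[np.isfinite(reference)]
    if signal.size == 0 or reference.size == 0:
        raise ValidationError("histogram matching needs non-empty inputs")

    ref_edges = np.linspace(0.0, 1.0, n_ref_bins + 1)
    ref_values = 0.5 * (ref_edges[:-1] + ref_edges[1:])
    ref_mass = np.histogram(reference, bins=ref_edges)[0] / reference.size
    H = np.cumsum(ref_mass) - 0.5 * ref_mass  # continuity-corrected CDF

    lo, hi = signal.min(), signal.max()
    if hi - lo < signal_resolution:
        warnings.warn("degenerate single-valued signal: constant transform",
                      stacklevel=2)
        sig_edges = np.array([lo - signal_resolution, hi + signal_resolution])
    else:
        n_bins = int(np.ceil((hi - lo) / signal_resolution))
        sig_edges = np.linspace(lo, hi, n_bins + 1)
        sig_edges[-1] = np.nextafter(sig_edges[-1], np.inf)
    sig_values = 0.5 * (sig_edges[:-1] + sig_edges[1:])
    sig_mass = np.histogram(signal, bins=sig_edges)[0] / signal.size
    h = np.cumsum(sig_mass) - 0.5 * sig_mass

    # argmin_i |H_i - h_j| with ties toward the smallest index
    i0 = np.argmin(np.abs(H[None, :] - h[:, None]), axis=1)
    mapped = ref_values[i0]
    return HistogramTransform(
        signal_edges=sig_edges, signal_bin_values=sig_values,
        ref_bin_values=ref_values, mapped_values=mapped,
    )


@dataclass(frozen=True)
class ReconstructionResult:
    """A reconstructed map plus the parameters the run resolved to."""

    map: MethylationMap
    effective_coverage: float
    deamination_rate: float
    window: int


def reconstruct_map(
    pooled_table: CpGCountTable,
    reference: ReferenceMethylome,
    p0: float = DEFAULT_P0,
    m0: float = DEFAULT_M0,
    W_max: int = DEFAULT_W_MAX,
    W: int | None = None,
    pi: float | None = None,
    anchor_methylation: float = 1.0,
) -> ReconstructionResult:
    """Reconstruct a methylation map from a filtered pooled count table.

    Resolves the deamination rate (from reference anchors, unless given),
    the effective coverage and the window size; aggregates C->T evidence in
    sliding windows; and histogram-matches the window ratios to the
    reference methylome's value distribution.
    """
    C = effective_coverage(pooled_table)
    if C < RECONSTRUCTABLE_COVERAGE:
        warnings.warn(
            f"effective coverage {C:.2f} is below the reconstruction "
            f"threshold {RECONSTRUCTABLE_COVERAGE:g}; the map may be biased",
            stacklevel=2,
        )
    if pi is None:
        pi = estimate_deamination_rate(pooled_table, reference,
                                       anchor_methylation).pi
    if W is None:
        W = window_size(C, p0=p0, m0=m0, pi=pi, W_max=W_max)
    windows = sliding_window_ratio(pooled_table, W)
    ratios = windows["ratio"].to_numpy()
    transform = fit_histogram_transform(ratios, reference.df["m"].to_numpy())
    m_hat = transform(ratios)
    map_ = MethylationMap(pd.DataFrame({
        "chrom": windows["chrom"], "pos": windows["pos"],
        "m_hat": m_hat, "n_window": windows["sum_n"],
    }))
    return ReconstructionResult(map_, C, float(pi), int(W))


@dataclass(frozen=True)
class EffectiveCoverageModel:
    """Linear model predicting cohort effective coverage before download.

    ``E.C = a * num_samples + b * (avg_snp_hits / 1e5) + intercept``.
    """

    coef_num_samples: float
    coef_snp_hits: float  # per 1e5 autosomal SNP hits
    intercept: float
    mse: float  # SSE / n
    r2: float

    def predict(self, num_samples: float, avg_snp_hits: float) -> float:
        return (self.coef_num_samples * num_samples
                + self.coef_snp_hits * avg_snp_hits / 1e5 + self.intercept)

    def is_reconstructable(self, num_samples: float, avg_snp_hits: float,
                           threshold: float = RECONSTRUCTABLE_COVERAGE) -> bool:
        return self.predict(num_samples, avg_snp_hits) >= threshold


def fit_effective_coverage_model(cohort_table: pd.DataFrame) -> EffectiveCoverageModel:
    """OLS of effective coverage on cohort size and mean SNP hits.

    ``cohort_table`` needs columns ``num_samples``, ``avg_snp_hits`` (raw
    hit counts) and ``effective_coverage``; at least 3 rows.
    """
    req = {"num_samples", "avg_snp_hits", "effective_coverage"}
    if not req <= set(cohort_table.columns):
        raise ValidationError(f"cohort table needs columns {sorted(req)}")
    if len(cohort_table) < 3:
        raise ValidationError("need at least 3 cohorts to fit")
    x1 = cohort_table["num_samples"].to_numpy(dtype=float)
    x2 = cohort_table["avg_snp_hits"].to_numpy(dtype=float) / 1e5
    y = cohort_table["effective_coverage"].to_numpy(dtype=float)
    X = np.column_stack([x1, x2, np.ones_like(x1)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValidationError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    return EffectiveCoverageModel(
        coef_num_samples=float(beta[0]), coef_snp_hits=float(beta[1]),
        intercept=float(beta[2]), mse=sse / len(y),
        r2=1.0 - sse / sst if sst > 0 else float("nan"),
    )


def predict_effective_coverage(
    model: EffectiveCoverageModel, num_samples: float, avg_snp_hits: float
) -> tuple[float, bool]:
    """Predicted effective coverage and whether it clears the threshold."""
    ec = model.predict(num_samples, avg_snp_hits)
    return ec, ec >= RECONSTRUCTABLE_COVERAGE


def binned_ct_qc(
    pooled_table: CpGCountTable,
    reference: ReferenceMethylome,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Mean C->T ratio per reference-methylation bin, plus Pearson r.

    CpGs are binned by reference methylation into ``n_bins`` equal-width
    bins ([0, 0.1), ..., [0.9, 1]); the correlation is computed between bin
    midpoints and bin means over occupied bins. A monotone increasing
    profile and high r indicate the pooled ratio tracks methylation.
    """
    merged = pooled_table.df.merge(reference.df, on=["chrom", "pos"])
    n = (merged["c"] + merged["t"]).to_numpy()
    merged = merged[n > 0]
    if len(merged) < n_bins:
        raise ValidationError("too few overlapping covered CpGs for QC bins")
    ratio = merged["t"] / (merged["c"] + merged["t"])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(merged["m"].to_numpy(), edges) - 1, 0, n_bins - 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for b in range(n_bins):
        sel = idx == b
        rows.append({
            "bin_mid": mids[b],
            "mean_ratio": float(ratio[sel].mean()) if sel.any() else np.nan,
            "n_sites": int(sel.sum()),
        })
    table = pd.DataFrame(rows)
    occupied = table["mean_ratio"].notna()
    if occupied.sum() < 2 or table.loc[occupied, "mean_ratio"].nunique() == 1:
        r = float("nan")  # correlation undefined (single or constant bins)
    else:
        r = float(stats.pearsonr(table.loc[occupied, "bin_mid"],
                                 table.loc[occupied, "mean_ratio"])[0])
    return table, r


def interval_mean_methylation(
    map_: MethylationMap, intervals: GenomicIntervalSet
) -> tuple[float, float]:
    """Mean methylation inside the interval set and genome-wide.

    Returns ``(interval_mean, genome_mean)``; the interval mean is NaN when
    no reconstructed CpG falls inside any interval.
    """
    present = map_.present
    genome_mean = float(present["m_hat"].mean()) if len(present) else float("nan")
    inside = intervals.mask(present["chrom"], present["pos"])
    if not inside.any():
        return float("nan"), genome_mean
    return float(present["m_hat"].to_numpy()[inside].mean()), genome_mean


def coverage_vs_target_distance(
    tables: CpGCountTable | list[CpGCountTable],
    targets: GenomicIntervalSet,
    max_dist: int = 300,
) -> pd.DataFrame:
    """Mean pooled coverage per distance-to-nearest-target-SNP.

    Capture probes tile ~100 bp around each target, so coverage should fall
    sharply with distance and flatten at the off-target plateau.
    """
    if len(targets) == 0:
        raise ValidationError("empty target set")
    from .pooling import naive_pool

    table = naive_pool(tables) if isinstance(tables, list) else tables
    df = table.df
    dist = np.full(len(df), np.iinfo(np.int64).max, dtype=np.int64)
    for chrom, sub in df.groupby("chrom", sort=False):
        tpos = targets.df.loc[targets.df["chrom"] == chrom, "start"].to_numpy()
        if tpos.size == 0:
            continue
        tpos = np.sort(tpos)
        pos = sub["pos"].to_numpy()
        right = np.searchsorted(tpos, pos)
        d_right = np.where(right < tpos.size, tpos[np.clip(right, 0, tpos.size - 1)] - pos,
                           np.iinfo(np.int64).max)
        d_left = np.where(right > 0, pos - tpos[np.clip(right - 1, 0, None)],
                          np.iinfo(np.int64).max)
        dist[sub.index] = np.minimum(np.abs(d_left), np.abs(d_right))
    n = (df["c"] + df["t"]).to_numpy()
    keep = dist <= max_dist
    out = pd.DataFrame({"distance": dist[keep], "coverage": n[keep]})
    curve = out.groupby("distance", as_index=False)["coverage"].mean()
    curve.columns = ["distance", "mean_coverage"]
    return curve


def block_correlation(
    map_a: MethylationMap, map_b: MethylationMap, block_size: int = 5000
) -> float:
    """Pearson correlation of block-averaged methylation.

    Fixed-size genomic blocks (default 5 kb) are averaged within each map
    and correlated over blocks where both maps have data. This is a simple
    fixed-grid similarity score between two maps.
    """
    merged = map_a.present.merge(map_b.present, on=["chrom", "pos"],
                                 suffixes=("_a", "_b"))
    if len(merged) == 0:
        raise ValidationError("maps share no reconstructed CpGs")
    merged["block"] = merged["pos"] // block_size
    grouped = merged.groupby(["chrom", "block"])[["m_hat_a", "m_hat_b"]].mean()
    if len(grouped) < 2:
        raise ValidationError("fewer than 2 shared blocks")
    return float(stats.pearsonr(grouped["m_hat_a"], grouped["m_hat_b"])[0])
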