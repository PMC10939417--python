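"""Differentially methylated regions between two reconstructed maps.

A DMR is a maximal run of at least ``min_cpgs`` consecutive CpGs shared by
both maps in which the signed methylation difference keeps a constant sign
and its magnitude is at least ``delta_min`` at every site. False discovery
is controlled by label permutation: sample labels are shuffled between the
two cohorts (group sizes preserved), both pseudo-cohorts are re-pooled and
re-reconstructed, and the FDR of a parameter cell is the mean permuted DMR
count divided by the observed count. Cells with FDR < 0.05 are accepted.

Each detected region carries the six descriptive features used to separate
credible DMRs from cohort artefacts: length in bases, CpG count, mean
methylation difference, an optional externally supplied peak score
(``max_qt``), mean coverage, and genomic context (CpG island / promoter /
gene body / intergenic).
"""

from __future__ import annotations

import operator
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CpGCountTable, GenomicIntervalSet, MethylationMap, ReferenceMethylome
from .errors import ValidationError
from .filtering import mutation_filter
from .pooling import naive_pool
from .reconstruction import reconstruct_map

__all__ = [
    "DMR",
    "detect_dmrs",
    "dmr_features",
    "filter_dmrs",
    "dmr_precision_recall",
    "permutation_fdr",
    "DEFAULT_DELTA_GRID",
    "DEFAULT_MIN_CPGS_GRID",
]

DEFAULT_DELTA_GRID = (0.3, 0.4, 0.5)
DEFAULT_MIN_CPGS_GRID = (30, 40, 50)
FDR_ACCEPT = 0.05


@dataclass(frozen=True)
class DMR:
    """One differentially methylated region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_cpg: int
    delta: float  # mean signed difference, group A - group B
    mean_coverage: float
    genomic_context: frozenset[str] | None = None
    max_qt: float | None = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def detect_dmrs(
    map_a: MethylationMap,
    map_b: MethylationMap,
    delta_min: float,
    min_cpgs: int,
) -> list[DMR]:
    """Scan for maximal constant-sign runs exceeding both thresholds."""
    if not 0 < delta_min <= 1:
        raise ValidationError("delta_min must be in (0, 1]")
    if min_cpgs < 1:
        raise ValidationError("min_cpgs must be >= 1")
    merged = map_a.present.merge(map_b.present, on=["chrom", "pos"],
                                 suffixes=("_a", "_b"))
    if len(merged) == 0:
        warnings.warn("maps share no reconstructed CpGs", stacklevel=2)
        return []
    diff = (merged["m_hat_a"] - merged["m_hat_b"]).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN coverage
        cov = np.nanmean(
            np.column_stack([merged["n_window_a"], merged["n_window_b"]]),
            axis=1,
        )
    out: list[DMR] = []
    offset = 0
    for chrom, sub in merged.groupby("chrom", sort=False):
        d = diff[offset:offset + len(sub)]
        cv = cov[offset:offset + len(sub)]
        pos = sub["pos"].to_numpy()
        offset += len(sub)
        state = np.where(np.abs(d) >= delta_min, np.sign(d), 0.0)
        # boundaries of constant-state runs
        change = np.nonzero(np.diff(state))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(state)]])
        for s, e in zip(starts, ends):
            if state[s] == 0 or e - s < min_cpgs:
                continue
            out.append(DMR(
                chrom=str(chrom), start=int(pos[s]), end=int(pos[e - 1]) + 1,
                n_cpg=int(e - s), delta=float(d[s:e].mean()),
                mean_coverage=float(np.nanmean(cv[s:e]))
                if np.isfinite(cv[s:e]).any() else float("nan"),
            ))
    return out


def dmr_features(
    dmr: DMR,
    annotations: Mapping[str, GenomicIntervalSet] | None = None,
    qt_track: pd.DataFrame | None = None,
) -> dict:
    """The six-feature description of a DMR.

    ``annotations`` may provide interval sets under the keys ``cgi``,
    ``promoter`` and ``gene_body``; absent keys leave the context partial,
    and no annotations at all leaves it missing. ``qt_track`` is an optional
    externally computed per-CpG score frame (chrom, pos, qt) whose maximum
    inside the region populates ``max_qt``.
    """
    context: frozenset[str] | None = None
    if annotations is not None:
        flags = set()
        for name in ("cgi", "promoter", "gene_body"):
            iv = annotations.get(name)
            if iv is None:
                continue
            sub = iv.df[(iv.df["chrom"] == dmr.chrom)
                        & (iv.df["start"] < dmr.end)
                        & (iv.df["end"] > dmr.start)]
            if len(sub):
                flags.add(name)
        context = frozenset(flags) if flags else frozenset({"intergenic"})
    max_qt = dmr.max_qt
    if qt_track is not None:
        sel = qt_track[(qt_track["chrom"] == dmr.chrom)
                       & (qt_track["pos"] >= dmr.start)
                       & (qt_track["pos"] < dmr.end)]
        if len(sel):
            max_qt = float(sel["qt"].max())
    return {
        "length_bp": dmr.length_bp,
        "n_cpg": dmr.n_cpg,
        "delta": dmr.delta,
        "max_qt": max_qt,
        "mean_coverage": dmr.mean_coverage,
        "genomic_context": context,
    }


_OPS = {">=": operator.ge, ">": operator.gt, "<=": operator.le,
        "<": operator.lt, "==": operator.eq}
_FEATURES = {"length_bp", "n_cpg", "delta", "abs_delta", "max_qt",
             "mean_coverage"}


def filter_dmrs(
    dmrs: Sequence[DMR], rules: Sequence[tuple[str, str, float]]
) -> list[DMR]:
    """Keep DMRs satisfying every ``(feature, op, value)`` predicate.

    ``abs_delta`` filters on the magnitude of the difference; ``max_qt``
    rules drop DMRs without a score.
    """
    for feat, op, _ in rules:
        if feat not in _FEATURES:
            raise ValidationError(f"unknown feature {feat!r}")
        if op not in _OPS:
            raise ValidationError(f"unknown operator {op!r}")

    def value(d: DMR, feat: str):
        if feat == "abs_delta":
            return abs(d.delta)
        if feat == "length_bp":
            return d.length_bp
        return getattr(d, feat)

    out = []
    for d in dmrs:
        ok = True
        for feat, op, thr in rules:
            v = value(d, feat)
            if v is None or not _OPS[op](v, thr):
                ok = False
                break
        if ok:
            out.append(d)
    return out


def _overlap_matrix(a: Sequence[DMR], b: Sequence[DMR],
                    reciprocal: float) -> np.ndarray:
    hit = np.zeros((len(a), len(b)), dtype=bool)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            ov = min(x.end, y.end) - max(x.start, y.start)
            if ov <= 0:
                continue
            if reciprocal <= 0:
                hit[i, j] = True
            else:
                hit[i, j] = (ov >= reciprocal * (x.end - x.start)
                             and ov >= reciprocal * (y.end - y.start))
    return hit


def dmr_precision_recall(
    detected: Sequence[DMR],
    reference: Sequence[DMR],
    reciprocal: float = 0.0,
) -> dict:
    """Agreement with a reference DMR set by interval overlap.

    Default: any overlap (>= 1 bp). ``reciprocal`` > 0 requires that
    fraction of both intervals to overlap.
    """
    if len(detected) == 0 or len(reference) == 0:
        return {"precision": float("nan") if not detected else 0.0,
                "recall": float("nan") if not reference else 0.0,
                "f1": float("nan")}
    hit = _overlap_matrix(detected, reference, reciprocal)
    precision = float(hit.any(axis=1).mean())
    recall = float(hit.any(axis=0).mean())
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1}


def _pipeline_map(tables: Sequence[CpGCountTable],
                  reference: ReferenceMethylome,
                  max_ct_ratio: float,
                  recon_kwargs: dict) -> MethylationMap:
    pooled = naive_pool(list(tables))
    pooled = mutation_filter(pooled, max_ct_ratio)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reconstruct_map(pooled, reference, **recon_kwargs).map


def permutation_fdr(
    cohort_a_samples: Sequence[CpGCountTable],
    cohort_b_samples: Sequence[CpGCountTable],
    reference: ReferenceMethylome,
    param_grid: Sequence[tuple[float, int]] | None = None,
    n_perm: int = 10,
    seed: int | None = None,
    max_ct_ratio: float = 0.25,
    **recon_kwargs,
) -> pd.DataFrame:
    """Permutation false-discovery-rate over a (delta, min_cpgs) grid.

    Observed DMR counts come from the true labels; each permutation
    shuffles sample labels between the cohorts (group sizes preserved,
    identity permutation excluded), re-pools, re-reconstructs with the same
    configuration and re-detects. Returns one row per grid cell with the
    observed count, the mean permuted count, FDR (NaN when nothing was
    observed) and the acceptance flag (FDR < 0.05).

    ``recon_kwargs`` are forwarded to :func:`reconstruct_map` (e.g. ``W``,
    ``pi``, ``p0``, ``m0``) and are held fixed across permutations.
    """
    if len(cohort_a_samples) < 2 or len(cohort_b_samples) < 2:
        raise ValidationError("each cohort needs at least 2 samples")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if param_grid is None:
        param_grid = [(d, m) for d in DEFAULT_DELTA_GRID
                      for m in DEFAULT_MIN_CPGS_GRID]
    rng = np.random.default_rng(seed)
    n_a = len(cohort_a_samples)
    all_samples = list(cohort_a_samples) + list(cohort_b_samples)
    n_total = len(all_samples)

    map_a = _pipeline_map(cohort_a_samples, reference, max_ct_ratio, recon_kwargs)
    map_b = _pipeline_map(cohort_b_samples, reference, max_ct_ratio, recon_kwargs)
    observed = {cell: len(detect_dmrs(map_a, map_b, *cell))
                for cell in param_grid}

    perm_counts = {cell: [] for cell in param_grid}
    identity = np.arange(n_total)
    for _ in range(n_perm):
        while True:
            order = rng.permutation(n_total)
            if not np.array_equal(order, identity):
                break
        pa = [all_samples[k] for k in order[:n_a]]
        pb = [all_samples[k] for k in order[n_a:]]
        pm_a = _pipeline_map(pa, reference, max_ct_ratio, recon_kwargs)
        pm_b = _pipeline_map(pb, reference, max_ct_ratio, recon_kwargs)
        for cell in param_grid:
            perm_counts[cell].append(len(detect_dmrs(pm_a, pm_b, *cell)))

    rows = []
    for (delta, min_cpgs) in param_grid:
        obs = observed[(delta, min_cpgs)]
        mean_perm = float(np.mean(perm_counts[(delta, min_cpgs)]))
        fdr = mean_perm / obs if obs > 0 else float("nan")
        rows.append({
            "delta": delta, "min_cpgs": min_cpgs, "observed": obs,
            "mean_permuted": mean_perm, "fdr": fdr,
            "accepted": bool(obs > 0 and fdr < FDR_ACCEPT),
        })
    return pd.DataFrame(rows)
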