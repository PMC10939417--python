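"""Pooling per-sample counts into population-level methylation evidence.

Two routes are provided. *Naive pooling* sums cytosine and thymine counts
across samples position-wise, giving every sample the same weight, and the
pooled table is then processed like a single sample. *Advanced pooling*
models the thymine count of sample ``i`` in the window around position ``j``
as ``t_ij ~ Binomial(n_ij, m_j * pi_i)``, where ``pi_i`` is the per-sample
deamination rate, and maximises the joint binomial likelihood over the
common window methylation ``m_j`` by Newton-Raphson on the score

    dl/dm = T_j / m - sum_i (n_ij - t_ij) * pi_i / (1 - m * pi_i),

with ``T_j = sum_i t_ij``. The variance of the estimate is approximated by
the inverse of the empirical Fisher information

    I(m) = T_j / m^2 + sum_i (n_ij - t_ij) * pi_i^2 / (1 - m * pi_i)^2.

Deamination rates are anchored at reference CpGs whose measured methylation
is exactly 1: there, every C->T event reflects deamination of a methylated
cytosine, so ``pi = sum(t) / sum(t + c)`` over the anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .core_io import CpGCountTable, ReferenceMethylome
from .errors import ValidationError

__all__ = [
    "ct_ratio",
    "naive_pool",
    "DeaminationEstimate",
    "DeaminationProfile",
    "estimate_deamination_rate",
    "estimate_deamination_profile",
    "pooled_effective_deamination",
    "MLEResult",
    "mle_window_methylation",
    "mle_methylation_map",
]

# Newton-Raphson controls; iterates are clamped to (EPS, upper - EPS)
NR_TOL = 1e-8
NR_MAX_ITER = 100
EPS = 1e-9


def ct_ratio(t, c):
    """C->T ratio ``t / (t + c)``; errors on zero coverage (scalar input)."""
    t_arr = np.asarray(t, dtype=float)
    c_arr = np.asarray(c, dtype=float)
    n = t_arr + c_arr
    if np.isscalar(t) or t_arr.ndim == 0:
        if n == 0:
            raise ValidationError("C->T ratio undefined at zero coverage")
        return float(t_arr / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, t_arr / np.where(n > 0, n, 1), np.nan)


def naive_pool(tables: Sequence[CpGCountTable]) -> CpGCountTable:
    """Sum counts position-wise across samples (equal sample weights)."""
    if len(tables) == 0:
        raise ValidationError("naive_pool needs at least one table")
    if len(tables) == 1:
        return CpGCountTable(tables[0].df)
    df = pd.concat([t.df for t in tables], ignore_index=True)
    pooled = df.groupby(["chrom", "pos"], as_index=False, sort=False).sum()
    return CpGCountTable(pooled)


@dataclass(frozen=True)
class DeaminationEstimate:
    """Deamination rate of one sample (or one pooled table)."""

    pi: float
    n_anchor: int
    total_t: int
    total_n: int


@dataclass(frozen=True)
class DeaminationProfile:
    """Per-sample deamination rates for a cohort."""

    rates: Mapping[str, DeaminationEstimate]

    def pi(self, sample_id: str) -> float:
        return self.rates[sample_id].pi

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.rates[s].pi for s in order])


def estimate_deamination_rate(
    table: CpGCountTable,
    reference: ReferenceMethylome,
    anchor_methylation: float = 1.0,
) -> DeaminationEstimate:
    """Deamination rate from fully methylated reference CpGs.

    ``pi = sum(t) / sum(t + c)`` over covered CpGs where the reference
    methylation is >= ``anchor_methylation`` (default: exactly 1).
    """
    anchors = reference.df[reference.df["m"] >= anchor_methylation]
    if len(anchors) == 0:
        raise ValidationError(
            "no anchor CpGs with reference methylation "
            f">= {anchor_methylation}; relax anchor_methylation or supply pi"
        )
    merged = table.df.merge(anchors[["chrom", "pos"]], on=["chrom", "pos"])
    n = (merged["c"] + merged["t"]).to_numpy()
    merged = merged[n > 0]
    if len(merged) == 0:
        raise ValidationError(
            "no covered anchor CpGs; relax anchor_methylation or supply pi"
        )
    total_t = int(merged["t"].sum())
    total_n = int((merged["c"] + merged["t"]).sum())
    if total_t == 0:
        warnings.warn("all anchor thymine counts are zero: degenerate "
                      "deamination rate 0", stacklevel=2)
    return DeaminationEstimate(
        pi=total_t / total_n, n_anchor=len(merged), total_t=total_t,
        total_n=total_n,
    )


def estimate_deamination_profile(
    tables: Mapping[str, CpGCountTable],
    reference: ReferenceMethylome,
    anchor_methylation: float = 1.0,
) -> DeaminationProfile:
    """Per-sample deamination rates for advanced pooling."""
    return DeaminationProfile({
        sid: estimate_deamination_rate(tab, reference, anchor_methylation)
        for sid, tab in tables.items()
    })


def pooled_effective_deamination(
    profile: DeaminationProfile,
    coverages: Mapping[str, float] | None = None,
) -> float:
    """Coverage-weighted mean deamination rate of a cohort."""
    if len(profile.rates) == 0:
        raise ValidationError("empty deamination profile")
    ids = list(profile.rates)
    pis = profile.as_array(ids)
    if coverages is None:
        weights = np.array([float(profile.rates[s].total_n) for s in ids])
        if weights.sum() == 0:
            weights = np.ones_like(weights)
    else:
        weights = np.array([float(coverages[s]) for s in ids])
    total = weights.sum()
    if total <= 0:
        raise ValidationError("zero total coverage weight")
    return float((pis * weights).sum() / total)


@dataclass(frozen=True)
class MLEResult:
    """Maximum-likelihood window methylation with its curvature."""

    m_hat: float
    fisher_info: float | None
    var: float | None
    n_iterations: int
    converged: bool
    total_t: int
    n_pi: float  # sum_i pi_i * n_ij
    t_pi: float  # sum_i pi_i * t_ij


def _score(m, n, t, pi):
    return np.sum(t) / m - np.sum((n - t) * pi / (1.0 - m * pi))


def _fisher(m, n, t, pi):
    return np.sum(t) / m**2 + np.sum((n - t) * pi**2 / (1.0 - m * pi) ** 2)


def _loglik_grid(grid, n, t, pi):
    # grid: (G,), sample arrays: (N,) -> (G,) log-likelihood
    mp = grid[:, None] * pi[None, :]
    with np.errstate(divide="ignore"):
        ll = t[None, :] * np.log(mp) + (n - t)[None, :] * np.log1p(-mp)
    return ll.sum(axis=1)


def mle_window_methylation(
    n: Sequence[int],
    t: Sequence[int],
    pi: Sequence[float],
    tol: float = NR_TOL,
    max_iter: int = NR_MAX_ITER,
) -> MLEResult:
    """Maximise the pooled binomial likelihood for one window.

    Parameters are per-sample window totals ``n`` (reads), ``t`` (thymines)
    and deamination rates ``pi``. Samples with ``n == 0`` contribute nothing
    and are dropped; at least one sample must have ``n >= 1``. The iterate is
    kept inside ``(0, min(1, 1/max(pi)))`` so every ``log(1 - m*pi)`` stays
    defined; on ``T = 0`` the boundary solution ``m = 0`` is returned with an
    undefined variance. If Newton-Raphson fails to settle, a grid search over
    the feasible interval is used and ``converged`` is set to False.
    """
    n = np.asarray(n, dtype=float)
    t = np.asarray(t, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if not (n.shape == t.shape == pi.shape):
        raise ValidationError("n, t and pi must have equal length")
    if (t > n).any():
        raise ValidationError("t_ij > n_ij")
    if ((pi <= 0) | (pi > 1)).any():
        raise ValidationError("deamination rates must lie in (0, 1]")
    keep = n >= 1
    if not keep.any():
        raise ValidationError("window has no informative sample (all n = 0)")
    n, t, pi = n[keep], t[keep], pi[keep]

    total_t = float(t.sum())
    n_pi = float((pi * n).sum())
    t_pi = float((pi * t).sum())
    if total_t == 0:
        return MLEResult(0.0, None, None, 0, True, 0, n_pi, t_pi)

    upper = min(1.0, 1.0 / pi.max()) - EPS
    m = total_t / (n_pi - t_pi) if n_pi > t_pi else upper
    m = float(np.clip(m, EPS, upper))
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        s = _score(m, n, t, pi)
        h = -_fisher(m, n, t, pi)  # observed second derivative (negative)
        m_new = float(np.clip(m - s / h, EPS, upper))
        if abs(m_new - m) < tol:
            m = m_new
            converged = True
            break
        m = m_new
    if not converged:
        grid = np.linspace(EPS, upper, 100_001)
        m = float(grid[np.argmax(_loglik_grid(grid, n, t, pi))])
    info = float(_fisher(m, n, t, pi))
    return MLEResult(
        m_hat=m, fisher_info=info, var=1.0 / info if info > 0 else None,
        n_iterations=n_iter, converged=converged, total_t=int(total_t),
        n_pi=n_pi, t_pi=t_pi,
    )


def mle_methylation_map(
    tables: Mapping[str, CpGCountTable],
    profile: DeaminationProfile,
    window: int,
) -> pd.DataFrame:
    """Advanced pooling across a whole map.

    For every CpG covered by any sample, sums each sample's counts over the
    ``window`` consecutive shared CpG positions centred on it and solves the
    window MLE. Returns a frame with ``chrom, pos, m_hat, var, n_window``.
    The Newton iteration is vectorised across positions.
    """
    from .reconstruction import _window_sums  # local import; no cycle at call

    ids = list(tables)
    pis = profile.as_array(ids)
    union = pd.concat(
        [tables[s].df[["chrom", "pos"]] for s in ids], ignore_index=True
    ).drop_duplicates().sort_values(["chrom", "pos"], ignore_index=True)

    n_mat = np.zeros((len(union), len(ids)))
    t_mat = np.zeros((len(union), len(ids)))
    key = union.set_index(["chrom", "pos"]).index
    for k, sid in enumerate(ids):
        df = tables[sid].df
        idx = key.get_indexer(pd.MultiIndex.from_frame(df[["chrom", "pos"]]))
        n_mat[idx, k] = (df["c"] + df["t"]).to_numpy()
        t_mat[idx, k] = df["t"].to_numpy()

    # per-chromosome centred window sums down the position axis
    wn = np.empty_like(n_mat)
    wt = np.empty_like(t_mat)
    for _, sub in union.groupby("chrom", sort=False):
        sl = slice(sub.index[0], sub.index[-1] + 1)
        wn[sl] = _window_sums(n_mat[sl], window)
        wt[sl] = _window_sums(t_mat[sl], window)

    m, var = _vector_newton(wn, wt, pis)
    return pd.DataFrame({
        "chrom": union["chrom"], "pos": union["pos"],
        "m_hat": m, "var": var, "n_window": wn.sum(axis=1),
    })


def _vector_newton(n_mat: np.ndarray, t_mat: np.ndarray, pi: np.ndarray,
                   tol: float = NR_TOL, max_iter: int = NR_MAX_ITER):
    """Newton-Raphson over many windows at once (rows = windows)."""
    total_t = t_mat.sum(axis=1)
    upper = min(1.0, 1.0 / pi.max()) - EPS
    n_pi = n_mat @ pi
    t_pi = t_mat @ pi
    denom = n_pi - t_pi
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(denom > 0, total_t / np.where(denom > 0, denom, 1.0), upper)
    m = np.clip(m, EPS, upper)
    active = total_t > 0
    rows = np.arange(n_mat.shape[0])
    for _ in range(max_iter):
        idx = rows[active]
        if idx.size == 0:
            break
        mm = m[idx][:, None]
        one_minus = 1.0 - mm * pi[None, :]
        resid = (n_mat[idx] - t_mat[idx])
        s = total_t[idx] / m[idx] - (resid * pi[None, :] / one_minus).sum(axis=1)
        info = total_t[idx] / m[idx] ** 2 + (
            resid * pi[None, :] ** 2 / one_minus**2
        ).sum(axis=1)
        m_new = np.clip(m[idx] + s / info, EPS, upper)
        done = np.abs(m_new - m[idx]) < tol
        m[idx] = m_new
        still = active.copy()
        still[idx] = ~done
        active = still
    m = np.where(total_t > 0, m, 0.0)
    one_minus = 1.0 - m[:, None] * pi[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        info = np.where(m > 0, total_t / np.where(m > 0, m, 1.0) ** 2, np.nan)
        info = info + ((n_mat - t_mat) * pi[None, :] ** 2 / one_minus**2).sum(axis=1)
        var = np.where((m > 0) & (info > 0), 1.0 / info, np.nan)
    covered = n_mat.sum(axis=1) >= 1
    m = np.where(covered, m, np.nan)
    var = np.where(covered, var, np.nan)
    return m, var
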