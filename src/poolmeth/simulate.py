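"""Synthetic ancient capture cohorts with known ground truth.

The generator mirrors the generative structure the estimators assume:

* a truth methylome drawn from a beta mixture — hypomethylated CpG-island
  blocks inside a highly methylated background (genome mean ~= 0.74, the
  mean measured in modern bone);
* capture-style coverage: per sample, Poisson coverage whose mean decays
  with distance to the nearest target SNP (halving every ~35 bp, reaching
  a flat off-target plateau beyond ~100 bp);
* deamination: thymine counts ``t ~ Binomial(n, m * pi_i)`` with one
  deamination rate per sample drawn from 1-3%;
* a small fraction of C>T mutation sites whose reads are almost all
  thymine, for exercising the mutation filter;
* optional coverage spikes emulating PCR-duplicate stacks, for exercising
  the coverage cap.

Everything is driven by a single mandatory seed, so outputs are
byte-identical across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (CpGCountTable, GenomicIntervalSet, ReferenceMethylome,
                      SampleRecord, make_promoter_intervals)
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "PlantedDMRSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_two_populations",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int
    n_cpgs: int = 20_000
    chrom: str = "chr1"
    cpg_spacing: float = 100.0       # mean bp between CpGs
    target_spacing: float = 2500.0   # mean bp between capture targets
    peak_coverage: float = 1.2       # per-sample on-target Poisson mean
    decay_bp: float = 35.0           # distance at which on-target mean halves
    plateau_coverage: float = 0.15   # per-sample off-target Poisson mean
    n_samples: int = 50
    pi_range: tuple[float, float] = (0.01, 0.03)
    cgi_fraction: float = 0.10       # fraction of CpGs inside island blocks
    cgi_width_cpgs: int = 30
    bg_beta: tuple[float, float] = (6.36, 1.64)   # mean 0.795
    cgi_beta: tuple[float, float] = (1.0, 9.0)    # mean 0.1
    fully_methylated_fraction: float = 0.08  # point mass at exactly 1 (anchors)
    mutation_fraction: float = 0.002
    duplicate_spike: tuple[float, int] | None = None  # (site fraction, extra n)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.n_cpgs < 1:
            raise ValidationError("n_cpgs must be >= 1")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        lo, hi = self.pi_range
        if not (0 <= lo <= hi < 1):
            raise ValidationError("pi_range must satisfy 0 <= lo <= hi < 1")
        for name in ("cgi_fraction", "mutation_fraction",
                     "fully_methylated_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("peak_coverage", "plateau_coverage"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.peak_coverage + self.plateau_coverage <= 0:
            raise ValidationError("coverage model is identically zero")


@dataclass(frozen=True)
class PlantedDMRSpec:
    """Planted differential-methylation signal between two populations."""

    count: int = 20
    width_cpgs: int = 100
    delta: float = 0.5

    def __post_init__(self) -> None:
        if self.count < 0 or self.width_cpgs < 1:
            raise ValidationError("invalid planted-DMR spec")
        if not 0 <= self.delta <= 1:
            raise ValidationError("planted delta must be in [0, 1]")


@dataclass
class SimulatedCohort:
    """A synthetic cohort plus every truth track needed for evaluation."""

    config: SimulationConfig
    samples: list[CpGCountTable]
    sample_ids: list[str]
    manifest: list[SampleRecord]
    truth: ReferenceMethylome
    targets: GenomicIntervalSet
    cgi: GenomicIntervalSet
    promoters: GenomicIntervalSet
    pis: dict[str, float]


def _truth_methylome(config: SimulationConfig, rng: np.random.Generator):
    spacing = 2 + rng.exponential(max(config.cpg_spacing - 2, 1),
                                  config.n_cpgs)
    pos = np.cumsum(spacing).astype(np.int64)
    m = rng.beta(*config.bg_beta, config.n_cpgs)
    # non-overlapping island blocks, one per evenly sized slot
    n_cgi = int(round(config.n_cpgs * config.cgi_fraction
                      / config.cgi_width_cpgs))
    cgi_idx = np.zeros(config.n_cpgs, dtype=bool)
    blocks = []
    if n_cgi > 0:
        slot = config.n_cpgs // n_cgi
        for k in range(n_cgi):
            hi = slot - config.cgi_width_cpgs
            if hi <= 0:
                break
            s = k * slot + rng.integers(0, hi)
            e = s + config.cgi_width_cpgs
            cgi_idx[s:e] = True
            blocks.append((int(pos[s]), int(pos[e - 1]) + 1))
    m[cgi_idx] = rng.beta(*config.cgi_beta, int(cgi_idx.sum()))
    # WGBS references carry a point mass at exactly 1; these sites anchor
    # the deamination-rate estimate
    fully = (rng.random(config.n_cpgs)
             < config.fully_methylated_fraction) & ~cgi_idx
    m[fully] = 1.0
    return pos, m, blocks


def _distance_to_targets(pos: np.ndarray, tpos: np.ndarray) -> np.ndarray:
    right = np.searchsorted(tpos, pos)
    big = np.iinfo(np.int64).max
    d_right = np.where(right < tpos.size,
                       tpos[np.clip(right, 0, tpos.size - 1)] - pos, big)
    d_left = np.where(right > 0, pos - tpos[np.clip(right - 1, 0, None)], big)
    return np.minimum(d_left, d_right)


def _draw_samples(config: SimulationConfig, pos: np.ndarray, m: np.ndarray,
                  dist: np.ndarray, tpos: np.ndarray,
                  rng: np.random.Generator, prefix: str):
    mu = config.plateau_coverage + config.peak_coverage * np.exp2(
        -dist / config.decay_bp)
    mutant = rng.random(pos.size) < config.mutation_fraction
    # genome-scale SNP-hit proxy: probability a target carries >= 1 read
    p_hit = 1 - np.exp(-(config.peak_coverage + config.plateau_coverage))
    samples, ids, manifest, pis = [], [], [], {}
    for i in range(config.n_samples):
        sid = f"{prefix}{i:03d}"
        pi = rng.uniform(*config.pi_range)
        n = rng.poisson(mu)
        if config.duplicate_spike is not None:
            frac, extra = config.duplicate_spike
            spiked = rng.random(pos.size) < frac
            n = n + np.where(spiked, extra, 0)
        p = np.where(mutant, 0.99, m * pi)
        t = rng.binomial(n, p)
        covered = n >= 1
        df = pd.DataFrame({
            "chrom": config.chrom, "pos": pos[covered],
            "c": n[covered] - t[covered], "t": t[covered],
        })
        samples.append(CpGCountTable(df))
        ids.append(sid)
        pis[sid] = float(pi)
        n_hit = int(1_150_000 * p_hit * rng.uniform(0.85, 1.15))
        manifest.append(SampleRecord(
            sample_id=sid, path="", autosomal_snp_hits=max(n_hit, 30_000),
            sex="F" if rng.random() < 0.5 else "M",
            skeletal_element="petrous",
        ))
    return samples, ids, manifest, pis


def simulate_cohort(config: SimulationConfig,
                    sample_prefix: str = "S") -> SimulatedCohort:
    """Generate one cohort with truth tracks (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    pos, m, blocks = _truth_methylome(config, rng)
    length = int(pos[-1]) + 2
    n_targets = max(1, int(length / config.target_spacing))
    tpos = np.sort(rng.integers(0, length, n_targets)).astype(np.int64)
    dist = _distance_to_targets(pos, tpos)
    samples, ids, manifest, pis = _draw_samples(config, pos, m, dist, tpos,
                                                rng, sample_prefix)

    truth = ReferenceMethylome(pd.DataFrame(
        {"chrom": config.chrom, "pos": pos, "m": m}))
    targets = GenomicIntervalSet(pd.DataFrame({
        "chrom": config.chrom, "start": tpos, "end": tpos + 1,
        "name": [f"snp{k}" for k in range(tpos.size)],
    }).drop_duplicates(["start"]))
    cgi = GenomicIntervalSet(pd.DataFrame(
        blocks, columns=["start", "end"]).assign(chrom=config.chrom)) \
        if blocks else GenomicIntervalSet(
            pd.DataFrame(columns=["chrom", "start", "end"]).astype(
                {"start": np.int64, "end": np.int64}))
    # promoters anchored on a subset of island blocks (hypomethylated, as
    # housekeeping promoters are)
    if blocks:
        tss = pd.DataFrame({
            "chrom": config.chrom,
            "pos": [b[0] for b in blocks[::2]],
            "strand": ["+" if k % 2 == 0 else "-"
                       for k in range(len(blocks[::2]))],
        })
        promoters = make_promoter_intervals(tss)
    else:
        promoters = GenomicIntervalSet(pd.DataFrame(
            columns=["chrom", "start", "end"]).astype(
                {"start": np.int64, "end": np.int64}))
    return SimulatedCohort(config, samples, ids, manifest, truth, targets,
                           cgi, promoters, pis)


def simulate_two_populations(
    config: SimulationConfig,
    planted: PlantedDMRSpec,
    config_b: SimulationConfig | None = None,
) -> tuple[SimulatedCohort, SimulatedCohort, GenomicIntervalSet]:
    """Two cohorts on one coordinate frame, differing only in planted DMRs.

    Population B's truth methylome equals A's except inside ``planted.count``
    non-overlapping regions of ``planted.width_cpgs`` CpGs, where the two
    differ by ``planted.delta`` (direction alternating between regions;
    within a region the truth is flat, as methylation domains are). Returns
    both cohorts and the truth DMR intervals.
    """
    if config_b is None:
        config_b = replace(config, seed=config.seed + 1)
    if planted.count > 0 and planted.delta == 0:
        warnings.warn("planted delta is 0: truth methylomes are identical",
                      stacklevel=2)
    rng = np.random.default_rng(config.seed)
    pos, m_a, blocks = _truth_methylome(config, rng)
    length = int(pos[-1]) + 2
    n_targets = max(1, int(length / config.target_spacing))
    tpos = np.sort(rng.integers(0, length, n_targets)).astype(np.int64)
    dist = _distance_to_targets(pos, tpos)

    m_a = m_a.copy()
    m_b = m_a.copy()
    regions = []
    if planted.count > 0:
        slot = config.n_cpgs // planted.count
        if slot <= planted.width_cpgs:
            raise ValidationError(
                "planted DMRs would overlap: too many/too wide for n_cpgs")
        for k in range(planted.count):
            s = k * slot + int(rng.integers(0, slot - planted.width_cpgs))
            e = s + planted.width_cpgs
            if k % 2 == 0:
                m_a[s:e], m_b[s:e] = 0.85, 0.85 - planted.delta
            else:
                m_a[s:e], m_b[s:e] = 0.15, 0.15 + planted.delta
            regions.append((int(pos[s]), int(pos[e - 1]) + 1))

    out = []
    for cfg, m, prefix in ((config, m_a, "A"), (config_b, m_b, "B")):
        sub_rng = np.random.default_rng(cfg.seed + 104_729)
        samples, ids, manifest, pis = _draw_samples(cfg, pos, m, dist, tpos,
                                                    sub_rng, prefix)
        truth = ReferenceMethylome(pd.DataFrame(
            {"chrom": cfg.chrom, "pos": pos, "m": m}))
        targets = GenomicIntervalSet(pd.DataFrame({
            "chrom": cfg.chrom, "start": tpos, "end": tpos + 1,
        }).drop_duplicates(["start"]))
        cgi = GenomicIntervalSet(pd.DataFrame(
            blocks, columns=["start", "end"]).assign(chrom=cfg.chrom))
        out.append(SimulatedCohort(cfg, samples, ids, manifest, truth,
                                   targets, cgi, cgi, pis))
    truth_dmrs = GenomicIntervalSet(pd.DataFrame(
        regions, columns=["start", "end"]).assign(
            chrom=config.chrom,
            name=[f"dmr{k}" for k in range(len(regions))])) \
        if regions else GenomicIntervalSet(pd.DataFrame(
            columns=["chrom", "start", "end"]).astype(
                {"start": np.int64, "end": np.int64}))
    return out[0], out[1], truth_dmrs
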