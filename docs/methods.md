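# Methods

## Signal model

At a CpG cytosine covered by `n` reads of a USER-treated ancient library,
the thymine count is modelled as `t ~ Binomial(n, m·π)`, where `m` is the
premortem methylation level of the site and `π` the sample's deamination
rate. Pooling individuals from one population assumes methylation is
homogeneous within the population relative to the noise — the premise that
within-population variability is small compared to between-population
differences. All downstream machinery (pooling, window aggregation, the
window MLE, the simulator) is built on this binomial model.

`π` is anchored at reference CpGs whose measured methylation is exactly 1:
there every C→T event reflects deamination of a methylated cytosine, so
`π = Σt / Σ(t+c)` over covered anchors. The anchor criterion is exact
equality by default; `anchor_methylation` can relax it (e.g. ≥ 0.95) for
references with few exact-1 sites.

## Filters

* **Sample screen**: individuals with fewer than 30 000 autosomal SNP hits
  are excluded; below that, inference is unreliable.
* **PCR-duplicate cap**: per sample and chromosome, the coverage histogram
  (from coverage 1; uncovered sites carry no duplicates) is smoothed with a
  centred running mean of length 5, truncated at the edges. The cap is the
  first coverage whose smoothed count is ≤ 1; sites at or above it are
  removed. If no smoothed count reaches 1, nothing is capped.
* **Mutation filter**: pooled sites with C→T ratio strictly above 0.25 are
  removed as likely C>T polymorphisms. The filter runs on the *pooled*
  table, after pooling and before windowing: at single-sample coverage a
  lone thymine read yields ratio 1 and the filter would delete the genome.
  Ordering is per-sample cap → pool → mutation filter.

All filters are idempotent, and every pipeline stage logs how many records
it dropped (`RunManifest`); counts are conserved.

## Window size

Requiring that a window over a region methylated at least `m0` shows zero
thymines with probability below `p0` gives a minimum accumulated coverage
`ln p0 / ln(1 − π·m0)`, hence `W = ⌈(1/C)·ln p0 / ln(1 − π·m0)⌉` CpGs at
effective coverage `C`, capped at `W_max = 31` and floored at 1. Defaults
`p0 = 0.01`, `m0 = 0.2` make a 15× cohort hit the 31-CpG cap (31 × 15 =
465× accumulated coverage, the depth single-sample shotgun reconstruction
operates at). Both are configurable; the cap keeps windows small enough
that methylation is locally constant. `C` is computed from the pooled
table after all filters. Even `W` (the ceiling can produce one) takes
⌈(W−1)/2⌉ rows before and ⌊(W−1)/2⌋ after the centre; windows truncate at
chromosome ends and never cross chromosomes.

## Histogram matching

Window C→T ratios are calibrated to methylation by matching their
distribution to a reference methylome (bone WGBS). The reference is
binned into 101 equal-width bins on [0,1], the signal at 0.001 resolution
over its observed range; each signal bin value maps to the reference bin
value whose normalised cumulative histogram is closest (argmin over
|H_i − h_j|, ties to the smallest index). The transform is monotone by
construction of the cumulative histograms.

Cumulative counts are evaluated at the middle of each bin's own mass
(continuity correction / Hazen position). This matters at low coverage:
windows with zero thymines form a clump of tied ratios, and an inclusive
CDF would map the whole clump to the *top* of its quantile range, biasing
the genome-wide mean upward by several percent right at the usability
threshold. With the continuity correction the clump maps to the centre of
its range; residual bias comes only from the curvature of the reference
quantile function, stays within ±0.01 of the truth mean for effective
coverage ≥ 12 in simulation, and grows monotonically (to ≈ 0.05–0.07 at
effective coverage ≈ 2–3) as coverage drops — the same
mean-versus-coverage saturation that motivates the threshold of 12.

Resolution limit: a bin-to-bin transform cannot spread an atom. When the
signal is compressed into a very small range (raw C→T ratios span only a
few hundredths), single 0.001-wide bins can hold percents of the mass and
the matched distribution is granular at that scale. This binning error is
well below the reconstruction noise (next section), which is why the
default resolution is left at 0.001; `signal_resolution` is configurable.

## Noise model and what accuracy to expect

For a window with accumulated coverage `n_w`, the C→T ratio has binomial
standard error `sqrt(m·π/n_w)`; divided by the calibration slope (≈ π),
the per-site methylation error is `σ ≈ sqrt(m/(n_w·π))`. At the usability
margin (C = 15, W = 31, π = 0.02: `n_w ≈ 465`) this is ≈ 0.28 — individual
sites are noisy, and neighbouring sites share windows so the noise is
block-correlated over ~W sites. Distribution-level summaries (genome mean,
interval means, binned-ratio QC) average this noise away; per-site values
should be read through the variance track, not as point estimates. The
property suite asserts the reconstruction achieves this floor (RMSE
against window-averaged truth ≤ 1.5σ), rather than an accuracy the depth
cannot support.

## Effective-coverage planning model

Ordinary least squares of cohort effective coverage on the number of
samples and the mean autosomal SNP hits in units of 10⁵, over the seven
bundled cohort summaries (`poolmeth.cohorts`):
`E.C = 0.2338·N + 5.04·(hits/10⁵) − 31.2914`, MSE (SSE/n) 0.85, R² 0.99.
The 10⁵ scaling is the convention under which these printed diagnostics
reproduce exactly. Predictions ≥ 12 flag a cohort as reconstructable; the
flag is advisory (a warning, not a refusal).

## DMR detection and FDR

A DMR between two maps is a maximal run of at least `min_cpgs` consecutive
CpGs present in both maps where the signed difference keeps one sign and
|difference| ≥ Δ at every site. This deterministic run-length scan is this
package's detection rule; an externally computed per-CpG score can be
attached (`max_qt`) but none is computed here. Default grids Δ ∈ {0.3,
0.4, 0.5}, min_cpgs ∈ {30, 40, 50}; between-population comparisons use
Δ = 0.4, min_cpgs = 40. Each DMR carries six features: length in bases,
CpG count, mean difference, optional max_qt, mean coverage, genomic
context (CpG island / promoter / gene body / intergenic).

FDR control permutes sample labels between the cohorts (group sizes
preserved, identity permutation excluded, seeded), re-pools and
re-reconstructs both pseudo-cohorts with the identical configuration
(permuting reconstructed maps instead would ignore pooling noise), and
re-detects; FDR = mean permuted count / observed count, accepted below
0.05. Ten permutations by default.

Power note: the site-wise threshold makes a detection only when *every*
site in a ≥ 40-CpG run clears Δ, so per-site noise must sit well below Δ.
With σ ≈ sqrt(m/(n_w·π)), holding a 0.1 margin below Δ = 0.4 over a run
needs accumulated window coverage in the tens of thousands — pooled
per-site depth of several hundred. The planted-DMR calibration simulation
therefore uses a dense, shotgun-like cohort (uniform coverage, 16 samples
at ~62× each, pooled ≈ 1000×; site σ ≈ 0.03), with 20 planted 100-CpG
regions at |Δ| = 0.5 on a 40 000-CpG genome (≤ 5% of sites perturbed, so
histogram matching stays calibrated). Null calibration (exchangeable
cohorts, FDR ratio ≈ 1) runs 50 replicates of 4 000-CpG, 8-vs-8-sample
cohorts at a lenient cell (Δ = 0.2, 10 CpGs) so that null detections
actually occur; exchangeability makes the observed/permuted ratio ≈ 1 at
any cell with nonzero counts.

## Simulator

The generator emulates, per sample: coverage Poisson-distributed around
`plateau + peak·2^(−d/35)` where `d` is the distance to the nearest target
SNP (defaults peak 1.2, plateau 0.15 per sample — the on-target component
decays onto the off-target plateau beyond ~100–150 bp, and effective
coverage ≈ 0.2 per pooled sample, matching the bundled cohort table's
slope); a deamination rate drawn uniformly from 1–3%; thymine counts
`t ~ Binomial(n, m·π)`; a configurable fraction of C>T mutation sites
emitting almost-all-thymine reads; optional coverage spikes emulating PCR
duplicate stacks. The truth methylome is a beta mixture: hypomethylated
CpG-island blocks (10% of CpGs in 30-CpG blocks, Beta(1, 9)), a point
mass at exactly 1 (8% of CpGs — WGBS references report many sites as
exactly 1, and deamination anchoring needs them), background
Beta(6.36, 1.64); genome mean ≈ 0.74, the bone-methylome average.
Promoter annotations are anchored on island blocks (housekeeping promoters
are hypomethylated). Two-population simulation plants non-overlapping
constant-methylation DMRs of configurable count/width/|Δ|, alternating
direction, and emits the truth intervals.

Everything is deterministic in a single mandatory seed.

What the simulator does *not* model — and what passing tests therefore do
not show about real data: single-strand overhang deamination structure
(one rate per sample only), contamination, fragment-length effects,
reference bias, tissue heterogeneity within a cohort, and real methylome
autocorrelation beyond block structure. It tests the estimators under
their own generative assumptions.

## Numerical choices

* Newton–Raphson: stop at |Δm| < 1e−8, max 100 iterations; iterates
  clamped to (1e−9, min(1, 1/max π) − 1e−9) so every log stays defined;
  T = 0 short-circuits to m̂ = 0 with undefined variance (the information
  degenerates at the boundary); non-convergence falls back to a 10⁵-point
  grid search and flags `converged = False`. Initial guess
  m⁰ = T/(N^π − T^π) from the small-π expansion of the score.
* Window MLE across a whole map is the same iteration vectorised over
  positions.
* Histogram-matching ties in the argmin break toward the smallest index;
  degenerate single-valued signals yield a constant transform with a
  warning.
* Coverage-histogram smoothing truncates the running mean at the edges
  (shorter windows at the boundaries).
* `window_size` is decreasing in C, π, m0, and also decreasing in p0 (a
  laxer zero-thymine probability permits a smaller window).
* Intervals are 0-based half-open everywhere; a CpG is identified by its
  plus-strand cytosine position; missing map values are encoded by
  omission in bedGraph output.

## Known limitations

* Per-site estimates at realistic capture depths are dominated by binomial
  noise (σ ≈ 0.2–0.3); only aggregate statements are reliable there.
* The run-length DMR scan is conservative and needs deep pooled coverage;
  between sparse cohorts, lenient cells of the (Δ, min_cpgs) grid plus the
  permutation FDR are the intended operating point.
* Strand handling happens upstream: the canonical count-table format is
  strand-agnostic, and BAM/CRAM processing is out of scope.
* The effective-coverage regression is fit to seven cohorts; treat
  extrapolations far outside their range (21–142 samples, ~0.6–0.8 M hits)
  with caution.
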