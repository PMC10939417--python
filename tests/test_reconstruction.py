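import warnings

import numpy as np
import pandas as pd
import pytest

from poolmeth import (MethylationMap, SimulationConfig, ValidationError,
                      binned_ct_qc, block_correlation, cohort_summary_table,
                      coverage_vs_target_distance, effective_coverage,
                      fit_effective_coverage_model, fit_histogram_transform,
                      interval_mean_methylation, mutation_filter, naive_pool,
                      predict_effective_coverage, reconstruct_map,
                      simulate_cohort, sliding_window_ratio, window_size)
from poolmeth.core_io import GenomicIntervalSet

from conftest import make_reference, make_table, random_table


def reconstruct_simulated(seed, n_samples, n_cpgs=20_000):
    cohort = simulate_cohort(SimulationConfig(seed=seed, n_cpgs=n_cpgs,
                                              n_samples=n_samples))
    pooled = mutation_filter(naive_pool(cohort.samples))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = reconstruct_map(pooled, cohort.truth)
    return cohort, result


class TestEffectiveCoverage:
    def test_mean_over_covered_sites(self):
        table = make_table([(100, 2, 0), (200, 3, 1)])
        assert effective_coverage(table) == 3.0

    def test_single_site(self):
        assert effective_coverage(make_table([(100, 7, 0)])) == 7.0

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            effective_coverage(make_table([]))


class TestWindowSize:
    def test_low_coverage_hits_cap(self):
        # raw value 77 before the cap
        assert window_size(15, p0=0.01, m0=0.2, pi=0.02) == 31

    def test_high_coverage(self):
        assert window_size(100, p0=0.01, m0=0.2, pi=0.02) == 12

    def test_monotonicity(self):
        base = dict(p0=0.01, m0=0.2, pi=0.02, W_max=10_000)
        assert window_size(30, **base) >= window_size(60, **base)
        assert window_size(30, p0=0.01, m0=0.2, pi=0.02, W_max=10_000) >= \
            window_size(30, p0=0.01, m0=0.2, pi=0.04, W_max=10_000)
        assert window_size(30, p0=0.01, m0=0.2, pi=0.02, W_max=10_000) >= \
            window_size(30, p0=0.01, m0=0.4, pi=0.02, W_max=10_000)
        # a laxer zero-thymine probability allows a smaller window
        assert window_size(30, p0=0.01, m0=0.2, pi=0.02, W_max=10_000) >= \
            window_size(30, p0=0.2, m0=0.2, pi=0.02, W_max=10_000)

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            window_size(15, pi=0.0)
        with pytest.raises(ValidationError):
            window_size(0.0)


class TestSlidingWindow:
    def test_w1_is_per_site_ratio(self):
        table = make_table([(100, 3, 1), (200, 5, 0), (300, 0, 2)])
        out = sliding_window_ratio(table, 1)
        np.testing.assert_allclose(out["ratio"], [0.25, 0.0, 1.0])

    def test_center_window(self):
        table = make_table([(100, 9, 1), (200, 8, 2), (300, 7, 3)])
        out = sliding_window_ratio(table, 3)
        assert out.loc[1, "ratio"] == pytest.approx(6 / 30)

    def test_edge_truncation_short_chromosome(self):
        table = make_table([(100, 9, 1), (200, 8, 2)])
        out = sliding_window_ratio(table, 31)
        # both sites see both rows
        np.testing.assert_allclose(out["sum_n"], [20, 20])
        np.testing.assert_allclose(out["ratio"], [0.15, 0.15])

    def test_matches_brute_force_windows(self, rng):
        import math
        table = random_table(rng, n_sites=60)
        for W in (2, 4, 7):
            out = sliding_window_ratio(table, W)
            t = table.df["t"].to_numpy()
            n = table.n.to_numpy()
            left = math.ceil((W - 1) / 2)
            right = (W - 1) // 2
            for j in range(len(table)):
                lo, hi = max(0, j - left), min(len(table), j + right + 1)
                assert out.loc[j, "sum_t"] == t[lo:hi].sum()
                assert out.loc[j, "sum_n"] == n[lo:hi].sum()

    def test_windows_do_not_cross_chromosomes(self):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"], "pos": [100, 200, 100],
            "c": [10, 10, 0], "t": [0, 0, 10]})
        from poolmeth import CpGCountTable
        out = sliding_window_ratio(CpGCountTable(df), 31)
        assert out.loc[0, "ratio"] == 0.0
        assert out.loc[2, "ratio"] == 1.0


class TestHistogramMatching:
    def test_identity_when_signal_equals_reference(self, rng):
        values = rng.beta(2, 1, 20_000)
        transform = fit_histogram_transform(values, values)
        out = transform(values)
        assert np.nanmax(np.abs(out - values)) <= 1.0 / 101 + 1e-12

    def test_halved_signal_recovers_doubling_map(self, rng):
        reference = rng.uniform(0, 1, 50_000)
        signal = reference * 0.5
        transform = fit_histogram_transform(signal, reference)
        grid = rng.uniform(0.05, 0.45, 200)
        np.testing.assert_allclose(transform(grid), 2 * grid, atol=0.03)

    def test_monotone_transform(self, rng):
        for _ in range(20):
            signal = rng.beta(rng.uniform(0.5, 3), rng.uniform(0.5, 3), 2000)
            signal *= rng.uniform(0.05, 1.0)
            reference = rng.beta(rng.uniform(0.5, 3), rng.uniform(0.5, 3),
                                 2000)
            transform = fit_histogram_transform(signal, reference)
            assert (np.diff(transform.mapped_values) >= 0).all()

    def test_degenerate_signal_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            transform = fit_histogram_transform(np.full(10, 0.3),
                                                np.linspace(0, 1, 100))
        assert np.unique(transform(np.full(5, 0.3))).size == 1

    def test_matched_signal_sits_on_reference(self, rng):
        # KS distance of the matched signal to the reference stays within
        # the binning resolution (signal spread over >= ~0.2 so 0.001-wide
        # bins each hold well under a percent of the mass)
        from scipy.stats import ks_2samp
        for _ in range(10):
            signal = rng.beta(2, 5, 5000) * rng.uniform(0.2, 1.0)
            reference = rng.beta(5, 2, 5000)
            out = fit_histogram_transform(signal, reference)(signal)
            assert ks_2samp(out, reference).statistic <= 2.0 / 101


class TestEffectiveCoverageModel:
    def test_seven_cohort_table_reproduces_printed_fit(self):
        model = fit_effective_coverage_model(cohort_summary_table())
        assert round(model.coef_num_samples, 4) == 0.2338
        assert round(model.coef_snp_hits, 2) == 5.04
        assert round(model.intercept, 4) == -31.2914
        assert round(model.mse, 2) == 0.85
        assert round(model.r2, 2) == 0.99

    def test_exact_linear_data_recovered(self):
        table = pd.DataFrame({
            "num_samples": [10, 20, 30, 40],
            "avg_snp_hits": np.array([1, 3, 2, 5]) * 1e5,
            "effective_coverage": [0.0, 0.0, 0.0, 0.0],
        })
        table["effective_coverage"] = (2 * table["num_samples"]
                                       + 3 * table["avg_snp_hits"] / 1e5 + 1)
        model = fit_effective_coverage_model(table)
        assert model.coef_num_samples == pytest.approx(2.0)
        assert model.coef_snp_hits == pytest.approx(3.0)
        assert model.intercept == pytest.approx(1.0)
        assert model.mse == pytest.approx(0.0, abs=1e-20)

    def test_too_few_rows(self):
        with pytest.raises(ValidationError):
            fit_effective_coverage_model(cohort_summary_table().head(2))

    def test_rank_deficient(self):
        table = pd.DataFrame({
            "num_samples": [10, 10, 10],
            "avg_snp_hits": [1e5, 1e5, 1e5],
            "effective_coverage": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValidationError):
            fit_effective_coverage_model(table)

    def test_predictions_and_threshold(self):
        model = fit_effective_coverage_model(cohort_summary_table())
        small, ok_small = predict_effective_coverage(model, 21, 685_503)
        large, ok_large = predict_effective_coverage(model, 142, 680_901)
        assert small == pytest.approx(8.17, abs=0.02)
        assert not ok_small
        assert large == pytest.approx(36.2, abs=0.1)
        assert ok_large


class TestQc:
    def test_binned_ct_monotone_on_simulation(self):
        cohort, result = reconstruct_simulated(seed=3, n_samples=70)
        pooled = mutation_filter(naive_pool(cohort.samples))
        table, r = binned_ct_qc(pooled, cohort.truth)
        occupied = table["mean_ratio"].dropna()
        assert r >= 0.95
        # allow one inversion from noise in sparse bins
        diffs = np.diff(occupied.to_numpy())
        assert (diffs >= -0.002).all()

    def test_constant_reference_single_bin(self):
        table = make_table([(100 + 10 * k, 5, 1) for k in range(20)])
        ref = make_reference([1.0] * 20, start=100, step=10)
        bins, r = binned_ct_qc(table, ref, n_bins=10)
        assert bins["mean_ratio"].notna().sum() == 1
        assert np.isnan(r)

    def test_no_deamination_all_zero(self):
        table = make_table([(100 + 10 * k, 5, 0) for k in range(20)])
        ref = make_reference(list(np.linspace(0, 1, 20)), start=100, step=10)
        bins, _ = binned_ct_qc(table, ref, n_bins=10)
        assert (bins["mean_ratio"].dropna() == 0).all()


class TestIntervalMeans:
    def test_half_open_overlap(self):
        m = MethylationMap(pd.DataFrame({
            "chrom": "chr1", "pos": [100, 200], "m_hat": [0.1, 0.9]}))
        iv = GenomicIntervalSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [50], "end": [150]}))
        inside, genome = interval_mean_methylation(m, iv)
        assert inside == pytest.approx(0.1)
        assert genome == pytest.approx(0.5)

    def test_full_cover_equals_genome_mean(self):
        m = MethylationMap(pd.DataFrame({
            "chrom": "chr1", "pos": [100, 200], "m_hat": [0.1, 0.9]}))
        iv = GenomicIntervalSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000]}))
        inside, genome = interval_mean_methylation(m, iv)
        assert inside == genome

    def test_cgi_hypomethylated_in_reconstruction(self):
        cohort, result = reconstruct_simulated(seed=3, n_samples=70)
        cgi_mean, genome_mean = interval_mean_methylation(result.map,
                                                          cohort.cgi)
        assert cgi_mean < genome_mean - 0.2


class TestCoverageVsDistance:
    def test_single_distance(self):
        table = make_table([(100, 5, 0)])
        targets = GenomicIntervalSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [101]}))
        curve = coverage_vs_target_distance(table, targets)
        assert curve["distance"].tolist() == [0]
        assert curve["mean_coverage"].tolist() == [5.0]

    def test_decay_then_plateau_on_simulation(self):
        cohort = simulate_cohort(SimulationConfig(seed=9, n_cpgs=30_000,
                                                  n_samples=30))
        curve = coverage_vs_target_distance(cohort.samples, cohort.targets,
                                            max_dist=300)
        near = curve[curve["distance"] <= 20]["mean_coverage"].mean()
        mid = curve[(curve["distance"] > 60)
                    & (curve["distance"] <= 100)]["mean_coverage"].mean()
        far = curve[curve["distance"] > 150]["mean_coverage"].mean()
        assert near > 2 * mid > 2 * far
        # off-target plateau: flat once the on-target component has decayed
        flat_a = curve[(curve["distance"] > 150)
                       & (curve["distance"] <= 225)]["mean_coverage"].mean()
        flat_b = curve[curve["distance"] > 225]["mean_coverage"].mean()
        assert flat_b == pytest.approx(flat_a, rel=0.25)

    def test_empty_targets_error(self):
        table = make_table([(100, 5, 0)])
        empty = GenomicIntervalSet(pd.DataFrame(
            columns=["chrom", "start", "end"]).astype(
                {"start": np.int64, "end": np.int64}))
        with pytest.raises(ValidationError):
            coverage_vs_target_distance(table, empty)


class TestReconstructMap:
    def test_error_shrinks_with_coverage(self):
        maes = []
        for n_samples in (25, 60, 140):
            cohort, result = reconstruct_simulated(seed=21, n_samples=n_samples,
                                                   n_cpgs=12_000)
            merged = result.map.present.merge(cohort.truth.df,
                                              on=["chrom", "pos"])
            maes.append(float((merged["m_hat"] - merged["m"]).abs().mean()))
        assert maes[0] > maes[1] > maes[2]

    def test_windowed_truth_rmse(self):
        # the binomial noise model puts the per-site standard error at
        # sqrt(m / (n_window * pi)); the reconstruction should not do much
        # worse than that floor against the window-averaged truth
        cohort, result = reconstruct_simulated(seed=21, n_samples=70)
        merged = result.map.present.merge(cohort.truth.df, on=["chrom", "pos"])
        win_truth = (merged["m"].rolling(result.window, center=True,
                                         min_periods=1).mean())
        rmse = float(np.sqrt(((merged["m_hat"] - win_truth) ** 2).mean()))
        n_w = float(np.median(merged["n_window"]))
        sigma_model = np.sqrt(win_truth.mean()
                              / (n_w * result.deamination_rate))
        assert rmse <= 1.5 * sigma_model

    def test_map_values_in_unit_interval(self):
        cohort, result = reconstruct_simulated(seed=5, n_samples=40,
                                               n_cpgs=8_000)
        m = result.map.present["m_hat"]
        assert ((m >= 0) & (m <= 1)).all()

    def test_map_only_covers_pooled_chromosomes(self):
        table = make_table([(100 + 30 * k, 6, 0) for k in range(200)])
        ref = make_reference([1.0] * 100 + [0.5] * 100, start=100, step=30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = reconstruct_map(table, ref, pi=0.02)
        assert set(result.map.df["chrom"]) == {"chr1"}

    def test_block_correlation_self(self):
        cohort, result = reconstruct_simulated(seed=5, n_samples=40,
                                               n_cpgs=8_000)
        assert block_correlation(result.map, result.map) == pytest.approx(1.0)
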