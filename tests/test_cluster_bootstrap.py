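import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

from surgicc import (
    ClusteredDataset,
    SimulationSpec,
    anova_icc,
    bc_interval,
    bca_interval,
    bootstrap_icc_ci,
    cluster_resample,
    jackknife_icc,
    percentile_interval,
    simulate_continuous,
)


# ---------------------------------------------------------------------------
# independent straight-line evaluations of the Efron formulas (test oracle)
# ---------------------------------------------------------------------------

def efron_bc(theta_hat, reps, level):
    reps = np.sort(np.asarray(reps, float))
    p = np.mean(reps < theta_hat)
    z0 = ndtri(p)
    z = ndtri(1 - (1 - level) / 2)
    return tuple(
        np.quantile(reps, ndtr(2 * z0 + s * z)) for s in (-1.0, 1.0)
    )


def efron_bca(theta_hat, reps, jack, level):
    reps = np.asarray(reps, float)
    jack = np.asarray(jack, float)
    z0 = ndtri(np.mean(reps < theta_hat))
    d = jack.mean() - jack
    a = (d**3).sum() / (6 * ((d**2).sum()) ** 1.5)
    z = ndtri(1 - (1 - level) / 2)
    lo = ndtr(z0 + (z0 - z) / (1 - a * (z0 - z)))
    hi = ndtr(z0 + (z0 + z) / (1 - a * (z0 + z)))
    return float(np.quantile(reps, lo)), float(np.quantile(reps, hi))


class TestPercentileInterval:
    def test_constant_replicates_collapse(self):
        assert percentile_interval([0.3] * 50, 0.95) == (0.3, 0.3)

    def test_order_statistic_oracle(self):
        reps = np.arange(1000) / 1000.0  # 0, .001, ..., .999
        lo, hi = percentile_interval(reps, 0.95)
        # linear-interpolation order statistics computed by hand:
        # h = 999*q -> 24.975 and 974.025
        assert lo == pytest.approx(0.024975, abs=1e-12)
        assert hi == pytest.approx(0.974025, abs=1e-12)

    def test_level_one_gives_min_max(self):
        reps = [0.2, 0.9, 0.4, 0.1]
        assert percentile_interval(reps, 1.0) == (0.1, 0.9)


class TestBCInterval:
    def test_symmetric_replicates_reduce_to_percentile(self):
        reps = np.linspace(0.1, 0.9, 100)
        theta = np.median(reps) + 1e-9  # exactly half below
        assert bc_interval(theta, reps, 0.95) == pytest.approx(
            percentile_interval(reps, 0.95), abs=1e-12
        )

    def test_all_replicates_at_theta_not_calculable(self):
        assert bc_interval(0.5, [0.5] * 20, 0.95) is None

    def test_hand_set_matches_straight_line_formula(self):
        reps = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        theta = 0.45  # 4 of 9 below
        got = bc_interval(theta, reps, 0.95)
        assert got == pytest.approx(efron_bc(theta, reps, 0.95), abs=1e-12)


class TestBCaInterval:
    def test_zero_bias_zero_acceleration_reduces_to_percentile(self):
        reps = np.linspace(0.0, 1.0, 200)
        theta = 0.5  # exactly half the replicates below: z0 = 0
        jack = np.array([0.4, 0.5, 0.6, 0.45, 0.55])  # symmetric: a = 0
        got = bca_interval(theta, reps, jack, 0.95)
        assert got == pytest.approx(percentile_interval(reps, 0.95), abs=1e-9)

    def test_constant_jackknife_not_calculable(self):
        reps = np.linspace(0, 1, 50)
        assert bca_interval(0.5, reps, [0.3] * 5, 0.95) is None

    def test_five_cluster_toy_matches_dual_implementation(self, rng):
        ds = simulate_continuous(
            SimulationSpec(n_centres=5, patients_per_surgeon=8, icc=0.3), rng
        )
        theta = anova_icc(ds).icc
        jack = jackknife_icc(ds)
        reps = rng.uniform(0.0, 0.8, 400)
        got = bca_interval(theta, reps, jack, 0.95)
        want = efron_bca(theta, reps, jack, 0.95)
        assert got == pytest.approx(want, abs=1e-12)

    def test_agrees_with_scipy_bca_on_same_replicates(self):
        # independent cross-check of the whole BCa pipeline against
        # scipy.stats.bootstrap with a shared resampling RNG
        from scipy.stats import bootstrap as scipy_bootstrap
        from surgicc.icc_anova import cluster_sufficient_stats, icc_from_sums

        ds = simulate_continuous(
            SimulationSpec(n_centres=15, patients_per_surgeon=12, icc=0.25),
            np.random.default_rng(5),
        )
        n_i, s_i, ss_i = cluster_sufficient_stats(ds.values, ds.cluster_labels)

        def stat(n, s, ss, axis=-1):
            return np.maximum(np.nan_to_num(icc_from_sums(n, s, ss, axis=axis)), 0)

        res = scipy_bootstrap(
            (n_i, s_i, ss_i), stat, paired=True, vectorized=True,
            n_resamples=20000, confidence_level=0.95, method="BCa",
            random_state=np.random.default_rng(0),
        )
        ci = bootstrap_icc_ci(ds, n_replicates=20000, method="bca", seed=0)
        assert ci.method_used == "bca"
        assert ci.lower == pytest.approx(res.confidence_interval.low, abs=5e-3)
        assert ci.upper == pytest.approx(res.confidence_interval.high, abs=5e-3)


class TestClusterResample:
    def test_singleton_clusters_conserve_size(self, rng):
        df = pd.DataFrame({"value": [1.0, 2.0, 3.0, 4.0], "centre": list("abcd")})
        ds = ClusteredDataset("x", "", "continuous", df, validate_on_init=False)
        out = cluster_resample(ds, rng)
        assert out.n == 4  # k draws of singleton clusters
        assert out.k == 4  # relabelled duplicates stay distinct

    def test_identical_clusters_leave_icc_unchanged(self, rng):
        df = pd.DataFrame(
            {"value": [0.0, 1.0] * 6, "centre": list("aabbccddeeff")}
        )
        ds = ClusteredDataset("x", "", "continuous", df)
        out = cluster_resample(ds, rng)
        assert anova_icc(out).raw_icc == pytest.approx(
            anova_icc(ds).raw_icc, abs=1e-12
        )

    def test_seeded_resamples_are_identical(self, nested_dataset):
        a = cluster_resample(nested_dataset, np.random.default_rng(3))
        b = cluster_resample(nested_dataset, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_nesting_survives_duplicate_centres(self, nested_dataset):
        out = cluster_resample(nested_dataset, np.random.default_rng(0))
        per_surgeon = out.data.groupby("surgeon")["centre"].nunique()
        assert (per_surgeon == 1).all()


class TestBootstrapICC:
    def test_degenerate_constant_data_percentile_fallback(self, constant_dataset):
        ci = bootstrap_icc_ci(constant_dataset, n_replicates=500, seed=0)
        assert ci.method_used == "percentile"
        assert (ci.lower, ci.upper) == (0.0, 0.0)

    def test_seeded_runs_are_bit_reproducible(self, nested_dataset):
        a = bootstrap_icc_ci(nested_dataset, n_replicates=300, seed=11)
        b = bootstrap_icc_ci(nested_dataset, n_replicates=300, seed=11)
        assert a == b

    def test_bounds_lie_in_unit_interval_and_are_ordered(self, rng):
        for icc in (0.0, 0.2, 0.45):
            ds = simulate_continuous(
                SimulationSpec(n_centres=12, patients_per_surgeon=10, icc=icc), rng
            )
            ci = bootstrap_icc_ci(ds, n_replicates=400, seed=7)
            assert 0.0 <= ci.lower <= ci.upper <= 1.0

    def test_interval_monotone_in_level(self, rng):
        ds = simulate_continuous(
            SimulationSpec(n_centres=15, patients_per_surgeon=10, icc=0.2), rng
        )
        ci90 = bootstrap_icc_ci(ds, n_replicates=800, level=0.90, seed=5)
        ci95 = bootstrap_icc_ci(ds, n_replicates=800, level=0.95, seed=5)
        assert ci95.lower <= ci90.lower
        assert ci90.upper <= ci95.upper

    def test_zero_clustering_small_k_lower_bound_censored_to_zero(self, rng):
        ds = simulate_continuous(
            SimulationSpec(n_centres=8, patients_per_surgeon=10, icc=0.0), rng
        )
        ci = bootstrap_icc_ci(ds, n_replicates=500, seed=2)
        assert ci.lower == 0.0

    def test_fast_path_equals_materialised_resamples(self, nested_dataset):
        # the sufficient-statistic shortcut must reproduce, replicate by
        # replicate, what estimating each materialised resample would give
        ds = nested_dataset.with_level("surgeon")
        fast = bootstrap_icc_ci(ds, n_replicates=100, seed=13, method="percentile")
        slow = bootstrap_icc_ci(
            ds,
            estimator=lambda d: anova_icc(d).icc,
            n_replicates=100,
            seed=13,
            method="percentile",
        )
        assert fast.lower == pytest.approx(slow.lower, abs=1e-12)
        assert fast.upper == pytest.approx(slow.upper, abs=1e-12)
        assert fast.replicates_summary == pytest.approx(
            slow.replicates_summary, abs=1e-12
        )
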