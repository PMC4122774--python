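import numpy as np
import pandas as pd
import pytest

from conftest import constant_profile
from snpsens.overall import (CoverageDistribution, breadth_requirement,
                             coverage_distribution, depth_requirement,
                             distribution_from_depths, overall_sensitivity,
                             subset_sensitivity)
from snpsens.regions_io import make_regions
from snpsens.simulate import CoverageModel, DepthProfile, simulate_coverage


def curve_of(mapping, counts=1000, d_cap=50):
    depth = np.arange(d_cap + 2)
    n = np.array([counts if d in mapping else 0 for d in depth])
    sens = np.array([mapping.get(d, np.nan) for d in depth], dtype=float)
    return pd.DataFrame({"depth": depth, "n_sites": n,
                         "n_correct": np.where(n > 0, (sens * n).round(), 0),
                         "sensitivity": sens, "overflow": depth > d_cap})


def full_curve(fn, d_cap=50, counts=1000):
    return curve_of({d: fn(d) for d in range(d_cap + 1)}, counts=counts, d_cap=d_cap)


class TestCoverageDistribution:
    def test_constant_depth(self):
        regions = make_regions(["chr1"], [0], [1000])
        dist = coverage_distribution(constant_profile(regions, 7), regions)
        assert dist.p[7] == 1.0
        assert dist.mean == 7.0
        assert dist.n_bases == 1000

    def test_half_zero_half_ten(self):
        depth = np.array([0] * 500 + [10] * 500)
        dist = distribution_from_depths(depth)
        assert dist.mean == 5.0
        assert dist.p[0] == dist.p[10] == 0.5

    def test_mean_computed_before_capping(self):
        depth = np.array([0, 200])
        dist = distribution_from_depths(depth, d_cap=50)
        assert dist.mean == 100.0
        assert dist.overflow == 0.5

    def test_matches_direct_tabulation(self):
        regions = make_regions(["chr1"], [0], [30_000])
        prof = simulate_coverage(regions, CoverageModel(mean_depth=12, dispersion=2, seed=9))
        dist = coverage_distribution(prof, regions, d_cap=50)
        depth = prof.df["depth"].to_numpy()
        for d in range(51):
            assert dist.p[d] == (depth == d).sum() / len(depth)
        assert dist.overflow == (depth > 50).sum() / len(depth)

    def test_empty_regions_rejected(self):
        regions = make_regions(["chr1"], [0], [100])
        with pytest.raises(ValueError, match="empty"):
            coverage_distribution(constant_profile(regions, 5), regions.iloc[:0])

    def test_histogram_mass_validated(self):
        with pytest.raises(ValueError, match="mass"):
            CoverageDistribution(p=np.array([0.5, 0.2]), overflow=0.0, mean=1.0, n_bases=10)


class TestOverallSensitivity:
    def test_perfect_curve_no_zero_mass(self):
        dist = distribution_from_depths(np.full(100, 10))
        assert overall_sensitivity(full_curve(lambda d: 1.0), dist) == 1.0

    def test_zero_depth_mass_is_pure_loss(self):
        depth = np.array([0] * 200 + [10] * 800)
        dist = distribution_from_depths(depth)
        assert overall_sensitivity(full_curve(lambda d: 1.0), dist) == pytest.approx(0.8)

    def test_hand_summation_oracle(self):
        # s(d)=min(1, d/10), P uniform on 0..20
        depth = np.repeat(np.arange(21), 10)
        dist = distribution_from_depths(depth)
        S = overall_sensitivity(full_curve(lambda d: min(1.0, d / 10)), dist)
        expected = sum(min(1.0, d / 10) for d in range(1, 21)) / 21  # s(0) forced 0
        assert S == pytest.approx(expected)

    def test_degenerate_distribution_returns_curve_value(self):
        curve = full_curve(lambda d: min(1.0, 0.2 + 0.05 * d))
        for d_star in (3, 17, 42):
            dist = distribution_from_depths(np.full(50, d_star))
            assert overall_sensitivity(curve, dist) == pytest.approx(
                min(1.0, 0.2 + 0.05 * d_star))

    def test_s_zero_forced_even_if_bin_zero_claims_success(self):
        curve = full_curve(lambda d: 1.0)  # including bin 0
        depth = np.array([0] * 50 + [10] * 50)
        dist = distribution_from_depths(depth)
        assert overall_sensitivity(curve, dist) == pytest.approx(0.5)

    def test_undefined_interior_bins_imputed_monotonically(self):
        curve = curve_of({1: 0.2, 10: 0.8, 20: 1.0})
        dist = distribution_from_depths(np.full(100, 5))
        S = overall_sensitivity(curve, dist)
        assert 0.2 <= S <= 0.8  # isotonic interpolation between neighbours

    def test_overflow_mass_uses_cap_sensitivity(self):
        curve = full_curve(lambda d: min(1.0, d / 25))
        depth = np.full(100, 500)  # all mass above the cap
        dist = distribution_from_depths(depth, d_cap=50)
        assert overall_sensitivity(curve, dist) == pytest.approx(1.0)

    def test_entirely_undefined_curve_rejected(self):
        curve = curve_of({})
        dist = distribution_from_depths(np.full(10, 5))
        with pytest.raises(ValueError, match="undefined"):
            overall_sensitivity(curve, dist)

    def test_monotone_under_stochastic_dominance(self):
        curve = full_curve(lambda d: min(1.0, d / 15))
        lo = distribution_from_depths(np.repeat([2, 5, 9], 100))
        hi = distribution_from_depths(np.repeat([4, 8, 14], 100))
        assert overall_sensitivity(curve, hi) > overall_sensitivity(curve, lo)


class TestDepthRequirement:
    def test_linear_midpoint(self):
        assert depth_requirement([(10, 0.90), (20, 0.98)], 0.94) == pytest.approx(15.0)

    def test_threshold_above_max_refused(self):
        assert depth_requirement([(10, 0.90), (20, 0.98)], 0.99) is None

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            depth_requirement([(10, 0.9)], 0.5)

    def test_isotonic_adjustment_of_noisy_ladder(self):
        points = [(10, 0.90), (15, 0.89), (20, 0.98)]  # small dip gets pooled
        req = depth_requirement(points, 0.94)
        assert 15 < req < 20

    def test_heterogeneous_cohort_needs_more_depth(self):
        """With an identical per-site curve, an overdispersed coverage field
        requires strictly greater mean on-target depth for the same overall
        sensitivity than a homogeneous one."""
        regions = make_regions(["chr1"], [0], [50_000])
        curve = full_curve(lambda d: min(1.0, d / 12))
        reqs = {}
        for name, k in [("hom", 1e6), ("het", 5.0)]:
            prof = simulate_coverage(regions, CoverageModel(mean_depth=40, dispersion=k, seed=21))
            points = []
            for i, p in enumerate(np.linspace(0.1, 1.0, 10)):
                from snpsens.simulate import downsample
                thinned = downsample(prof, round(float(p), 2), seed=100 + i)
                dist = distribution_from_depths(thinned.df["depth"].to_numpy())
                points.append((dist.mean, overall_sensitivity(curve, dist)))
            reqs[name] = depth_requirement(points, 0.95)
        assert reqs["het"] > reqs["hom"]


class TestBreadthRequirement:
    def test_constant_profiles_cross_exactly_at_threshold(self):
        regions = make_regions(["chr1"], [0], [1000])
        profiles = [constant_profile(regions, d) for d in (2, 6, 10, 14)]
        req = breadth_requirement(profiles, per_base_min=10, fraction_min=0.9)
        assert req == pytest.approx(10.0)

    def test_persistent_zero_fraction_never_crosses(self):
        regions = make_regions(["chr1"], [0], [1000])
        profiles = []
        for d in (5, 20, 50):
            df = constant_profile(regions, d).df
            df.loc[df.index[:200], "depth"] = 0  # 20% dead zone at every scale
            profiles.append(DepthProfile(df))
        assert breadth_requirement(profiles, 10, 0.9) is None


class TestSubsetSensitivity:
    def _setup(self):
        regions = make_regions(["chr1"], [0], [20_000])
        prof = simulate_coverage(regions, CoverageModel(mean_depth=15, dispersion=2, seed=33))
        curve = full_curve(lambda d: min(1.0, d / 12))
        return regions, prof, curve

    def test_full_target_subset_equals_overall(self):
        regions, prof, curve = self._setup()
        subset = prof.df[["chrom", "pos"]]
        S_sub = subset_sensitivity(subset, prof, curve)
        S_all = overall_sensitivity(curve, coverage_distribution(prof, regions))
        assert S_sub == pytest.approx(S_all)

    def test_random_subset_close_to_overall(self):
        regions, prof, curve = self._setup()
        rng = np.random.default_rng(3)
        idx = rng.choice(len(prof.df), 10_000, replace=False)
        S_sub = subset_sensitivity(prof.df.iloc[idx][["chrom", "pos"]], prof, curve)
        S_all = overall_sensitivity(curve, coverage_distribution(prof, regions))
        # binomial-ish sampling noise on a bounded statistic
        assert abs(S_sub - S_all) < 3 * 0.5 / np.sqrt(10_000)

    def test_zero_coverage_subset_is_zero(self):
        regions, prof, curve = self._setup()
        df = prof.df.copy()
        df.loc[df.index[:100], "depth"] = 0
        prof0 = DepthProfile(df)
        subset = df.iloc[:100][["chrom", "pos"]]
        assert subset_sensitivity(subset, prof0, curve) == 0.0

    def test_empty_subset_rejected(self):
        regions, prof, curve = self._setup()
        with pytest.raises(ValueError, match="empty"):
            subset_sensitivity(prof.df.iloc[:0][["chrom", "pos"]], prof, curve)
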