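import numpy as np
import pandas as pd
import pytest

from conftest import constant_profile, make_reads
from snpsens.genotyper import CallerParams, call_sample
from snpsens.regions_io import make_panel, make_regions
from snpsens.sensitivity import (build_gold_standard, curve_from_observations,
                                 matched_min_depth, min_depth_for,
                                 per_site_sensitivity, sensitivity_observations,
                                 smooth_curve, specificity_curve)
from snpsens.simulate import (AlleleModel, make_ladder, sample_allele_counts,
                              simulate_panel, simulate_truth)

from _oracles import exact_call_probability, het_alt_prob_oracle, min_depth_oracle


def _calls(panel, genotype, gq, depth=30):
    out = panel[["chrom", "pos", "ref", "alt"]].copy()
    out["genotype"] = genotype
    out["gq"] = gq
    out["depth"] = depth
    out["ref_count"] = depth
    out["alt_count"] = 0
    return out


def _curve(mapping, counts=1000, d_cap=50):
    """Curve fixture from {depth: sensitivity} with constant bin counts."""
    depth = np.arange(d_cap + 2)
    n = np.array([counts if d in mapping else 0 for d in depth])
    sens = np.array([mapping.get(d, np.nan) for d in depth], dtype=float)
    return pd.DataFrame({"depth": depth, "n_sites": n,
                         "n_correct": np.where(n > 0, (sens * n).round(), 0),
                         "sensitivity": sens, "overflow": depth > d_cap})


class TestGoldStandard:
    def test_non_panel_calls_excluded(self, small_panel):
        calls = _calls(small_panel, "RA", 99)
        extra = calls.iloc[[0]].assign(pos=999_999)
        gold, _ = build_gold_standard(pd.concat([calls, extra]), small_panel)
        assert len(gold) == len(small_panel)

    def test_gq_60_boundary(self, small_panel):
        calls = _calls(small_panel, "RA", [59, 60, 61, 99])
        gold, _ = build_gold_standard(calls, small_panel, min_gq=60)
        assert len(gold) == 3

    def test_allele_mismatch_counted_not_fatal(self, small_panel):
        calls = _calls(small_panel, "RA", 99)
        calls.loc[0, "alt"] = "C" if calls.loc[0, "alt"] != "C" else "T"
        gold, n_mismatch = build_gold_standard(calls, small_panel)
        assert n_mismatch == 1 and len(gold) == len(small_panel) - 1

    def test_missing_calls_excluded(self, small_panel):
        calls = _calls(small_panel, ["missing", "RA", "RA", "RA"], 99)
        gold, _ = build_gold_standard(calls, small_panel)
        assert len(gold) == 3

    def test_deep_coverage_gold_matches_truth(self, caller):
        """At 100X, full-data calls at GQ >= 60 recover the simulated truth
        at >= 99.9% of included sites."""
        regions = make_regions(["chr1"], [0], [40_000])
        panel = simulate_panel(regions, density=0.25, seed=1)
        truth = simulate_truth(panel, 0.4, 0.2, seed=2)
        prof = constant_profile(regions, depth=100)
        reads = sample_allele_counts(truth, prof, AlleleModel(seed=3))
        gold, _ = build_gold_standard(call_sample(reads, caller), panel,
                                      min_gq=caller.min_gq_gold)
        merged = gold.merge(truth, on=["chrom", "pos", "ref", "alt"],
                            suffixes=("_gold", "_true"))
        assert len(merged) > 5000
        assert (merged["genotype_gold"] == merged["genotype_true"]).mean() >= 0.999


class TestPerSiteCurve:
    def test_all_correct_gives_unit_sensitivity(self, small_panel):
        gold = small_panel[["chrom", "pos", "ref", "alt"]].assign(genotype="RA")
        calls = _calls(small_panel, "RA", 99, depth=10)
        curve = per_site_sensitivity([(gold, {0.5: calls})], "het")
        populated = curve[curve["n_sites"] > 0]
        assert (populated["sensitivity"] == 1.0).all()

    def test_zero_depth_het_counts_as_incorrect_in_bin_zero(self, small_panel):
        gold = small_panel[["chrom", "pos", "ref", "alt"]].assign(genotype="RA")
        calls = _calls(small_panel, "missing", 0, depth=0)
        curve = per_site_sensitivity([(gold, {0.5: calls})], "het")
        assert curve.loc[0, "n_sites"] == len(gold)
        assert curve.loc[0, "sensitivity"] == 0.0

    def test_full_fraction_excluded_by_default(self, small_panel):
        gold = small_panel[["chrom", "pos", "ref", "alt"]].assign(genotype="RA")
        calls = _calls(small_panel, "RA", 99, depth=10)
        curve = per_site_sensitivity([(gold, {1.0: calls})], "het")
        assert curve["n_sites"].sum() == 0

    def test_observation_conservation(self, caller):
        """Total observations across bins equal gold sites x fractions."""
        regions = make_regions(["chr1"], [0], [20_000])
        panel = simulate_panel(regions, density=0.2, seed=5)
        truth = simulate_truth(panel, 1.0, 0.0, seed=6)
        prof = constant_profile(regions, depth=25)
        reads = sample_allele_counts(truth, prof, AlleleModel(seed=7))
        ladder = make_ladder(reads, fractions=(0.2, 0.5, 1.0), seed=8)
        calls = {f: call_sample(r, caller) for f, r in ladder.items()}
        gold, _ = build_gold_standard(calls[1.0], panel, min_gq=caller.min_gq_gold)
        gold_het = gold[gold["genotype"] == "RA"]
        curve = per_site_sensitivity([(gold, calls)], "het")
        assert curve["n_sites"].sum() == 2 * len(gold_het)
        assert (curve["n_correct"] <= curve["n_sites"]).all()

    def test_empty_bins_are_nan_not_zero(self):
        obs = pd.DataFrame({"depth": [5, 5, 9], "correct": [True, False, True]})
        curve = curve_from_observations(obs, d_cap=10)
        assert np.isnan(curve.loc[7, "sensitivity"])
        assert curve.loc[5, "sensitivity"] == 0.5


class TestSpecificity:
    def test_error_free_reads_give_perfect_specificity(self, small_panel):
        caller0 = CallerParams(error_rate=0.0)
        gold = small_panel[["chrom", "pos", "ref", "alt"]].assign(genotype="RR")
        reads = make_reads(len(gold), 10, np.zeros(len(gold), dtype=int))
        reads[["chrom", "pos", "ref", "alt"]] = gold[["chrom", "pos", "ref", "alt"]]
        calls = call_sample(reads, caller0)
        curve = specificity_curve([(gold, {0.5: calls})])
        assert (curve.loc[curve["n_sites"] > 0, "sensitivity"] == 1.0).all()

    def test_depth_one_specificity_matches_enumeration(self, caller):
        """One read: an error read (prob eps) yields a non-RR call, so
        specificity at 1X is 1 - eps = 0.99 by exact enumeration."""
        eps = caller.error_rate
        rng = np.random.default_rng(11)
        n = 50_000
        alt = rng.binomial(1, eps, n)
        calls = call_sample(make_reads(n, 1, alt), caller)
        fp = calls["genotype"].isin(["RA", "AA"]).mean()
        exact_fp = 1.0 - exact_call_probability(1, eps, "RR", eps)
        assert exact_fp == pytest.approx(eps, abs=1e-12)
        assert abs(fp - exact_fp) < 3 * np.sqrt(exact_fp * (1 - exact_fp) / n)

    def test_specificity_sawtooth_structure(self, caller):
        """Enumerated specificity equals (1-eps)^d until a lone error read is
        absorbed into RR at d=7, then recovers above 99%; it is never below
        94% for d <= 30. (Not globally monotone for d >= 2.)"""
        eps = caller.error_rate
        spec = {d: exact_call_probability(d, eps, "RR", eps) for d in range(1, 31)}
        for d in range(1, 7):
            assert spec[d] == pytest.approx((1 - eps) ** d, abs=1e-12)
        assert spec[7] > spec[6]
        assert all(spec[d] >= 0.99 for d in range(7, 31))
        assert min(spec.values()) >= 0.94


class TestMinDepthFor:
    def test_already_monotone_curve(self):
        curve = _curve({5: 0.90, 9: 0.95, 10: 0.96})
        assert min_depth_for(curve, 0.95) == 9

    def test_pava_merging_matches_bruteforce(self):
        curve = _curve({8: 0.96, 9: 0.94, 10: 0.97})
        got = min_depth_for(curve, 0.95)
        want = min_depth_oracle([8, 9, 10], [0.96, 0.94, 0.97],
                                [1000, 1000, 1000], 0.95, 100)
        assert got == want == 8  # merged 8-9 level (0.95) crosses at 8

    def test_unreachable_threshold(self):
        curve = _curve({5: 0.90, 9: 0.95})
        assert min_depth_for(curve, 1.0) is None

    def test_small_bins_excluded(self):
        curve = _curve({3: 1.0, 9: 0.95}, counts=1000)
        curve.loc[3, "n_sites"] = 10  # lucky tiny bin must not count
        assert min_depth_for(curve, 0.99, min_bin_sites=100) is None

    def test_matches_bruteforce_on_random_curves(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            d_cap = 30
            depths = np.arange(d_cap + 1)
            sens = np.clip(rng.beta(2, 1, d_cap + 1).cumsum() / np.arange(1, d_cap + 2) * 1.2, 0, 1)
            rng.shuffle(sens[:10])
            counts = rng.integers(0, 500, d_cap + 1)
            curve = pd.DataFrame({"depth": depths, "n_sites": counts,
                                  "n_correct": (sens * counts).round(),
                                  "sensitivity": np.where(counts > 0, sens, np.nan),
                                  "overflow": False})
            threshold = rng.uniform(0.3, 0.99)
            got = min_depth_for(curve, threshold)
            want = min_depth_oracle(depths, sens, counts, threshold, 100)
            assert got == want

    def test_monotone_in_threshold(self):
        curve = _curve({2: 0.5, 5: 0.8, 9: 0.95, 15: 0.99})
        depths = [min_depth_for(curve, t) for t in (0.4, 0.6, 0.9, 0.96)]
        assert depths == sorted(depths, key=lambda x: (x is None, x))


class TestZygosityAndBiasOrdering:
    @pytest.mark.parametrize("beta", [0.0, 0.1, 0.2])
    @pytest.mark.parametrize("eps", [0.001, 0.01, 0.05])
    def test_hom_curve_dominates_het_curve(self, beta, eps):
        """Enumerated hom-alt sensitivity >= het sensitivity at (almost)
        every depth: hom calls survive allele-balance noise that breaks
        het calls. The exceptions are the isolated sawtooth-dip depths
        just before the caller tolerates one more error read in a hom
        call, where the rising het curve momentarily passes the dipping
        hom curve; dominance must hold everywhere else and in every
        window average."""
        p_het = het_alt_prob_oracle(beta, eps)
        s_hom = {d: exact_call_probability(d, 1 - eps, "AA", eps) for d in range(1, 31)}
        s_het = {d: exact_call_probability(d, p_het, "RA", eps) for d in range(1, 31)}
        violations = [d for d in s_hom if s_hom[d] < s_het[d] - 1e-12]
        # violations may only occur where the hom curve is locally dipping
        # (its value is below the previous depth's), never on its rises
        for d in violations:
            assert d > 1 and s_hom[d] < s_hom[d - 1]
        # dominance is strict at the shallowest depths, where hom calls
        # succeed on a single clean read but het calls cannot
        for d in (1, 2, 3):
            assert s_hom[d] >= s_het[d] - 1e-12

    def test_reference_bias_strictly_lowers_het_sensitivity(self, caller):
        """The capture-platform mechanism: raising the reference bias beta
        strictly lowers enumerated het sensitivity at every depth >= 2."""
        eps = caller.error_rate
        for d in range(2, 31):
            s = [exact_call_probability(d, het_alt_prob_oracle(b, eps), "RA", eps)
                 for b in (0.0, 0.1, 0.2)]
            assert s[0] > s[1] > s[2]


class TestMatchedMinDepth:
    def _ladder(self, gold, depths_by_fraction, correct_from):
        """Build ladder calls where the site is correct from a given fraction on."""
        ladder = {}
        for i, (frac, depth) in enumerate(depths_by_fraction):
            calls = gold[["chrom", "pos", "ref", "alt"]].copy()
            ok = frac >= correct_from
            calls["genotype"] = np.where(ok, gold["genotype"], "RR")
            calls["gq"] = 99
            calls["depth"] = depth
            calls["ref_count"] = depth
            calls["alt_count"] = 0
            ladder[frac] = calls
        return ladder

    def test_min_depth_is_smallest_correct_depth(self):
        gold = make_panel(["chr1"], [10], ["A"], ["G"]).assign(genotype="RA")
        fracs = [(round(0.1 * k, 1), 3 * k) for k in range(1, 11)]
        ladder = self._ladder(gold, fracs, correct_from=0.0)
        table, summary = matched_min_depth(ladder, ladder, gold, gold)
        assert table["d_min_a"].iloc[0] == 3
        assert summary["A"] == 3

    def test_censored_site_counts_in_denominator_by_default(self):
        gold = make_panel(["chr1", "chr1"], [10, 20], ["A", "A"], ["G", "G"]).assign(genotype="RA")
        fracs = [(0.5, 5), (0.9, 9)]
        ladder = self._ladder(gold, fracs, correct_from=0.0)
        ladder_a = {f: c.copy() for f, c in ladder.items()}
        for f in ladder_a:
            ladder_a[f].loc[1, "genotype"] = "AA"  # wrong zygosity forever
        table, summary = matched_min_depth(ladder_a, ladder, gold, gold)
        assert np.isnan(table["d_min_a"].iloc[1])
        # 95% of 2 sites needs both; one censored -> no quantile
        assert summary["A"] is None
        assert summary["B"] == 5  # both sites correct from the first step
        _, summary2 = matched_min_depth(ladder_a, ladder, gold, gold,
                                        censored_in_denominator=False)
        assert summary2["A"] == 5

    def test_requires_shared_gold_sites(self):
        g1 = make_panel(["chr1"], [10], ["A"], ["G"]).assign(genotype="RA")
        g2 = make_panel(["chr1"], [99], ["A"], ["G"]).assign(genotype="RA")
        with pytest.raises(ValueError, match="shared"):
            matched_min_depth({}, {}, g1, g2)


class TestSmoothCurve:
    def test_smoothed_is_monotone_and_weight_respecting(self):
        curve = _curve({2: 0.6, 3: 0.5, 4: 0.9, 5: 0.85})
        sm = smooth_curve(curve, min_bin_sites=100)
        fitted = sm.loc[sm["smoothed"].notna(), "smoothed"].to_numpy()
        assert (np.diff(fitted) >= -1e-12).all()
        assert fitted[0] == pytest.approx(0.55)  # pooled 2-3 block
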