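"""Region-set scoring: nested-stat and overlap-weighted aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cocoa import (
    GenomicInterval,
    RegionSet,
    RegionSetDatabase,
    SignalMatrix,
    compute_fcs,
    region_set_signal_average,
    run_cocoa,
    score_region_set_nucleotide,
    score_region_set_weighted,
)
from cocoa.variation import FeatureContributionScores

from conftest import random_intervals


def loci(*positions, chrom="chr1"):
    return [GenomicInterval(chrom, p, p + 1) for p in positions]


def oracle_nucleotide(fcs, coords, region_set, stat, use_abs):
    """Quadratic scan: enumerate every (locus, region) pair directly."""
    f = np.abs(fcs) if use_abs else np.asarray(fcs, float)
    agg = np.mean if stat == "mean" else np.median
    region_vals = []
    covered = 0
    features = set()
    for region in region_set.regions:
        vals = []
        for i, c in enumerate(coords):
            if c.chrom == region.chrom and max(c.start, region.start) < min(
                c.end, region.end
            ):
                features.add(i)
                if np.isfinite(f[i]):
                    vals.append(f[i])
        if vals:
            region_vals.append(agg(vals))
        # a region counts as covered when any data locus overlaps it,
        # even if that locus's FCS is missing
        if any(
            c.chrom == region.chrom
            and max(c.start, region.start) < min(c.end, region.end)
            for c in coords
        ):
            covered += 1
    score = agg(region_vals) if region_vals else np.nan
    return score, covered, len(features)


def oracle_weighted(fcs, coords, region_set, use_abs):
    f = np.abs(fcs) if use_abs else np.asarray(fcs, float)
    num = den = 0.0
    covered_regions = set()
    features = set()
    for j, region in enumerate(region_set.regions):
        for i, c in enumerate(coords):
            if c.chrom != region.chrom:
                continue
            ov = min(c.end, region.end) - max(c.start, region.start)
            if ov <= 0:
                continue
            covered_regions.add(j)
            features.add(i)
            if np.isfinite(f[i]):
                w = ov / region.width
                num += w * f[i]
                den += w
    score = num / den if den > 0 else np.nan
    return score, len(covered_regions), len(features)


class TestNucleotideScorer:
    def test_nested_mean_by_hand(self):
        coords = loci(5, 8, 25)
        fcs = np.array([0.2, 0.4, 0.6])
        rs = RegionSet(
            "rs", [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        )
        score, ncov, nfeat = score_region_set_nucleotide(fcs, coords, rs, "mean", False)
        assert score == pytest.approx(0.45)  # mean of region means 0.3, 0.6
        assert (ncov, nfeat) == (2, 3)

    def test_abs_applied_before_averaging(self):
        coords = loci(5, 8, 25)
        fcs = np.array([-0.2, 0.4, 0.6])
        rs = RegionSet(
            "rs", [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        )
        score, _, _ = score_region_set_nucleotide(fcs, coords, rs, "mean", True)
        assert score == pytest.approx(0.45)

    def test_uncovered_set_scores_missing(self):
        score, ncov, nfeat = score_region_set_nucleotide(
            np.array([0.5]), loci(5), RegionSet("rs", [GenomicInterval("chr2", 0, 10)]),
        )
        assert np.isnan(score) and ncov == 0 and nfeat == 0

    def test_locus_in_two_regions_contributes_to_both(self):
        coords = loci(5)
        rs = RegionSet(
            "rs", [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 3, 8)]
        )
        score, ncov, nfeat = score_region_set_nucleotide(
            np.array([0.7]), coords, rs, "mean", False
        )
        assert score == pytest.approx(0.7)
        assert ncov == 2 and nfeat == 1  # counted once as a feature

    @pytest.mark.parametrize("stat", ["mean", "median"])
    @pytest.mark.parametrize("use_abs", [True, False])
    def test_random_instances_match_quadratic_oracle(self, rng, stat, use_abs):
        for _ in range(20):
            coords = loci(*rng.choice(2000, size=50, replace=False))
            fcs = rng.normal(size=50)
            fcs[rng.random(50) < 0.1] = np.nan
            rs = RegionSet("rs", random_intervals(rng, 15, max_coord=2000, max_width=200))
            got = score_region_set_nucleotide(fcs, coords, rs, stat, use_abs)
            exp = oracle_nucleotide(fcs, coords, rs, stat, use_abs)
            np.testing.assert_allclose(got[0], exp[0], atol=1e-10)
            assert got[1:] == exp[1:]


class TestWeightedScorer:
    def test_formula_by_hand(self):
        # data region covering 100% of r1 (FCS 0.5), another covering 50%
        # of r2 (FCS 1.0) -> (0.5*1 + 1.0*0.5)/(1 + 0.5) = 2/3
        coords = [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 200, 250),
        ]
        rs = RegionSet(
            "rs",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 150, 250)],
        )
        score, ncov, nfeat = score_region_set_weighted(
            np.array([0.5, 1.0]), coords, rs, use_abs=False
        )
        assert score == pytest.approx(2 / 3)
        assert (ncov, nfeat) == (2, 2)

    def test_identity_case(self):
        iv = GenomicInterval("chr1", 10, 60)
        score, _, _ = score_region_set_weighted(
            np.array([0.8]), [iv], RegionSet("rs", [iv]), use_abs=False
        )
        assert score == pytest.approx(0.8)

    @pytest.mark.parametrize("use_abs", [True, False])
    def test_random_instances_match_quadratic_oracle(self, rng, use_abs):
        for _ in range(20):
            coords = random_intervals(rng, 30, max_coord=3000, max_width=150)
            fcs = rng.normal(size=30)
            fcs[rng.random(30) < 0.1] = np.nan
            rs = RegionSet("rs", random_intervals(rng, 15, max_coord=3000, max_width=300))
            got = score_region_set_weighted(fcs, coords, rs, use_abs)
            exp = oracle_weighted(fcs, coords, rs, use_abs)
            np.testing.assert_allclose(got[0], exp[0], atol=1e-10)
            assert got[1:] == exp[1:]


class TestScoringInvariants:
    def test_scores_within_fcs_hull(self, rng):
        """Both scorers are nested convex combinations of the FCS values."""
        coords = loci(*rng.choice(1000, size=40, replace=False))
        data_regions = random_intervals(rng, 40, max_coord=1000, max_width=60)
        fcs = rng.normal(size=40)
        rs = RegionSet("rs", random_intervals(rng, 10, max_coord=1000))
        for use_abs in (True, False):
            f = np.abs(fcs) if use_abs else fcs
            s, ncov, _ = score_region_set_nucleotide(fcs, coords, rs, "mean", use_abs)
            if ncov:
                assert f.min() - 1e-12 <= s <= f.max() + 1e-12
            sw, ncovw, _ = score_region_set_weighted(fcs, data_regions, rs, use_abs)
            if ncovw:
                assert f.min() - 1e-12 <= sw <= f.max() + 1e-12

    def test_one_locus_per_region_reduces_to_plain_stat(self):
        coords = loci(5, 105, 205)
        fcs = np.array([0.1, 0.5, 0.9])
        rs = RegionSet(
            "rs", [GenomicInterval("chr1", s, s + 10) for s in (0, 100, 200)]
        )
        for stat, expected in (("mean", 0.5), ("median", 0.5)):
            s, _, _ = score_region_set_nucleotide(fcs, coords, rs, stat, False)
            assert s == pytest.approx(expected)

    def test_equal_weights_reduce_to_plain_mean(self):
        # all data regions cover the same fraction of equal-width set regions
        coords = [GenomicInterval("chr1", s, s + 50) for s in (0, 100, 200)]
        rs = RegionSet(
            "rs", [GenomicInterval("chr1", s, s + 100) for s in (0, 100, 200)]
        )
        fcs = np.array([0.2, 0.3, 0.7])
        s, _, _ = score_region_set_weighted(fcs, coords, rs, use_abs=False)
        assert s == pytest.approx(fcs.mean())

    def test_storage_order_invariance(self, rng):
        coords = loci(*rng.choice(1000, size=30, replace=False))
        fcs = rng.normal(size=30)
        regions = random_intervals(rng, 12, max_coord=1000)
        perm = rng.permutation(30)
        rperm = rng.permutation(12)
        a = score_region_set_nucleotide(fcs, coords, RegionSet("rs", regions), "mean", True)
        b = score_region_set_nucleotide(
            fcs[perm],
            [coords[i] for i in perm],
            RegionSet("rs", [regions[i] for i in rperm]),
            "mean",
            True,
        )
        assert a[0] == pytest.approx(b[0], abs=1e-12)
        assert a[1:] == b[1:]


class TestRunCocoa:
    def make_inputs(self):
        coords = loci(5, 15, 25)
        fcs = FeatureContributionScores(
            np.array([[0.2], [0.4], [0.9]]), ["t"], "covariance"
        )
        sets = [
            RegionSet("covers_all", [GenomicInterval("chr1", 0, 30)]),
            RegionSet("covers_last", [GenomicInterval("chr1", 20, 30)]),
            RegionSet("uncovered", [GenomicInterval("chr2", 0, 30)]),
        ]
        return fcs, coords, RegionSetDatabase(sets=sets)

    def test_filter_drops_uncovered_sets(self):
        fcs, coords, db = self.make_inputs()
        res = run_cocoa(fcs, coords, db, "nucleotide", min_covered_regions=1)
        assert set(res["region_set"]) == {"covers_all", "covers_last"}
        assert list(res.sort_values("rank")["rank"]) == [1, 2]

    def test_all_filtered_returns_empty(self):
        fcs, coords, db = self.make_inputs()
        res = run_cocoa(fcs, coords, db, "nucleotide", min_covered_regions=5)
        assert len(res) == 0

    def test_constant_fcs_gives_constant_scores(self):
        coords = loci(5, 15, 25)
        fcs = FeatureContributionScores(
            np.full((3, 1), -0.3), ["t"], "covariance"
        )
        db = RegionSetDatabase(
            sets=[
                RegionSet("a", [GenomicInterval("chr1", 0, 30)]),
                RegionSet("b", [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]),
            ]
        )
        res = run_cocoa(fcs, coords, db, "nucleotide", use_abs=True, min_covered_regions=1)
        np.testing.assert_allclose(res["score"], 0.3)
        signed = run_cocoa(fcs, coords, db, "nucleotide", use_abs=False, min_covered_regions=1)
        np.testing.assert_allclose(signed["score"], -0.3)

    def test_planted_set_ranks_first(self, small_planted):
        signal, targets, planted, db = small_planted
        fcs = compute_fcs(signal, targets, "covariance")
        res = run_cocoa(
            fcs, signal.coords, db, "nucleotide", min_covered_regions=1
        )
        top = res[res["rank"] == 1]
        assert list(top["region_set"]) == [planted.name]

    def test_mean_median_rankings_strongly_correlated(self, small_planted):
        """Rankings under mean and median scoring agree when set scores are
        driven by signal rather than sampling noise: sets mixing k planted
        regions with 30-k decoy regions grade smoothly in true effect."""
        signal, targets, planted, db = small_planted
        decoy_regions = db["decoy_0"].regions if "decoy_0" in db.names else db.sets[1].regions
        graded = RegionSetDatabase(
            sets=[
                RegionSet(
                    f"mix_{k:02d}",
                    planted.regions[:k] + decoy_regions[k:30],
                )
                for k in range(31)
            ]
        )
        fcs = compute_fcs(signal, targets, "covariance")
        mean_res = run_cocoa(fcs, signal.coords, graded, "nucleotide", stat="mean",
                             min_covered_regions=1)
        med_res = run_cocoa(fcs, signal.coords, graded, "nucleotide", stat="median",
                            min_covered_regions=1)
        merged = mean_res.merge(
            med_res, on=["region_set", "target"], suffixes=("_mean", "_median")
        )
        rho = spearmanr(merged["score_mean"], merged["score_median"]).statistic
        assert rho > 0.9


class TestRegionSetSignalAverage:
    def test_single_region_mean(self):
        signal = SignalMatrix(
            loci(2, 6),
            np.array([[0.2], [0.6]]),
            ["s"],
            "nucleotide",
        )
        rs = RegionSet("rs", [GenomicInterval("chr1", 0, 10)])
        np.testing.assert_allclose(region_set_signal_average(signal, rs), [0.4])

    def test_regions_weighted_equally(self):
        # region 1 has 3 loci (mean 0.4), region 2 has 1 locus (0.8):
        # the answer is 0.6, not the pooled locus mean
        signal = SignalMatrix(
            loci(1, 2, 3, 25),
            np.array([[0.3], [0.4], [0.5], [0.8]]),
            ["s"],
            "nucleotide",
        )
        rs = RegionSet(
            "rs", [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        )
        np.testing.assert_allclose(region_set_signal_average(signal, rs), [0.6])

    def test_no_overlap_gives_all_missing(self):
        signal = SignalMatrix(loci(5), np.array([[0.5]]), ["s"], "nucleotide")
        rs = RegionSet("rs", [GenomicInterval("chrX", 0, 10)])
        assert np.isnan(region_set_signal_average(signal, rs)).all()

    def test_matches_nested_mean_oracle(self, rng):
        n = 40
        positions = rng.choice(2000, size=n, replace=False)
        values = rng.random((n, 3))
        values[rng.random((n, 3)) < 0.1] = np.nan
        signal = SignalMatrix(loci(*positions), values, ["a", "b", "c"], "nucleotide")
        regions = random_intervals(rng, 10, max_coord=2000, max_width=300)
        rs = RegionSet("rs", regions)
        got = region_set_signal_average(signal, rs)
        for s in range(3):
            region_means = []
            for region in regions:
                vals = [
                    values[i, s]
                    for i, c in enumerate(signal.coords)
                    if c.chrom == region.chrom
                    and max(c.start, region.start) < min(c.end, region.end)
                    and np.isfinite(values[i, s])
                ]
                if vals:
                    region_means.append(np.mean(vals))
            expected = np.mean(region_means) if region_means else np.nan
            np.testing.assert_allclose(got[s], expected, atol=1e-10)
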