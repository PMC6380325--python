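"""Region assignment, length-proportional chi-square, permutation nulls."""

import numpy as np
import pytest
from scipy import stats

from phsdup.annotation import (
    GenomeAnnotation,
    age_group_trend,
    assign_regions,
    homolog_fraction_permutation,
    permutation_enrichment,
    region_chi_square,
    sign_test_ratios,
)


@pytest.fixture
def annotation():
    # one 100-kb chromosome: transcript A at [10k, 20k), transcript B overlapping
    return GenomeAnnotation(
        chrom_lengths={"ref": 100_000},
        regions={
            "CDS": {"ref": [(12_000, 15_000), (16_000, 18_000)]},
            "five_prime_UTR": {"ref": [(10_000, 12_000)]},
            "three_prime_UTR": {"ref": [(18_000, 20_000)]},
            "intron": {"ref": [(15_000, 16_000), (13_000, 14_000)]},
        },
    )


class TestAssignRegions:
    def test_priority_and_partition(self, annotation):
        sites = [
            ("ref", 12_500),  # CDS
            ("ref", 13_500),  # CDS of one transcript, intron of another -> CDS
            ("ref", 15_500),  # intron
            ("ref", 11_000),  # 5'UTR
            ("ref", 19_000),  # 3'UTR
            ("ref", 50_000),  # intergenic
        ]
        labels, counts = assign_regions(sites, annotation)
        assert labels == [
            "CDS", "CDS", "intron", "five_prime_UTR", "three_prime_UTR", "intergenic"
        ]
        assert sum(counts.values()) == len(sites)

    def test_out_of_bounds_site_rejected(self, annotation):
        with pytest.raises(ValueError):
            assign_regions([("ref", 200_000)], annotation)

    def test_region_lengths_resolve_overlaps_by_priority(self, annotation):
        lengths = annotation.region_lengths()
        assert lengths["CDS"] == 5000
        assert lengths["intron"] == 1000  # the (13k,14k) part is CDS-owned
        assert sum(lengths.values()) == 100_000


class TestRegionChiSquare:
    def test_proportional_counts_give_unity_p(self):
        lengths = {"CDS": 2000, "intron": 3000, "intergenic": 5000}
        counts = {"CDS": 20, "intron": 30, "intergenic": 50}
        results = region_chi_square(counts, lengths)
        assert all(r["p"] == pytest.approx(1.0) for r in results.values())

    def test_concentrated_counts_match_hand_computed_statistic(self):
        # all 100 sites in a region covering 10% of the genome:
        # chi2 = (100-10)^2/10 + (0-90)^2/90 = 810 + 90 = 900
        lengths = {"small": 10_000, "rest": 90_000}
        counts = {"small": 100, "rest": 0}
        results = region_chi_square(counts, lengths)
        assert results["small"]["chi2"] == pytest.approx(900.0)

    def test_uniform_random_sites_reject_at_nominal_rate(self, rng):
        lengths = {"a": 30_000, "b": 70_000}
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            hits = int(rng.binomial(200, 0.3))
            results = region_chi_square({"a": hits, "b": 200 - hits}, lengths)
            rejections += results["a"]["p"] < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_zero_length_region_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            results = region_chi_square({"a": 5, "b": 5}, {"a": 1000, "b": 0})
        assert "b" not in results


class TestPermutationEnrichment:
    def test_full_coverage_track_gives_ratio_one(self, rng):
        calls = [(100, 300), (5_000, 5_400)]
        res = permutation_enrichment(
            calls, [(0, 100_000)], 100_000, n_permutations=200, rng=rng
        )
        assert res.observed == len(calls)
        assert res.ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_empty_track_is_degenerate(self, rng):
        res = permutation_enrichment(
            [(100, 300)], [], 100_000, n_permutations=200, rng=rng
        )
        assert res.observed == 0 and res.ratio == 0.0 and res.p == 1.0

    def test_planted_depletion_detected(self):
        # track covers [0, 50k); calls placed exclusively in [50k, 100k)
        rng = np.random.default_rng(99)
        calls = [(60_000 + 400 * i, 60_200 + 400 * i) for i in range(40)]
        res = permutation_enrichment(
            calls, [(0, 50_000)], 100_000, n_permutations=999, rng=rng,
            alternative="less",
        )
        assert res.observed == 0
        assert res.p == pytest.approx(1 / 1000, abs=2e-3)

    def test_seed_reproducible_and_order_invariant(self):
        track = [(10_000, 12_000), (40_000, 45_000), (70_000, 70_500)]
        calls = [(500, 700), (41_000, 41_200), (90_000, 90_300)]
        res1 = permutation_enrichment(
            calls, track, 100_000, n_permutations=300,
            rng=np.random.default_rng(5),
        )
        res2 = permutation_enrichment(
            calls, track[::-1], 100_000, n_permutations=300,
            rng=np.random.default_rng(5),
        )
        assert res1.p == res2.p
        assert np.array_equal(res1.null, res2.null)

    def test_empirical_p_bounds(self, rng):
        for _ in range(20):
            calls = [(int(s), int(s) + 100) for s in rng.integers(0, 99_000, 5)]
            res = permutation_enrichment(
                calls, [(0, 30_000)], 100_000, n_permutations=99, rng=rng
            )
            assert 1 / 100 <= res.p <= 1.0


class TestHomologFraction:
    def test_constant_status_gives_unity_p(self, rng):
        res = homolog_fraction_permutation(
            [(100, 500), (9_000, 9_400)],
            lambda s, e: True,
            100_000,
            n_permutations=200,
            rng=rng,
        )
        assert res.p == pytest.approx(1.0)

    def test_minimal_p_is_resampling_floor(self):
        # status true only beyond 90k where all calls sit: 1/(N+1) floor
        rng = np.random.default_rng(3)
        calls = [(95_000 + 10 * i, 95_400 + 10 * i) for i in range(30)]
        res = homolog_fraction_permutation(
            calls,
            lambda s, e: s >= 90_000,
            100_000,
            fragment_length=400,
            n_permutations=1000,
            rng=rng,
        )
        assert res.p == pytest.approx(1 / 1001, abs=1e-6)


class TestAgeGroupTrend:
    def test_all_unity_ratios_are_null(self, rng):
        # track covers everything: every group overlaps fully, all ratios 1
        groups = {
            "young": [(1000 * i, 1000 * i + 200) for i in range(1, 7)],
            "old": [(2000 * i, 2000 * i + 200) for i in range(1, 7)],
            "nonsingleton": [(3000 * i, 3000 * i + 200) for i in range(1, 7)],
        }
        tracks = {f"t{k}": [(0, 100_000)] for k in range(6)}
        out = age_group_trend(groups, tracks, 100_000, n_permutations=100, rng=rng)
        for g in groups:
            assert out["sign_tests"][g]["p_two_sided"] == pytest.approx(1.0)
        assert out["friedman"]["p"] == pytest.approx(1.0)

    def test_sign_test_closed_form_for_consistent_depletion(self):
        result = sign_test_ratios([0.5] * 8)
        assert result["p_one_sided"] == pytest.approx(2.0**-8)

    def test_planted_depletion_gradient_recovered(self):
        # older groups avoid an active region more strongly; the element
        # tracks are subsets of that region, so depletion must deepen with
        # age and the Friedman test must separate the groups
        rng = np.random.default_rng(12)
        L = 200_000
        active = [(2000 * i, 2000 * i + 1000) for i in range(30)]  # 30 kb total
        tracks = {
            f"t{t}": [iv for i, iv in enumerate(active) if (i + t) % 3 != 0]
            for t in range(6)
        }

        def place(n, avoid_prob):
            calls = []
            while len(calls) < n:
                s = int(rng.integers(0, L - 200))
                inside = any(a < s + 200 and s < b for a, b in active)
                if inside and rng.random() < avoid_prob:
                    continue
                calls.append((s, s + 200))
            return calls

        groups = {
            "young": place(80, 0.3),
            "old": place(80, 0.7),
            "nonsingleton": place(80, 0.95),
        }
        out = age_group_trend(groups, tracks, L, n_permutations=300, rng=rng)
        assert out["friedman"]["p"] < 0.05
        medians = {g: np.median(out["ratios"][g]) for g in groups}
        assert medians["young"] > medians["old"] > medians["nonsingleton"]
        assert out["sign_tests"]["nonsingleton"]["p_one_sided"] < 0.05
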