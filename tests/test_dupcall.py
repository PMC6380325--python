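"""Merging linked PHS, exclusion, classification and population collation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phsdup.detect import HighCopyRegion, TandemDuplication
from phsdup.dupcall import (
    apply_exclusions,
    classify_duplications,
    collate_population,
    merge_phs,
    merge_phs_population,
    size_class_fractions,
)
from phsdup.phs import PHSRecord
from tests._oracles import gap_partition


def _phs(pos, genome_id=0, chrom="ref"):
    return PHSRecord(chrom, pos, genome_id, "A", "G", 6, 6, 14)


class TestMerge:
    def test_gap_rule_splits_at_401(self):
        calls = merge_phs([_phs(1000), _phs(1350), _phs(1800)], gap=400)
        assert [c.phs_positions for c in calls] == [(1000, 1350), (1800,)]

    def test_single_phs_is_singleton_call_of_length_one(self):
        (call,) = merge_phs([_phs(500)])
        assert call.phs_count == 1
        assert call.length == 1
        assert (call.start, call.end) == (499, 500)

    def test_matches_bruteforce_partition_oracle(self, rng):
        positions = sorted(int(p) for p in rng.choice(10**6, size=10_000, replace=False))
        calls = merge_phs([_phs(p) for p in positions], gap=400)
        expected = gap_partition(positions, 400)
        assert [list(c.phs_positions) for c in calls] == expected

    def test_call_count_non_increasing_in_gap(self, rng):
        positions = sorted(int(p) for p in rng.choice(200_000, size=800, replace=False))
        records = [_phs(p) for p in positions]
        counts = [len(merge_phs(records, gap=g)) for g in (100, 200, 300, 400, 500, 600)]
        assert counts == sorted(counts, reverse=True)

    def test_partition_is_exhaustive(self, rng):
        positions = sorted(int(p) for p in rng.choice(50_000, size=300, replace=False))
        calls = merge_phs([_phs(p) for p in positions])
        assert sum(c.phs_count for c in calls) == len(positions)
        covered = sorted(p for c in calls for p in c.phs_positions)
        assert covered == positions

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        positions=st.sets(st.integers(min_value=1, max_value=100_000),
                          min_size=1, max_size=120),
        gap=st.integers(min_value=1, max_value=2000),
    )
    def test_partition_properties_hold_for_any_input(self, positions, gap):
        records = [_phs(p) for p in sorted(positions)]
        calls = merge_phs(records, gap=gap)
        # exhaustive partition matching the brute-force oracle
        assert [list(c.phs_positions) for c in calls] == gap_partition(
            sorted(positions), gap
        )
        assert sum(c.phs_count for c in calls) == len(positions)
        # within a call consecutive PHS are <= gap apart; across calls > gap
        for call in calls:
            assert all(
                b - a <= gap
                for a, b in zip(call.phs_positions, call.phs_positions[1:])
            )
        for a, b in zip(calls, calls[1:]):
            assert b.phs_positions[0] - a.phs_positions[-1] > gap

    def test_mixed_genomes_rejected(self):
        with pytest.raises(ValueError):
            merge_phs([_phs(10, genome_id=0), _phs(20, genome_id=1)])

    def test_population_merge_separates_genomes(self):
        records = [_phs(100, 0), _phs(150, 1), _phs(200, 0)]
        calls = merge_phs_population(records)
        assert len(calls) == 2
        assert {c.genome_id for c in calls} == {0, 1}


class TestExclusions:
    def test_call_inside_excluded_region_removed(self):
        calls = merge_phs([_phs(1000), _phs(5000)])
        kept, removed, _ = apply_exclusions(calls, [("ref", 900, 1100)])
        assert [c.phs_positions for c in kept] == [(5000,)]
        assert [c.phs_positions for c in removed] == [(1000,)]

    def test_empty_exclusion_list_is_identity(self):
        calls = merge_phs([_phs(1000), _phs(5000)])
        kept, removed, flagged = apply_exclusions(calls, [])
        assert kept == calls and removed == [] and flagged == []

    def test_large_span_flagged_at_28kb(self):
        positions = list(range(1000, 31_400, 300))  # one 30-kb chained cluster
        calls = merge_phs([_phs(p) for p in positions])
        assert len(calls) == 1
        _, _, flagged = apply_exclusions(calls)
        assert flagged == calls


class TestClassification:
    def _call(self, start, end, positions=None, genome_id=0):
        from phsdup.dupcall import PHSDuplication

        return PHSDuplication(
            chrom="ref",
            start=start,
            end=end,
            genome_id=genome_id,
            phs_positions=tuple(positions or (start + 1, end)),
        )

    def test_three_quarters_overlap_is_high_copy(self):
        call = self._call(1000, 1400)
        hc = [HighCopyRegion("ref", 1100, 1600, 2.5, 2.0)]
        (out,) = classify_duplications([call], hc, [])
        assert out.dup_class == "high_copy"

    def test_exactly_half_overlap_is_not_high_copy(self):
        call = self._call(1000, 1400)
        hc = [HighCopyRegion("ref", 1200, 1400, 2.5, 2.0)]  # exactly 200/400
        (out,) = classify_duplications([call], hc, [])
        assert out.dup_class == "undetermined"

    def test_both_evidence_types_give_class_both(self):
        call = self._call(1000, 1400)
        hc = [HighCopyRegion("ref", 1000, 1400, 2.5, 2.0)]
        td = [TandemDuplication("ref", 900, 1500, 0, 36)]
        (out,) = classify_duplications([call], hc, td)
        assert out.dup_class == "both"

    def test_classification_stable_under_translation(self):
        shift = 10_000
        call_a = self._call(1000, 1400)
        call_b = self._call(1000 + shift, 1400 + shift)
        hc_a = [HighCopyRegion("ref", 1100, 1600, 2.5, 2.0)]
        hc_b = [HighCopyRegion("ref", 1100 + shift, 1600 + shift, 2.5, 2.0)]
        (out_a,) = classify_duplications([call_a], hc_a, [])
        (out_b,) = classify_duplications([call_b], hc_b, [])
        assert out_a.dup_class == out_b.dup_class


class TestCollation:
    def test_shared_positions_union_into_one_event(self):
        calls = merge_phs_population([_phs(100, 0), _phs(100, 1), _phs(400, 1)])
        catalog = collate_population(calls)
        assert catalog.n_events == 1
        assert set(catalog.events.values()) == {frozenset({0, 1})}
        assert all(c.frequency == 2 for c in catalog.calls)

    def test_disjoint_calls_stay_distinct_singletons(self):
        calls = merge_phs_population([_phs(100, 0), _phs(5000, 1)])
        catalog = collate_population(calls)
        assert catalog.n_events == 2
        assert all(len(c) == 1 for c in catalog.events.values())

    def test_overlap_identity_flag_merges_overlapping_spans(self):
        calls = merge_phs_population([_phs(100, 0), _phs(300, 0), _phs(200, 1)])
        by_pos = collate_population(calls, by="position")
        by_ov = collate_population(calls, by="overlap")
        assert by_pos.n_events == 2  # no shared position
        assert by_ov.n_events == 1  # spans overlap

    def test_sfs_counts_match_event_frequencies(self):
        calls = merge_phs_population(
            [_phs(100, 0), _phs(100, 1), _phs(100, 2), _phs(9000, 3)]
        )
        catalog = collate_population(calls)
        assert catalog.sfs_counts(4) == [1, 0, 1]

    def test_size_class_fractions(self):
        calls = merge_phs_population(
            [_phs(100, 0)]  # lone PHS: length 1
            + [_phs(10_000, 1), _phs(10_400, 1), _phs(10_800, 1)]  # chained: 801 bp
            + [_phs(50_000, 2), _phs(51_500, 2)]  # 1500 bp apart: two length-1 calls
        )
        fractions = size_class_fractions(calls)
        assert fractions["lt_500"] == pytest.approx(3 / 4)
        assert fractions["500_to_1k"] == pytest.approx(1 / 4)
        assert fractions["gt_1k"] == 0.0
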