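"""Paralog reconstruction and NG86 dN/dS counting."""

import warnings

import numpy as np
import pytest

from phsdup.dupcall import PHSDuplication
from phsdup.paralogs import (
    HomologyHit,
    ParalogPair,
    compare_paralog_ortholog,
    dn_ds,
    filter_homology_hits,
    ng86,
    reconstruct_paralogs,
)
from phsdup.phs import PHSRecord
from tests._oracles import ng86_bruteforce

# 30-codon pair with scattered single-base differences; dN/dS frozen from
# the independent path-enumeration oracle computed before wiring this test.
FIXTURE_A = (
    "ACCGTTGCTCGGCGGTCGACCGGGATAACCGAATTGGTAGTGGGTGTTCTTACTTCCCGTCTGCCGAGT"
    "TGTGTTGCTCGATCAGACCGT"
)
FIXTURE_B = (
    "GCCGTGGCTCGGTGGTCGACCGCGAAAACCGAATTGGTGGTGGATGTTCGTACTTCCCGTCTTCCGAGA"
    "TGTGTAGCGCGATCAGACCGT"
)
FIXTURE_DN = 0.11991291139482743
FIXTURE_DS = 0.21421036454079145


def _call(start, end, positions):
    return PHSDuplication(
        chrom="ref", start=start, end=end, genome_id=0, phs_positions=tuple(positions)
    )


def _phs(pos, a1="A", a2="G"):
    return PHSRecord("ref", pos, 0, a1, a2, 6, 6, 14)


class TestReconstruct:
    REF = "ACGTACGTACGTACGTACGTACGTACGTACGT"

    def test_no_internal_phs_gives_identical_copies(self):
        pair = reconstruct_paralogs(_call(4, 20, (5, 20)), [], self.REF)
        assert pair.copy_a == pair.copy_b == self.REF[4:20]

    def test_copies_differ_exactly_at_phs(self):
        records = [_phs(6, "C", "T"), _phs(10, "A", "G"), _phs(15, "G", "C")]
        pair = reconstruct_paralogs(_call(4, 20, (6, 10, 15)), records, self.REF)
        diffs = [i for i, (a, b) in enumerate(zip(pair.copy_a, pair.copy_b)) if a != b]
        assert diffs == [1, 5, 10]  # offsets of pos-1 within the span

    def test_hamming_distance_equals_phs_count(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=500))
        positions = sorted(int(p) for p in rng.choice(np.arange(101, 400), 12, replace=False))
        records = []
        for pos in positions:
            src = ref[pos - 1]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[src]
            records.append(_phs(pos, src, alt))
        pair = reconstruct_paralogs(_call(100, 400, tuple(positions)), records, ref)
        assert pair.n_differences == len(positions)

    def test_phs_outside_span_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_paralogs(_call(4, 10, (5,)), [_phs(20)], self.REF)


class TestNG86:
    def test_identical_sequences_are_zero(self):
        est = ng86("ATGAAACCC", "ATGAAACCC")
        assert est.dn == est.ds == 0.0
        assert not est.undefined_ratio

    def test_synonymous_third_position_change(self):
        # TTT -> TTC is Phe -> Phe: purely synonymous
        est = ng86("TTTCTTGAAGAT", "TTCCTTGAAGAT")
        assert est.s_differences == 1.0 and est.n_differences == 0.0
        assert est.ds > 0 and est.dn == 0.0

    def test_nonsynonymous_first_position_change(self):
        # TTT -> ATT is Phe -> Ile: purely nonsynonymous
        est = ng86("TTTCTTGAAGAT", "ATTCTTGAAGAT")
        assert est.n_differences == 1.0 and est.s_differences == 0.0
        assert est.dn > 0 and est.ds == 0.0
        assert est.undefined_ratio and est.ratio is None

    def test_frozen_fixture_matches_hand_worked_oracle(self):
        est = ng86(FIXTURE_A, FIXTURE_B)
        assert est.dn == pytest.approx(FIXTURE_DN, abs=1e-9)
        assert est.ds == pytest.approx(FIXTURE_DS, abs=1e-9)

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        non_stop = [c for c in codons if c not in ("TAA", "TAG", "TGA")]
        for _ in range(50):
            n_codons = int(rng.integers(5, 25))
            seq_a = []
            seq_b = []
            for _ in range(n_codons):
                ca = non_stop[int(rng.integers(len(non_stop)))]
                cb = ca
                if rng.random() < 0.3:  # <=10% per-site divergence on average
                    pos = int(rng.integers(3))
                    base = str(rng.choice([x for x in "ACGT" if x != ca[pos]]))
                    cand = ca[:pos] + base + ca[pos + 1 :]
                    if cand not in ("TAA", "TAG", "TGA"):
                        cb = cand
                seq_a.append(ca)
                seq_b.append(cb)
            a, b = "".join(seq_a), "".join(seq_b)
            est = ng86(a, b)
            dn, ds, n_sites, s_sites, n_diff, s_diff = ng86_bruteforce(a, b)
            assert est.dn == pytest.approx(dn, abs=1e-9)
            assert est.ds == pytest.approx(ds, abs=1e-9)
            assert est.n_sites == pytest.approx(n_sites, abs=1e-9)

    def test_biopython_cross_check_on_fixture(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        dn, ds = cal_dn_ds(CodonSeq(FIXTURE_A), CodonSeq(FIXTURE_B), method="NG86")
        est = ng86(FIXTURE_A, FIXTURE_B)
        assert est.dn == pytest.approx(dn, abs=1e-9)
        assert est.ds == pytest.approx(ds, abs=1e-9)

    def test_symmetry(self, rng):
        est_ab = ng86(FIXTURE_A, FIXTURE_B)
        est_ba = ng86(FIXTURE_B, FIXTURE_A)
        assert est_ab.dn == pytest.approx(est_ba.dn, abs=1e-12)
        assert est_ab.ds == pytest.approx(est_ba.ds, abs=1e-12)

    def test_site_count_conservation(self):
        est = ng86(FIXTURE_A, FIXTURE_B)
        assert est.n_sites + est.s_sites == pytest.approx(3 * est.n_codons, abs=1e-9)

    def test_partial_codon_trimmed_with_warning(self):
        with pytest.warns(UserWarning):
            est = ng86("ATGAAACC", "ATGAAACC")
        assert est.n_codons == 2

    def test_stop_codon_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            est = ng86("ATGTAAAAA", "ATGTAAAAA")
        assert est.n_codons == 2

    def test_dn_ds_over_cds_overlap(self):
        ref = "A" * 12 + FIXTURE_A + "C" * 9
        pair = ParalogPair("d", ref[12:102], ref[12:102].replace("TTG", "TTA", 1), 12)
        est = dn_ds(pair, [(12, 102)], frame=0)
        assert est.n_codons == 30

    def test_zero_phs_reconstruction_gives_zero_estimate(self):
        ref = "ATG" + FIXTURE_A + "TAA"
        pair = reconstruct_paralogs(_call(3, 93, (4, 92)), [], ref)
        est = dn_ds(pair, [(3, 93)])
        assert est.dn == est.ds == 0.0


class TestSignTest:
    def test_twelve_one_directional_pairs(self):
        # all paralog ratios above their ortholog partner: p = 2 * 2^-12
        paralogs = [0.8 + 0.01 * i for i in range(12)]
        orthologs = [0.2 + 0.01 * i for i in range(12)]
        out = compare_paralog_ortholog(paralogs, orthologs)
        assert out["p"] == pytest.approx(2 * 2.0**-12)
        assert out["n_paralog_greater"] == 12

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError):
            compare_paralog_ortholog([0.5, 0.5], [0.5, 0.5])

    def test_null_calibration(self, rng):
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            a = rng.uniform(0, 1, size=20)
            b = rng.uniform(0, 1, size=20)
            out = compare_paralog_ortholog(list(a), list(b))
            rejections += out["p"] < 0.05
        assert rejections / n_sims < 0.1


class TestBlastReader:
    def test_reads_outfmt6_and_classifies(self, tmp_path):
        from phsdup.paralogs import read_blast_tabular

        path = tmp_path / "hits.tsv"
        path.write_text(
            # dup1: one strong hit; dup2: weak identity; dup3: no hits
            "dup1\tscf_1\t95.0\t300\t10\t1\t1\t300\t5000\t5299\t1e-50\t500\n"
            "dup2\tscf_1\t85.0\t380\t40\t2\t1\t380\t9000\t9379\t1e-40\t400\n"
        )
        hits = read_blast_tabular(path, {"dup1": 400, "dup2": 400, "dup3": 400})
        assert filter_homology_hits(hits["dup1"]) == "single_copy"
        assert filter_homology_hits(hits["dup2"]) == "no_homolog"
        assert filter_homology_hits(hits["dup3"]) == "no_homolog"
        assert hits["dup1"][0].subject_start == 4999

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("dup1\tscf_1\t95.0\n")
        with pytest.raises(ValueError, match="line 1"):
            from phsdup.paralogs import read_blast_tabular

            read_blast_tabular(path, {"dup1": 400})


class TestHomologyHits:
    def _hit(self, identity, coverage, start=0):
        qlen = 400
        return HomologyHit("q", start, start + int(qlen * coverage), identity,
                           int(qlen * coverage), qlen)

    def test_qualifying_hit(self):
        assert filter_homology_hits([self._hit(95, 0.6)]) == "single_copy"

    def test_identity_below_threshold_fails(self):
        assert filter_homology_hits([self._hit(89, 0.9)]) == "no_homolog"

    def test_coverage_exactly_half_fails(self):
        assert filter_homology_hits([self._hit(95, 0.5)]) == "no_homolog"

    def test_two_nonoverlapping_hits_mean_subject_duplication(self):
        hits = [self._hit(95, 0.6, start=0), self._hit(95, 0.6, start=1000)]
        assert filter_homology_hits(hits) == "duplicated_in_subject"

    def test_overlapping_extra_hit_collapses(self):
        hits = [self._hit(95, 0.6, start=0), self._hit(95, 0.6, start=100)]
        assert filter_homology_hits(hits) == "single_copy"
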