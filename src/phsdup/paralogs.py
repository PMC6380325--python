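"""Paralog reconstruction and Nei-Gojobori (1986) dN/dS counting.

The two copies of a PHS duplication are reconstructed from the reference
sequence by assigning one allele of every PHS to each copy; outside the PHS
positions the copies equal the reference.  Because NG86 counting is
symmetric in the two sequences, the (unknown) phase of the alleles does
not affect the estimate.

NG86 conventions used here (matching the standard counting method):

* synonymous site count of a codon = (number of the 9 one-step changes that
  preserve the amino acid) / 3; changes creating stop codons count as
  nonsynonymous; N + S = 3 per codon exactly;
* for codons differing at 2 or 3 positions, synonymous/nonsynonymous
  differences are averaged over all minimal mutational paths with equal
  weights;
* proportions are Jukes-Cantor corrected: d = -3/4 ln(1 - 4p/3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from math import log

import numpy as np
from scipy import stats

__all__ = [
    "ParalogPair",
    "DnDsEstimate",
    "HomologyHit",
    "reconstruct_paralogs",
    "ng86",
    "dn_ds",
    "compare_paralog_ortholog",
    "read_blast_tabular",
    "filter_homology_hits",
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_BASES = "ACGT"


@dataclass(frozen=True)
class ParalogPair:
    """The two reconstructed copies of one duplication, equal length."""

    dup_id: str
    copy_a: str
    copy_b: str
    span_start: int = 0  # 0-based reference start of the reconstructed span

    def __post_init__(self) -> None:
        if len(self.copy_a) != len(self.copy_b):
            raise ValueError("copies must have equal length")

    @property
    def n_differences(self) -> int:
        return sum(a != b for a, b in zip(self.copy_a, self.copy_b))


@dataclass(frozen=True)
class DnDsEstimate:
    dn: float
    ds: float
    n_sites: float
    s_sites: float
    n_differences: float
    s_differences: float
    n_codons: int
    undefined_ratio: bool  # dS = 0 (ratio not computable)

    @property
    def ratio(self) -> float | None:
        if self.ds == 0:
            return None
        return self.dn / self.ds


@dataclass(frozen=True)
class HomologyHit:
    """One alignment hit of a duplication query in a subject genome."""

    query_id: str
    subject_start: int
    subject_end: int
    identity: float  # percent, 0..100
    alignment_length: int
    query_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")

    def qualifies(self, min_identity: float = 90.0, min_coverage: float = 0.5) -> bool:
        return (
            self.identity > min_identity
            and self.alignment_length > min_coverage * self.query_length
        )


def reconstruct_paralogs(call, phs_records, reference: str) -> ParalogPair:
    """Rebuild both copies of a duplication call from its PHS alleles.

    Copy A takes allele1 and copy B allele2 at every PHS of the call;
    elsewhere both copies equal the reference.  All PHS must fall inside
    the call span.
    """
    span_a = list(reference[call.start : call.end])
    span_b = list(span_a)
    for rec in phs_records:
        pos0 = rec.pos - 1
        if not call.start <= pos0 < call.end:
            raise ValueError(f"PHS at {rec.pos} outside call span")
        span_a[pos0 - call.start] = rec.allele1
        span_b[pos0 - call.start] = rec.allele2
    return ParalogPair(
        dup_id=call.event_id or f"{call.chrom}:{call.start}-{call.end}",
        copy_a="".join(span_a),
        copy_b="".join(span_b),
        span_start=call.start,
    )


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3."""
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for i in range(3):
        for base in _BASES:
            if base == codon[i]:
                continue
            neighbor = codon[:i] + base + codon[i + 1 :]
            if _CODON_TABLE[neighbor] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _codon_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal paths."""
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    paths = list(permutations(diff_pos))
    weight = 1.0 / len(paths)
    for path in paths:
        current = codon1
        for i in path:
            nxt = current[:i] + codon2[i] + current[i + 1 :]
            if _CODON_TABLE[current] == _CODON_TABLE[nxt]:
                syn += weight
            else:
                nonsyn += weight
            current = nxt
    return syn, nonsyn


def _jukes_cantor(p: float) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        raise ValueError("substitution proportion saturated (p >= 3/4)")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86(seq_a: str, seq_b: str) -> DnDsEstimate:
    """Pairwise NG86 dN and dS over two codon-aligned coding sequences.

    Sequences must have equal length; a trailing partial codon is trimmed
    with a warning.  Codons that are stop codons in either sequence are
    skipped with a warning (internal stops signal a frame problem).  The
    estimate is symmetric in its arguments.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    if len(seq_a) % 3:
        warnings.warn("length not divisible by 3; trailing bases trimmed")
        trim = len(seq_a) - len(seq_a) % 3
        seq_a, seq_b = seq_a[:trim], seq_b[:trim]
    if not seq_a:
        raise ValueError("need at least one codon")

    s_sites = n_sites = s_diff = n_diff = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if _CODON_TABLE.get(ca) == "*" or _CODON_TABLE.get(cb) == "*":
            warnings.warn(f"stop codon at alignment position {i}; codon skipped")
            continue
        if ca not in _CODON_TABLE or cb not in _CODON_TABLE:
            raise ValueError(f"non-ACGT codon at position {i}")
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, nd = _codon_differences(ca, cb)
        s_diff += sd
        n_diff += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no usable codons")

    ps = s_diff / s_sites if s_sites > 0 else 0.0
    pn = n_diff / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    return DnDsEstimate(
        dn=dn,
        ds=ds,
        n_sites=n_sites,
        s_sites=s_sites,
        n_differences=n_diff,
        s_differences=s_diff,
        n_codons=n_codons,
        undefined_ratio=(ds == 0.0 and dn > 0.0),
    )


def dn_ds(pair: ParalogPair, cds_intervals, frame: int = 0) -> DnDsEstimate:
    """NG86 estimate over the CDS overlap of a reconstructed paralog pair.

    ``cds_intervals`` are 0-based half-open reference intervals; the parts
    overlapping the pair's span are concatenated in order and read in the
    given frame (offset of the first complete codon within the
    concatenated coding sequence).
    """
    parts_a: list[str] = []
    parts_b: list[str] = []
    span_end = pair.span_start + len(pair.copy_a)
    for start, end in sorted(cds_intervals):
        lo, hi = max(start, pair.span_start), min(end, span_end)
        if hi <= lo:
            continue
        parts_a.append(pair.copy_a[lo - pair.span_start : hi - pair.span_start])
        parts_b.append(pair.copy_b[lo - pair.span_start : hi - pair.span_start])
    coding_a = "".join(parts_a)[frame:]
    coding_b = "".join(parts_b)[frame:]
    if len(coding_a) < 3:
        raise ValueError("CDS overlap shorter than one codon")
    return ng86(coding_a, coding_b)


def compare_paralog_ortholog(paralog_ratios, ortholog_ratios) -> dict[str, float]:
    """Two-sided sign test of paired paralog vs ortholog dN/dS ratios.

    Pairs are matched by position (same gene); ties and pairs with a
    non-finite ratio are dropped.  Raises when every pair is tied.
    """
    pairs = [
        (p, o)
        for p, o in zip(paralog_ratios, ortholog_ratios, strict=True)
        if p is not None and o is not None and np.isfinite(p) and np.isfinite(o)
    ]
    greater = sum(1 for p, o in pairs if p > o)
    less = sum(1 for p, o in pairs if p < o)
    k = greater + less
    if k == 0:
        raise ValueError("all pairs tied; sign test undefined")
    if k < 6:
        warnings.warn("fewer than 6 informative pairs; sign test has low power")
    result = stats.binomtest(greater, k, 0.5, alternative="two-sided")
    return {
        "n_informative": k,
        "n_paralog_greater": greater,
        "p": float(result.pvalue),
    }


def read_blast_tabular(path, query_lengths: dict[str, int]) -> dict[str, list[HomologyHit]]:
    """Read BLAST tabular (outfmt 6) hits, grouped by query id.

    Expects the default 12 columns (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore); ``query_lengths``
    supplies each query's total length for the coverage rule.  Queries with
    no hits are returned with empty lists.
    """
    hits: dict[str, list[HomologyHit]] = {q: [] for q in query_lengths}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"line {lineno}: outfmt 6 needs 12 columns")
            query = fields[0]
            if query not in query_lengths:
                raise ValueError(f"line {lineno}: unknown query {query!r}")
            sstart, send = sorted((int(fields[8]), int(fields[9])))
            hits[query].append(
                HomologyHit(
                    query_id=query,
                    subject_start=sstart - 1,
                    subject_end=send,
                    identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    query_length=query_lengths[query],
                )
            )
    return hits


def filter_homology_hits(
    hits,
    *,
    min_identity: float = 90.0,
    min_coverage: float = 0.5,
) -> str:
    """Classify a duplication's cross-species homology status.

    Qualifying hits need identity strictly above 90% and alignment length
    strictly above half the query length.  Zero qualifying hits ->
    ``no_homolog``; one -> ``single_copy``; two or more non-overlapping
    (in the subject) -> ``duplicated_in_subject``; overlapping extras
    collapse onto one copy.
    """
    qualifying = [
        h for h in hits if h.qualifies(min_identity=min_identity, min_coverage=min_coverage)
    ]
    if not qualifying:
        return "no_homolog"
    qualifying.sort(key=lambda h: (h.subject_start, h.subject_end))
    distinct = 1
    cursor = qualifying[0].subject_end
    for hit in qualifying[1:]:
        if hit.subject_start >= cursor:
            distinct += 1
        cursor = max(cursor, hit.subject_end)
    return "single_copy" if distinct == 1 else "duplicated_in_subject"
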