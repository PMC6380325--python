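"""Pseudoheterozygous-site (PHS) calling from per-genome pileup columns.

A PHS is a biallelic pileup column in a haploid genome that survives a set
of stringent quality filters designed to remove sequencing and mapping
artefacts: both alleles must be supported by high-quality, well-positioned
reads, the total depth must be adequate, and the site must not fall in a
homopolymer run, a non-unique (repeat) region, or near an indel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "PileupColumn",
    "CandidateSite",
    "SiteMasks",
    "PHSRecord",
    "IndelRecord",
    "build_masks",
    "call_candidate_sites",
    "filter_phs",
]

# One read's view of a site: (base, phred quality, distance from read start,
# distance from read end); both distances in bp and >= 0.
Observation = tuple[str, int, int, int]


@dataclass(frozen=True)
class PileupColumn:
    """All read observations overlapping one reference position (1-based)."""

    chrom: str
    pos: int
    ref: str
    observations: tuple[Observation, ...]

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class CandidateSite:
    """A biallelic pileup column prior to quality filtering."""

    column: PileupColumn
    allele1: str
    allele2: str


@dataclass(frozen=True)
class IndelRecord:
    chrom: str
    pos: int  # 1-based position of the base preceding the event
    length: int  # >0 insertion, <0 deletion; never 0
    genotype_quality: float
    supporting_reads: int

    def __post_init__(self) -> None:
        if self.length == 0:
            raise ValueError("indel length must be nonzero")


@dataclass(frozen=True)
class PHSRecord:
    """A retained pseudoheterozygous site in one haploid genome."""

    chrom: str
    pos: int  # 1-based
    genome_id: int
    allele1: str
    allele2: str
    support1: int  # well-positioned, high-quality reads per allele
    support2: int
    total_depth: int


@dataclass
class SiteMasks:
    """Excluded positions, 0-based half-open intervals per chromosome."""

    homopolymer: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    repeat: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    indel: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def finalize(self) -> "SiteMasks":
        self._trees = {}
        for mask in (self.homopolymer, self.repeat, self.indel):
            for chrom, ivals in mask.items():
                tree = self._trees.setdefault(chrom, IntervalTree())
                for start, end in ivals:
                    if end > start:
                        tree.addi(start, end)
        return self

    def is_masked(self, chrom: str, pos0: int) -> bool:
        """True if 0-based position falls in any mask interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos0))


def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(ivals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


def _repeat_positions(seq: str, k: int) -> list[tuple[int, int]]:
    # Exact k-mer multiplicity as a deterministic stand-in for remapping:
    # a position is repetitive when the k-mer starting there is non-unique.
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    ivals = [(i, i + 1) for i in range(len(seq) - k + 1) if counts[seq[i : i + k]] > 1]
    return _merge_intervals(ivals)


def build_masks(
    reference: dict[str, str] | str,
    indel_records: Sequence[IndelRecord] = (),
    *,
    homopolymer_min: int = 6,
    kmer: int = 30,
    indel_flank: int = 5,
    min_indel_gq: float = 30.0,
    min_indel_reads: int = 5,
) -> SiteMasks:
    """Build homopolymer, repeat and indel exclusion masks.

    Parameters
    ----------
    reference
        Mapping of chromosome name to sequence, or a bare sequence (taken as
        a single chromosome named ``"ref"``).
    indel_records
        Indels considered for masking; an indel qualifies when its genotype
        quality exceeds ``min_indel_gq`` and it has more than
        ``min_indel_reads`` supporting reads, and is then extended
        ``indel_flank`` bp on both sides.
    """
    if isinstance(reference, str):
        reference = {"ref": reference}
    if not reference or any(len(s) == 0 for s in reference.values()):
        raise ValueError("reference is empty")

    masks = SiteMasks()
    for chrom, seq in reference.items():
        seq = seq.upper()
        masks.homopolymer[chrom] = _homopolymer_runs(seq, homopolymer_min)
        masks.repeat[chrom] = _repeat_positions(seq, kmer)

    indel_ivals: dict[str, list[tuple[int, int]]] = {}
    for rec in indel_records:
        if rec.genotype_quality > min_indel_gq and rec.supporting_reads > min_indel_reads:
            length = abs(rec.length) if rec.length < 0 else 0
            start = max(0, rec.pos - 1 - indel_flank)
            end = rec.pos + length + indel_flank
            end = min(end, len(reference.get(rec.chrom, "")))
            indel_ivals.setdefault(rec.chrom, []).append((start, end))
    masks.indel = {c: _merge_intervals(v) for c, v in indel_ivals.items()}
    return masks.finalize()


def call_candidate_sites(columns: Sequence[PileupColumn]) -> list[CandidateSite]:
    """Extract biallelic candidate sites from sorted pileup columns.

    Columns with a single observed allele are monomorphic and skipped;
    columns with three or more alleles signal error or higher copy number
    and are discarded entirely.  Input must be position-sorted per
    chromosome.
    """
    last: dict[str, int] = {}
    candidates: list[CandidateSite] = []
    for col in columns:
        if last.get(col.chrom, 0) > col.pos:
            raise ValueError(f"pileup columns not sorted at {col.chrom}:{col.pos}")
        last[col.chrom] = col.pos
        alleles = sorted({obs[0] for obs in col.observations})
        if len(alleles) != 2:
            continue
        candidates.append(CandidateSite(col, alleles[0], alleles[1]))
    return candidates


def filter_phs(
    candidates: Sequence[CandidateSite],
    masks: SiteMasks,
    *,
    genome_id: int = 0,
    min_quality: int = 25,
    min_end_distance: int = 15,
    min_allele_reads: int = 5,
    min_depth_exclusive: int = 8,
) -> list[PHSRecord]:
    """Apply the PHS quality filters to biallelic candidates.

    A candidate is retained iff

    1. every counted supporting observation of each allele has base quality
       >= ``min_quality`` (observations below Q25 do not count as support);
    2. each allele has at least ``min_allele_reads`` supporting reads whose
       site position is >= ``min_end_distance`` bp from both read ends;
    3. total read depth (all reads) is strictly greater than
       ``min_depth_exclusive``;
    4. the site is not inside any mask interval.

    The filter is a pure per-site function of its inputs.
    """
    records: list[PHSRecord] = []
    for cand in candidates:
        col = cand.column
        if col.depth <= min_depth_exclusive:
            continue
        if masks.is_masked(col.chrom, col.pos - 1):
            continue
        support = {cand.allele1: 0, cand.allele2: 0}
        for base, qual, off_start, off_end in col.observations:
            if qual < min_quality:
                continue
            if off_start >= min_end_distance and off_end >= min_end_distance:
                support[base] = support.get(base, 0) + 1
        if (
            support[cand.allele1] >= min_allele_reads
            and support[cand.allele2] >= min_allele_reads
        ):
            records.append(
                PHSRecord(
                    chrom=col.chrom,
                    pos=col.pos,
                    genome_id=genome_id,
                    allele1=cand.allele1,
                    allele2=cand.allele2,
                    support1=support[cand.allele1],
                    support2=support[cand.allele2],
                    total_depth=col.depth,
                )
            )
    return records
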