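"""Readers and writers for the plain-text formats used by the pipeline.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based conventions of VCF and GFF3 happens only at the format boundary.
BED records stay 0-based half-open.  Malformed lines raise with the line
number.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from phsdup.phs import PHSRecord

__all__ = [
    "BedRecord",
    "Gff3Record",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_phs_vcf",
    "write_phs_vcf",
    "write_phs_bed",
    "read_pileup_tsv",
    "parse_mpileup",
]


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    name: str = "."
    score: str = "."
    strand: str = "."


@dataclass(frozen=True)
class Gff3Record:
    seqid: str
    source: str
    type: str
    start: int  # 1-based inclusive, as in the format
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str]


def read_fasta(path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_bed(path) -> list[BedRecord]:
    records = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ValueError(f"line {lineno}: non-integer coordinates") from err
            if end < start or start < 0:
                raise ValueError(f"line {lineno}: invalid interval {start}-{end}")
            records.append(
                BedRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3] if len(fields) > 3 else ".",
                    score=fields[4] if len(fields) > 4 else ".",
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            )
    return records


def write_bed(records: Sequence[BedRecord], path) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{rec.score}"
                f"\t{rec.strand}\n"
            )


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff3(path) -> list[Gff3Record]:
    records = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: GFF3 needs 9 columns")
            try:
                start, end = int(fields[3]), int(fields[4])
                attrs = _parse_attributes(fields[8])
            except ValueError as err:
                raise ValueError(f"line {lineno}: {err}") from err
            records.append(
                Gff3Record(
                    seqid=fields[0],
                    source=fields[1],
                    type=fields[2],
                    start=start,
                    end=end,
                    score=fields[5],
                    strand=fields[6],
                    phase=fields[7],
                    attributes=attrs,
                )
            )
    return records


def write_gff3(records: Sequence[Gff3Record], path) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = ";".join(f"{k}={v}" for k, v in rec.attributes.items())
            fh.write(
                f"{rec.seqid}\t{rec.source}\t{rec.type}\t{rec.start}\t{rec.end}"
                f"\t{rec.score}\t{rec.strand}\t{rec.phase}\t{attrs}\n"
            )


def write_phs_vcf(records: Sequence[PHSRecord], path, sample: str = "sample") -> None:
    """Minimal single-sample VCF of PHS, genotyped 0/1 with allele depths."""
    with _open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.allele1}\t{rec.allele2}\t.\tPASS"
                f"\tGID={rec.genome_id}\tGT:AD:DP"
                f"\t0/1:{rec.support1},{rec.support2}:{rec.total_depth}\n"
            )


def read_phs_vcf(path) -> list[PHSRecord]:
    records = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"line {lineno}: VCF record needs >= 10 columns")
            try:
                pos = int(fields[1])
                genome_id = 0
                for item in fields[7].split(";"):
                    if item.startswith("GID="):
                        genome_id = int(item[4:])
                gt, ad, dp = fields[9].split(":")
                support1, support2 = (int(x) for x in ad.split(","))
            except ValueError as err:
                raise ValueError(f"line {lineno}: malformed VCF record") from err
            records.append(
                PHSRecord(
                    chrom=fields[0],
                    pos=pos,
                    genome_id=genome_id,
                    allele1=fields[3],
                    allele2=fields[4],
                    support1=support1,
                    support2=support2,
                    total_depth=int(dp),
                )
            )
    return records


def write_phs_bed(records: Sequence[PHSRecord], path) -> None:
    bed = [
        BedRecord(
            chrom=rec.chrom,
            start=rec.pos - 1,
            end=rec.pos,
            name=f"g{rec.genome_id}:{rec.allele1}/{rec.allele2}",
            score=str(rec.total_depth),
            strand="+",
        )
        for rec in records
    ]
    write_bed(bed, path)


def read_pileup_tsv(path) -> Iterator:
    """Read the synthetic pileup TSV (chrom, pos, ref, base:qual:off5:off3,...)."""
    from phsdup.phs import PileupColumn

    with _open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\tpos"):
            raise ValueError("line 1: unexpected pileup TSV header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                chrom, pos, ref, obs_text = line.split("\t")
                observations = tuple(
                    (b, int(q), int(s), int(e))
                    for b, q, s, e in (o.split(":") for o in obs_text.split(",") if o)
                )
            except ValueError as err:
                raise ValueError(f"line {lineno}: malformed pileup row") from err
            yield PileupColumn(chrom, int(pos), ref, observations)


def parse_mpileup(path, assumed_offset: int = 15) -> Iterator:
    """Convert ``samtools mpileup`` text output into pileup columns.

    The mpileup text format does not carry per-read positional offsets, so
    every observation is given ``assumed_offset`` from both read ends
    (default 15, i.e. treated as well-positioned); positional filtering
    therefore needs the richer pileup TSV that the synthetic module writes.
    Handles match/mismatch symbols, read start (``^``) / end (``$``)
    markers, deletions placeholders and indel insertions.
    """
    from phsdup.phs import PileupColumn

    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: mpileup needs 6 columns")
            chrom, pos, ref, _depth, bases, quals = fields[:6]
            observations = []
            i = qi = 0
            while i < len(bases):
                ch = bases[i]
                if ch == "^":
                    i += 2  # mapping-quality char follows
                    continue
                if ch == "$":
                    i += 1
                    continue
                if ch in "+-":
                    j = i + 1
                    while j < len(bases) and bases[j].isdigit():
                        j += 1
                    i = j + int(bases[i + 1 : j])
                    continue
                if ch not in "*<>":
                    base = ref.upper() if ch in ".," else ch.upper()
                    observations.append(
                        (base, ord(quals[qi]) - 33, assumed_offset, assumed_offset)
                    )
                qi += 1
                i += 1
            yield PileupColumn(chrom, int(pos), ref.upper(), tuple(observations))
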