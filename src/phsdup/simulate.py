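"""Synthetic haploid-genome populations carrying segmental duplications.

The generator emulates a haploid-embryo resequencing study: ``n_genomes``
haploid genomes sampled from one population, each carrying a subset of
segmental duplication events (tandem or interspersed) whose two copies have
diverged after duplication.  Because every duplicated copy maps back onto
the single-copy reference locus, each divergent site surfaces in the pileup
as a balanced biallelic column — a pseudoheterozygous site.

Reads are not simulated as FASTQ; the observation tracks a mapping-based
pipeline would produce (pileup columns, split-read clusters, 200-bp window
depths) are generated directly from the truth set, which isolates the
downstream decision rules from any external aligner.

Duplication lengths follow a log-normal distribution calibrated
analytically so that 83.4% of events are shorter than 500 bp
(``mu=5.175, sigma=1.073`` on the log scale).  Carrier counts follow either
the standard neutral frequency spectrum (P(i carriers) proportional to 1/i)
or a singleton-excess mixture that adds a point mass at one carrier.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from phsdup.phs import PileupColumn

__all__ = [
    "SimulationConfig",
    "DuplicationEvent",
    "ObservationTracks",
    "generate_reference",
    "inject_duplications",
    "apply_events",
    "simulate_observations",
    "write_truth_bed",
    "write_divergent_sites_tsv",
    "write_reference_fasta",
    "write_tracks_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe the emulated study design: 29 haploid genomes, 73-bp
    effective reads at ~30x depth, duplications mostly <500 bp with 1%
    post-duplication divergence between copies.
    """

    genome_length: int = 2_000_000
    n_genomes: int = 29
    n_events: int = 200
    size_mu: float = 5.175  # log-scale mean; P(length < 500 bp) = 0.834
    size_sigma: float = 1.073
    min_length: int = 10
    tandem_fraction: float = 0.3
    divergence_rate: float = 0.01
    frequency_model: str = "neutral"  # "neutral" | "singleton_excess"
    singleton_weight: float = 0.4  # extra point mass at 1 carrier
    read_length: int = 73
    mean_depth: float = 30.0
    base_error_rate: float = 0.001
    qual_range: tuple[int, int] = (25, 40)
    window: int = 200
    chrom: str = "ref"
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_genomes < 2:
            raise ValueError("need at least two genomes")
        for name in ("tandem_fraction", "divergence_rate", "base_error_rate",
                     "singleton_weight"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.frequency_model not in ("neutral", "singleton_excess"):
            raise ValueError(f"unknown frequency_model {self.frequency_model!r}")
        if self.read_length <= 0 or self.mean_depth <= 0:
            raise ValueError("read_length and mean_depth must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class DuplicationEvent:
    """One segmental duplication with its diverged copy and carriers."""

    id: str
    chrom: str
    source_start: int  # 0-based half-open source interval
    source_end: int
    dest_position: int  # insertion point of the copy; tandem => source_end
    kind: str  # "tandem" | "interspersed"
    divergent_sites: tuple[tuple[int, str, str], ...]  # (offset, src, copy)
    carriers: frozenset[int]

    @property
    def length(self) -> int:
        return self.source_end - self.source_start

    @property
    def frequency(self) -> int:
        return len(self.carriers)


@dataclass
class ObservationTracks:
    """Per-genome observation tracks derived from the truth set.

    Depth is recorded per ``bin_size``-bp bin (half a window) so that
    overlapping 200-bp windows built from adjacent bins share their
    sampling noise, as windows built from the same mapped reads would.
    """

    pileups: dict[int, list[PileupColumn]]
    split_clusters: dict[int, list[tuple[int, int, int, int]]]  # (left, right, n+, n-)
    bin_depth: dict[int, np.ndarray]  # per-bp depth averaged over each bin
    bin_size: int = 100
    window: int = 200
    chrom: str = "ref"

    def window_depth(self, genome_id: int, *, step: int | None = None) -> np.ndarray:
        """Per-bp depth of 200-bp windows at the given step (default: tiled)."""
        from phsdup.detect import windows_from_bins

        return windows_from_bins(
            self.bin_depth[genome_id], self.bin_size, self.window,
            step=step if step is not None else self.window,
        )


def generate_reference(
    config: SimulationConfig,
    *,
    homopolymer_runs: int = 0,
    homopolymer_length: int = 8,
    repeat_copies: int = 0,
    repeat_length: int = 100,
) -> str:
    """Generate a random reference sequence over {A, C, G, T}.

    Optionally embeds homopolymer runs and exact repeat copies so mask
    construction can be exercised against a known ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seq = rng.choice(_BASES, size=config.genome_length)
    if homopolymer_runs:
        starts = rng.choice(
            config.genome_length - homopolymer_length, homopolymer_runs, replace=False
        )
        for start in starts:
            seq[start : start + homopolymer_length] = rng.choice(_BASES)
    if repeat_copies:
        template = rng.choice(_BASES, size=repeat_length)
        starts = rng.choice(
            config.genome_length - repeat_length, repeat_copies, replace=False
        )
        for start in starts:
            seq[start : start + repeat_length] = template
    return seq.tobytes().decode("ascii")


def _draw_lengths(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lengths = np.exp(rng.normal(config.size_mu, config.size_sigma, size=n))
    return np.maximum(np.rint(lengths).astype(int), config.min_length)


def _draw_carrier_count(config: SimulationConfig, rng: np.random.Generator) -> int:
    n = config.n_genomes
    classes = np.arange(1, n)
    weights = 1.0 / classes
    weights /= weights.sum()
    if config.frequency_model == "singleton_excess" and rng.random() < config.singleton_weight:
        return 1
    return int(rng.choice(classes, p=weights))


def inject_duplications(
    reference: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[DuplicationEvent]]:
    """Sample duplication events and build the per-genome mutated sequences.

    Source intervals are non-overlapping.  Each event's copy differs from
    its source at Binomial(L, divergence_rate) sites; carrier sets are drawn
    from the configured frequency model.  Returns the mutated sequence per
    genome and the truth set for recovery scoring.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    glen = len(reference)
    lengths = _draw_lengths(config, config.n_events, rng)
    if lengths.max() > glen:
        raise ValueError("duplication length exceeds genome length")

    events: list[DuplicationEvent] = []
    occupied: list[tuple[int, int]] = []
    guard = 500  # spacing so source intervals (and tandem copies) stay distinct
    attempts = 0
    for idx, length in enumerate(lengths):
        while True:
            attempts += 1
            if attempts > 50 * config.n_events:
                raise RuntimeError("could not place events; genome too small")
            start = int(rng.integers(guard, glen - length - guard))
            end = start + int(length)
            if all(end + guard <= s or start >= e + guard for s, e in occupied):
                break
        occupied.append((start, end))
        kind = "tandem" if rng.random() < config.tandem_fraction else "interspersed"
        if kind == "tandem":
            dest = end
        else:
            dest = int(rng.integers(0, glen))
        offsets = np.nonzero(rng.random(length) < config.divergence_rate)[0]
        sites = []
        for off in offsets:
            src = reference[start + off]
            alt = rng.choice([b for b in "ACGT" if b != src])
            sites.append((int(off), src, str(alt)))
        count = _draw_carrier_count(config, rng)
        carriers = frozenset(
            int(g) for g in rng.choice(config.n_genomes, size=count, replace=False)
        )
        events.append(
            DuplicationEvent(
                id=f"dup{idx:05d}",
                chrom=config.chrom,
                source_start=start,
                source_end=end,
                dest_position=dest,
                kind=kind,
                divergent_sites=tuple(sites),
                carriers=carriers,
            )
        )
    genomes = [apply_events(reference, events, g) for g in range(config.n_genomes)]
    return genomes, events


def apply_events(reference: str, events: Sequence[DuplicationEvent], genome_id: int) -> str:
    """Materialize one genome's sequence by inserting its carried copies."""
    inserts: list[tuple[int, str]] = []
    for ev in events:
        if genome_id not in ev.carriers:
            continue
        copy = list(reference[ev.source_start : ev.source_end])
        for off, _src, alt in ev.divergent_sites:
            copy[off] = alt
        inserts.append((ev.dest_position, "".join(copy)))
    pieces: list[str] = []
    prev = 0
    for pos, seq in sorted(inserts):
        pieces.append(reference[prev:pos])
        pieces.append(seq)
        prev = pos
    pieces.append(reference[prev:])
    return "".join(pieces)


def _copy_number_profile(
    events: Sequence[DuplicationEvent], genome_id: int, glen: int
) -> np.ndarray:
    cn = np.ones(glen, dtype=np.float64)
    for ev in events:
        if genome_id in ev.carriers:
            cn[ev.source_start : ev.source_end] += 1.0
    return cn


def _pileup_column(
    chrom: str,
    pos1: int,
    ref_base: str,
    alleles: tuple[str, ...],
    copy_number: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PileupColumn | None:
    """Sample one pileup column; reads drawn evenly from the mapped copies."""
    depth = int(rng.poisson(copy_number * config.mean_depth))
    if depth == 0:
        return None
    qlo, qhi = config.qual_range
    observations = []
    for _ in range(depth):
        base = alleles[int(rng.integers(len(alleles)))]
        if config.base_error_rate and rng.random() < config.base_error_rate:
            base = str(rng.choice([b for b in "ACGT" if b != base]))
        qual = int(rng.integers(qlo, qhi + 1))
        off_start = int(rng.integers(0, config.read_length))
        observations.append((base, qual, off_start, config.read_length - 1 - off_start))
    return PileupColumn(chrom, pos1, ref_base, tuple(observations))


def simulate_observations(
    reference: str,
    events: Sequence[DuplicationEvent],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ObservationTracks:
    """Derive pileup, split-read and window-depth tracks from the truth set.

    At each divergent site of a carried duplication the pileup shows the two
    copy alleles at an expected 1:1 ratio (two copies mapped onto one
    locus), perturbed by Poisson depth sampling and the base error rate.
    Window depth over a duplicated source interval doubles in expectation.
    Carried tandem events emit one split-read cluster at the breakpoint pair
    with the spanning reads split between strands.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    glen = len(reference)
    bin_size = max(config.window // 2, 1)

    pileups: dict[int, list[PileupColumn]] = {}
    clusters: dict[int, list[tuple[int, int, int, int]]] = {}
    depth: dict[int, np.ndarray] = {}

    for g in range(config.n_genomes):
        cn = _copy_number_profile(events, g, glen)
        bin_starts = np.arange(0, glen, bin_size)
        bin_cn = np.add.reduceat(cn, bin_starts)  # summed copy number per bin
        sizes = np.diff(np.append(bin_starts, glen))
        lam = config.mean_depth * bin_cn  # expected base count per bin
        depth[g] = rng.poisson(lam).astype(np.float64) / sizes

        cols: list[PileupColumn] = []
        for ev in events:
            carried = g in ev.carriers
            for off, src, alt in ev.divergent_sites:
                pos1 = ev.source_start + off + 1
                alleles = (src, alt) if carried else (src,)
                col = _pileup_column(
                    config.chrom, pos1, src, alleles, 2 if carried else 1, config, rng
                )
                if col is not None:
                    cols.append(col)
        cols.sort(key=lambda c: c.pos)
        pileups[g] = cols

        cl: list[tuple[int, int, int, int]] = []
        for ev in events:
            if ev.kind != "tandem" or g not in ev.carriers:
                continue
            support = int(rng.poisson(config.mean_depth / 2.0))
            if support == 0:
                continue
            fwd = int(rng.binomial(support, 0.5))
            cl.append((ev.source_start, ev.source_end, fwd, support - fwd))
        clusters[g] = sorted(cl)

    return ObservationTracks(
        pileups=pileups,
        split_clusters=clusters,
        bin_depth=depth,
        bin_size=bin_size,
        window=config.window,
        chrom=config.chrom,
    )


# ---------------------------------------------------------------------------
# plain-text writers


def write_reference_fasta(reference: str, path: str | Path, name: str = "ref") -> None:
    from phsdup.io import write_fasta

    write_fasta({name: reference}, path)


def write_truth_bed(events: Sequence[DuplicationEvent], path: str | Path) -> None:
    """Truth set as BED: 0-based half-open, name=event id, score=copy number."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                f"{ev.chrom}\t{ev.source_start}\t{ev.source_end}\t{ev.id}\t2\t+"
                f"\t{ev.kind}\t{ev.frequency}\n"
            )


def write_divergent_sites_tsv(events: Sequence[DuplicationEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tchrom\tpos\tsource_allele\tcopy_allele\n")
        for ev in events:
            for off, src, alt in ev.divergent_sites:
                fh.write(f"{ev.id}\t{ev.chrom}\t{ev.source_start + off + 1}\t{src}\t{alt}\n")


def write_tracks_tsv(tracks: ObservationTracks, directory: str | Path) -> None:
    """Write pileup, split-cluster and depth tracks as gzipped TSV.

    Pileup columns: chrom, pos, ref, comma-joined base:qual:off5:off3.
    Clusters: chrom, left, right, n_forward, n_reverse.
    Depth: chrom, window_start, depth.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for g, cols in tracks.pileups.items():
        with gzip.open(directory / f"pileup.g{g}.tsv.gz", "wt") as fh:
            fh.write("chrom\tpos\tref\tobservations\n")
            for col in cols:
                obs = ",".join(f"{b}:{q}:{s}:{e}" for b, q, s, e in col.observations)
                fh.write(f"{col.chrom}\t{col.pos}\t{col.ref}\t{obs}\n")
    for g, cl in tracks.split_clusters.items():
        with gzip.open(directory / f"splits.g{g}.tsv.gz", "wt") as fh:
            fh.write("chrom\tleft\tright\tn_forward\tn_reverse\n")
            for left, right, fwd, rev in cl:
                fh.write(f"{tracks.chrom}\t{left}\t{right}\t{fwd}\t{rev}\n")
    for g, d in tracks.bin_depth.items():
        with gzip.open(directory / f"depth.g{g}.tsv.gz", "wt") as fh:
            fh.write("chrom\tbin_start\tdepth\n")
            for i, value in enumerate(d):
                fh.write(f"{tracks.chrom}\t{i * tracks.bin_size}\t{value:.4f}\n")
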