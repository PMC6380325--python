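"""Merging linked PHS into duplication calls and population collation.

Consecutive PHS within 400 bp in the same genome are chained into one
PHS duplication (single linkage).  Calls are classified against the
independent evidence tracks: a call is *high_copy* when more than half of
its length overlaps high-copy regions, *tandem* when more than half
overlaps split-read tandem intervals, *both* when both hold, otherwise
*undetermined*.  Calls from different genomes sharing at least one PHS
position are collapsed into one population event whose frequency is its
carrier count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from phsdup.detect import HighCopyRegion, TandemDuplication
from phsdup.phs import PHSRecord

__all__ = [
    "PHSDuplication",
    "DuplicationCatalog",
    "merge_phs",
    "merge_phs_population",
    "apply_exclusions",
    "classify_duplications",
    "collate_population",
    "size_class_fractions",
]

LARGE_REGION_SPAN = 28_000  # flag merged spans above this for exclusion review


@dataclass(frozen=True)
class PHSDuplication:
    """A merged run of linked PHS in one genome."""

    chrom: str
    start: int  # 0-based half-open span from first to last PHS
    end: int
    genome_id: int
    phs_positions: tuple[int, ...]  # 1-based
    dup_class: str | None = None  # tandem | high_copy | both | undetermined
    event_id: str | None = None
    frequency: int | None = None

    @property
    def phs_count(self) -> int:
        return len(self.phs_positions)

    @property
    def length(self) -> int:
        """Span between first and last PHS; a lone PHS has length 1."""
        return self.end - self.start


@dataclass
class DuplicationCatalog:
    """All classified calls across genomes with population event identity."""

    calls: list[PHSDuplication]
    events: dict[str, frozenset[int]] = field(default_factory=dict)
    excluded: list[PHSDuplication] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_genome_calls(self) -> int:
        return len(self.calls)

    def event_frequencies(self) -> dict[str, int]:
        return {eid: len(carriers) for eid, carriers in self.events.items()}

    def sfs_counts(self, n_genomes: int) -> list[int]:
        """Counts of events carried by i genomes, i = 1..n-1."""
        counts = [0] * (n_genomes - 1)
        for carriers in self.events.values():
            i = len(carriers)
            if 1 <= i <= n_genomes - 1:
                counts[i - 1] += 1
        return counts

    def per_genome_counts(self) -> dict[int, int]:
        counts: dict[int, int] = defaultdict(int)
        for call in self.calls:
            counts[call.genome_id] += 1
        return dict(counts)


def merge_phs(records: Sequence[PHSRecord], gap: int = 400) -> list[PHSDuplication]:
    """Chain PHS of one genome into duplication calls (single linkage).

    Consecutive PHS on the same chromosome at most ``gap`` bp apart join
    one call; the partition is exhaustive and order-independent.  Records
    must all come from one genome.
    """
    if not records:
        return []
    genomes = {r.genome_id for r in records}
    if len(genomes) > 1:
        raise ValueError(f"merge_phs expects one genome, got {sorted(genomes)}")
    genome_id = genomes.pop()

    by_chrom: dict[str, list[int]] = defaultdict(list)
    for rec in records:
        by_chrom[rec.chrom].append(rec.pos)
    calls: list[PHSDuplication] = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        chain = [positions[0]]
        for pos in positions[1:]:
            if pos - chain[-1] <= gap:
                chain.append(pos)
            else:
                calls.append(_make_call(chrom, genome_id, chain))
                chain = [pos]
        calls.append(_make_call(chrom, genome_id, chain))
    return calls


def _make_call(chrom: str, genome_id: int, positions: list[int]) -> PHSDuplication:
    return PHSDuplication(
        chrom=chrom,
        start=positions[0] - 1,
        end=positions[-1],
        genome_id=genome_id,
        phs_positions=tuple(positions),
    )


def merge_phs_population(
    records: Sequence[PHSRecord], gap: int = 400
) -> list[PHSDuplication]:
    """Merge PHS per genome across a whole population sample."""
    by_genome: dict[int, list[PHSRecord]] = defaultdict(list)
    for rec in records:
        by_genome[rec.genome_id].append(rec)
    calls: list[PHSDuplication] = []
    for genome_id in sorted(by_genome):
        calls.extend(merge_phs(by_genome[genome_id], gap=gap))
    return calls


def apply_exclusions(
    calls: Sequence[PHSDuplication],
    excluded: Iterable[tuple[str, int, int]] = (),
    *,
    span_flag: int = LARGE_REGION_SPAN,
) -> tuple[list[PHSDuplication], list[PHSDuplication], list[PHSDuplication]]:
    """Drop calls overlapping excluded regions; flag very large spans.

    Returns ``(kept, removed, flagged)``.  ``flagged`` lists kept calls
    whose span exceeds ``span_flag`` (default 28 kb) for manual review of
    large clustered duplication regions; they are not removed.
    """
    excluded = list(excluded)
    kept: list[PHSDuplication] = []
    removed: list[PHSDuplication] = []
    for call in calls:
        hit = any(
            call.chrom == chrom and call.start < end and call.end > start
            for chrom, start, end in excluded
        )
        (removed if hit else kept).append(call)
    flagged = [c for c in kept if c.length > span_flag]
    return kept, removed, flagged


def _overlap_length(
    call: PHSDuplication, intervals: Sequence[tuple[str, int, int]]
) -> int:
    merged: list[tuple[int, int]] = []
    for chrom, start, end in sorted(i for i in intervals if i[0] == call.chrom):
        start, end = max(start, call.start), min(end, call.end)
        if end <= start:
            continue
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return sum(end - start for start, end in merged)


def classify_duplications(
    calls: Sequence[PHSDuplication],
    high_copy_regions: Sequence[HighCopyRegion],
    tandem_calls: Sequence[TandemDuplication],
    *,
    min_overlap_fraction: float = 0.5,
    per_genome_evidence: bool = True,
) -> list[PHSDuplication]:
    """Assign tandem/high-copy/both/undetermined classes by >50% overlap.

    The fraction is of the call's own length (first-to-last PHS span,
    minimum 1 bp) and must strictly exceed ``min_overlap_fraction``.  With
    ``per_genome_evidence`` only evidence from the call's genome is used;
    high-copy regions with genome id absent (plain intervals) always apply.
    """
    hc_by_genome: dict[int | None, list[tuple[str, int, int]]] = defaultdict(list)
    for region in high_copy_regions:
        genome = getattr(region, "genome_id", None)
        hc_by_genome[genome].append((region.chrom, region.start, region.end))
    td_by_genome: dict[int | None, list[tuple[str, int, int]]] = defaultdict(list)
    for tandem in tandem_calls:
        genome = tandem.genome_id if per_genome_evidence else None
        td_by_genome[genome].append((tandem.chrom, tandem.start, tandem.end))

    classified: list[PHSDuplication] = []
    for call in calls:
        hc_ivals = hc_by_genome.get(None, []) + (
            hc_by_genome.get(call.genome_id, []) if per_genome_evidence
            else [iv for k, v in hc_by_genome.items() if k is not None for iv in v]
        )
        td_ivals = td_by_genome.get(None, []) + td_by_genome.get(call.genome_id, [])
        length = max(call.length, 1)
        is_hc = _overlap_length(call, hc_ivals) > min_overlap_fraction * length
        is_td = _overlap_length(call, td_ivals) > min_overlap_fraction * length
        if is_hc and is_td:
            dup_class = "both"
        elif is_hc:
            dup_class = "high_copy"
        elif is_td:
            dup_class = "tandem"
        else:
            dup_class = "undetermined"
        classified.append(replace(call, dup_class=dup_class))
    return classified


def collate_population(
    calls: Sequence[PHSDuplication],
    *,
    by: str = "position",
) -> DuplicationCatalog:
    """Union calls across genomes into population events with frequencies.

    ``by="position"``: calls in different genomes sharing at least one PHS
    position are one event (conservative identity).  ``by="overlap"``:
    calls with overlapping spans are one event.
    """
    if by not in ("position", "overlap"):
        raise ValueError("by must be 'position' or 'overlap'")
    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    if by == "position":
        by_pos: dict[tuple[str, int], list[int]] = defaultdict(list)
        for idx, call in enumerate(calls):
            for pos in call.phs_positions:
                by_pos[(call.chrom, pos)].append(idx)
        for indices in by_pos.values():
            for other in indices[1:]:
                union(indices[0], other)
    else:
        order = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].start))
        for a, b in zip(order, order[1:]):
            if (
                calls[a].chrom == calls[b].chrom
                and calls[b].start < calls[find(a)].end
                and calls[a].end > calls[b].start
            ):
                union(a, b)

    groups: dict[int, list[int]] = defaultdict(list)
    for idx in range(len(calls)):
        groups[find(idx)].append(idx)

    events: dict[str, frozenset[int]] = {}
    updated = list(calls)
    for eid, root in enumerate(sorted(groups, key=lambda r: (calls[r].chrom, calls[r].start))):
        members = groups[root]
        carriers = frozenset(calls[i].genome_id for i in members)
        event_id = f"event{eid:05d}"
        events[event_id] = carriers
        for i in members:
            updated[i] = replace(
                updated[i], event_id=event_id, frequency=len(carriers)
            )
    return DuplicationCatalog(calls=updated, events=events)


def size_class_fractions(
    calls: Sequence[PHSDuplication],
    bounds: tuple[int, int] = (500, 1000),
) -> dict[str, float]:
    """Fractions of calls below 500 bp, 500 bp - 1 kb, and above 1 kb."""
    if not calls:
        return {"lt_500": 0.0, "500_to_1k": 0.0, "gt_1k": 0.0}
    low, high = bounds
    n = len(calls)
    small = sum(1 for c in calls if c.length < low)
    large = sum(1 for c in calls if c.length > high)
    return {
        "lt_500": small / n,
        "500_to_1k": (n - small - large) / n,
        "gt_1k": large / n,
    }
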