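"""End-to-end driver: simulate -> call PHS -> detect -> merge -> collate -> stats.

Every stage consumes the previous stage's in-memory products; the report
records per-stage counts with telescoping filter attrition, the thresholds
actually applied, and the population-level statistics.  All randomness
flows from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from phsdup import detect, dupcall, phs, popgen, simulate

__all__ = ["PipelineConfig", "RunReport", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds (defaults are the study values) and the simulation setup."""

    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    min_base_quality: int = 25
    min_end_distance: int = 15
    min_depth_exclusive: int = 8
    homopolymer_min: int = 6
    repeat_kmer: int = 30
    indel_flank: int = 5
    merge_gap: int = 400
    depth_window: int = 200
    high_copy_peak: float = 2.0
    high_copy_run: float = 1.25
    min_s1_exclusive: int = 15
    min_overlap_fraction: float = 0.5
    span_flag: int = 28_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_base_quality", "min_end_distance", "homopolymer_min",
            "repeat_kmer", "indel_flank", "merge_gap", "depth_window",
            "min_s1_exclusive", "span_flag",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.simulation = dataclasses.replace(
            self.simulation, seed=self.seed, window=self.depth_window
        )


@dataclass
class RunReport:
    """Per-stage counts, attrition, thresholds and headline statistics."""

    seed: int
    thresholds: dict
    stage_counts: dict = field(default_factory=dict)
    attrition: dict = field(default_factory=dict)
    statistics: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "seed": self.seed,
                "thresholds": self.thresholds,
                "stage_counts": self.stage_counts,
                "attrition": self.attrition,
                "statistics": self.statistics,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class PipelineResult:
    reference: str
    events: list
    tracks: simulate.ObservationTracks
    masks: phs.SiteMasks
    phs_records: list
    catalog: dupcall.DuplicationCatalog
    high_copy: dict
    tandem: dict
    report: RunReport


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full synthetic study and return products plus report."""
    sim = config.simulation
    reference = simulate.generate_reference(sim)
    rng = np.random.default_rng(sim.seed + 1)
    _genomes, events = simulate.inject_duplications(reference, sim, rng)
    tracks = simulate.simulate_observations(reference, events, sim, rng)

    masks = phs.build_masks(
        {sim.chrom: reference},
        homopolymer_min=config.homopolymer_min,
        kmer=config.repeat_kmer,
        indel_flank=config.indel_flank,
    )

    all_phs: list[phs.PHSRecord] = []
    n_candidates = 0
    high_copy: dict[int, list] = {}
    tandem: dict[int, list] = {}
    for g in range(sim.n_genomes):
        candidates = phs.call_candidate_sites(tracks.pileups[g])
        n_candidates += len(candidates)
        records = phs.filter_phs(
            candidates,
            masks,
            genome_id=g,
            min_quality=config.min_base_quality,
            min_end_distance=config.min_end_distance,
            min_depth_exclusive=config.min_depth_exclusive,
        )
        all_phs.extend(records)
        step = config.depth_window // 2  # sliding windows, half-window step
        profile = detect.compute_depth_profile(
            tracks.window_depth(g, step=step),
            genome_id=g,
            window=config.depth_window,
            step=step,
            trim_elevated=True,
        )
        high_copy[g] = detect.call_high_copy_regions(
            profile,
            chrom=sim.chrom,
            run_threshold=config.high_copy_run,
            peak_threshold=config.high_copy_peak,
        )
        tandem[g] = detect.call_tandem_duplications(
            tracks.split_clusters[g],
            genome_id=g,
            min_s1_exclusive=config.min_s1_exclusive,
            reference_length=sim.genome_length,
        )

    calls = dupcall.merge_phs_population(all_phs, gap=config.merge_gap)
    kept, removed, flagged = dupcall.apply_exclusions(calls, span_flag=config.span_flag)
    # evidence is pooled across genomes: a region duplicated in any sampled
    # genome counts as duplication evidence for the population catalog
    classified = dupcall.classify_duplications(
        kept,
        [r for regions in high_copy.values() for r in regions],
        [t for calls_g in tandem.values() for t in calls_g],
        min_overlap_fraction=config.min_overlap_fraction,
        per_genome_evidence=False,
    )
    catalog = dupcall.collate_population(classified)
    catalog.excluded = removed

    n = sim.n_genomes
    sfs_counts = catalog.sfs_counts(n)
    S = int(sum(sfs_counts))
    statistics: dict = {
        "n_events": catalog.n_events,
        "n_genome_calls": catalog.n_genome_calls,
        "size_fractions": dupcall.size_class_fractions(catalog.calls),
        "class_counts": _class_counts(catalog.calls),
    }
    if S > 0:
        singletons = sfs_counts[0]
        expectation = popgen.neutral_expectation(S, n)
        chi2, p = popgen.singleton_excess_test(singletons, S - singletons, n)
        statistics.update(
            {
                "sfs": sfs_counts,
                "singletons": singletons,
                "singleton_fraction": singletons / S,
                "expected_singletons": expectation["singleton"],
                "singleton_excess_chi2": chi2,
                "singleton_excess_p": p,
            }
        )

    report = RunReport(
        seed=config.seed,
        thresholds={
            "min_base_quality": config.min_base_quality,
            "min_end_distance": config.min_end_distance,
            "min_depth_exclusive": config.min_depth_exclusive,
            "homopolymer_min": config.homopolymer_min,
            "repeat_kmer": config.repeat_kmer,
            "indel_flank": config.indel_flank,
            "merge_gap": config.merge_gap,
            "depth_window": config.depth_window,
            "high_copy_peak": config.high_copy_peak,
            "high_copy_run": config.high_copy_run,
            "min_s1_exclusive": config.min_s1_exclusive,
            "min_overlap_fraction": config.min_overlap_fraction,
            "span_flag": config.span_flag,
        },
        stage_counts={
            "truth_events": len(events),
            "pileup_candidates": n_candidates,
            "phs_records": len(all_phs),
            "merged_calls": len(calls),
            "excluded_calls": len(removed),
            "flagged_large_spans": len(flagged),
            "classified_calls": len(classified),
            "population_events": catalog.n_events,
        },
        attrition={
            "merge": {
                "input_phs": len(all_phs),
                "retained_in_calls": sum(c.phs_count for c in calls),
            },
            "exclusion": {
                "input": len(calls),
                "retained": len(kept),
                "removed": len(removed),
            },
        },
        statistics=statistics,
    )
    return PipelineResult(
        reference=reference,
        events=events,
        tracks=tracks,
        masks=masks,
        phs_records=all_phs,
        catalog=catalog,
        high_copy=high_copy,
        tandem=tandem,
        report=report,
    )


def _class_counts(calls) -> dict[str, int]:
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.dup_class or "unclassified"] = (
            counts.get(call.dup_class or "unclassified", 0) + 1
        )
    return counts


def recovery_summary(result: PipelineResult, min_length: int = 200) -> dict:
    """Score truth-event recovery and classification correctness.

    A truth event of length >= ``min_length`` is recovered when at least
    one call in a carrier genome overlaps its source interval.  A recovered
    event is correctly classified when any overlapping carrier call has a
    class consistent with its kind (tandem -> tandem/both; interspersed ->
    high_copy/both).
    """
    calls_by_genome: dict[int, list] = {}
    for call in result.catalog.calls:
        calls_by_genome.setdefault(call.genome_id, []).append(call)

    eligible = [e for e in result.events if e.length >= min_length]
    recovered = 0
    correct = 0
    for event in eligible:
        hit_classes: set[str] = set()
        for g in event.carriers:
            for call in calls_by_genome.get(g, []):
                if call.start < event.source_end and call.end > event.source_start:
                    hit_classes.add(call.dup_class or "undetermined")
        if not hit_classes:
            continue
        recovered += 1
        wanted = {"tandem", "both"} if event.kind == "tandem" else {"high_copy", "both"}
        if hit_classes & wanted:
            correct += 1
    return {
        "eligible": len(eligible),
        "recovered": recovered,
        "recovery_rate": recovered / len(eligible) if eligible else float("nan"),
        "class_correct": correct,
        "class_correct_rate": correct / recovered if recovered else float("nan"),
    }
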