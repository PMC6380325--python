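"""Genomic-region assignment and permutation enrichment of duplications.

Sites and duplication calls are assigned to one of five region classes
(CDS, 5'UTR, 3'UTR, intron, intergenic) with coding-priority tie-breaking,
and compared against length-proportional expectations by chi-square.
Overlap of duplication calls with functional-element interval tracks is
tested against a null of length-matched fragments sampled uniformly from
the genome (the permutation expectation), with depletion trends across
duplication age groups assessed by sign, Friedman and Wilcoxon tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GenomeAnnotation",
    "PermutationResult",
    "REGION_PRIORITY",
    "assign_regions",
    "region_chi_square",
    "permutation_enrichment",
    "homolog_fraction_permutation",
    "sign_test_ratios",
    "age_group_trend",
]

REGION_PRIORITY = ("CDS", "five_prime_UTR", "three_prime_UTR", "intron", "intergenic")


def _merge(intervals) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if end <= start:
            continue
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class GenomeAnnotation:
    """Region intervals per class per chromosome (0-based half-open)."""

    chrom_lengths: dict[str, int]
    regions: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, per_chrom in self.regions.items():
            for chrom, ivals in per_chrom.items():
                bound = self.chrom_lengths.get(chrom)
                if bound is None:
                    raise ValueError(f"unknown chromosome {chrom!r} in {cls}")
                merged = _merge(ivals)
                if merged and (merged[0][0] < 0 or merged[-1][1] > bound):
                    raise ValueError(f"{cls} interval beyond {chrom} bounds")
                per_chrom[chrom] = merged

    @classmethod
    def from_gff3(cls, records, chrom_lengths: dict[str, int]) -> "GenomeAnnotation":
        """Build from GFF3 records (see :mod:`phsdup.io`).

        Uses CDS, five_prime_UTR, three_prime_UTR and intron features;
        introns are derived from exon gaps per transcript parent when not
        annotated explicitly.
        """
        regions: dict[str, dict[str, list[tuple[int, int]]]] = {
            k: {} for k in REGION_PRIORITY[:-1]
        }
        exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
        explicit_introns = False
        for rec in records:
            feature = rec.type
            if feature in ("CDS", "five_prime_UTR", "three_prime_UTR", "intron"):
                if feature == "intron":
                    explicit_introns = True
                regions[feature].setdefault(rec.seqid, []).append(
                    (rec.start - 1, rec.end)
                )
            elif feature == "exon":
                parent = rec.attributes.get("Parent", rec.attributes.get("ID", "?"))
                exons.setdefault((rec.seqid, parent), []).append((rec.start - 1, rec.end))
        if not explicit_introns:
            for (chrom, _parent), ivals in exons.items():
                ivals = sorted(ivals)
                for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                    if s2 > e1:
                        regions["intron"].setdefault(chrom, []).append((e1, s2))
        return cls(chrom_lengths=chrom_lengths, regions=regions)

    def region_lengths(self) -> dict[str, int]:
        """Total bp per region class with priority-resolved overlaps."""
        lengths: dict[str, int] = {}
        for chrom, bound in self.chrom_lengths.items():
            covered: list[tuple[int, int]] = []
            for cls in REGION_PRIORITY[:-1]:
                ivals = self.regions.get(cls, {}).get(chrom, [])
                remaining = _subtract(ivals, covered)
                lengths[cls] = lengths.get(cls, 0) + sum(e - s for s, e in remaining)
                covered = _merge(covered + ivals)
            lengths["intergenic"] = lengths.get("intergenic", 0) + bound - sum(
                e - s for s, e in covered
            )
        return lengths


def _subtract(
    intervals: list[tuple[int, int]], cover: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for start, end in _merge(intervals):
        cursor = start
        for cs, ce in cover:
            if ce <= cursor or cs >= end:
                continue
            if cs > cursor:
                out.append((cursor, cs))
            cursor = max(cursor, ce)
            if cursor >= end:
                break
        if cursor < end:
            out.append((cursor, end))
    return out


def _contains(ivals: list[tuple[int, int]], pos: int) -> bool:
    if not ivals:
        return False
    starts = [s for s, _ in ivals]
    idx = np.searchsorted(starts, pos, side="right") - 1
    return idx >= 0 and ivals[idx][0] <= pos < ivals[idx][1]


def assign_regions(sites, annotation: GenomeAnnotation) -> tuple[list[str], dict[str, int]]:
    """Label each (chrom, pos) site by region with CDS-first priority.

    When transcripts overlap, the highest-priority class containing the
    site wins (CDS > 5'UTR > 3'UTR > intron > intergenic).  Returns labels
    in input order and per-region counts.
    """
    labels: list[str] = []
    counts = {cls: 0 for cls in REGION_PRIORITY}
    for chrom, pos in sites:
        bound = annotation.chrom_lengths.get(chrom)
        if bound is None or not 0 <= pos < bound:
            raise ValueError(f"site {chrom}:{pos} beyond chromosome bounds")
        label = "intergenic"
        for cls in REGION_PRIORITY[:-1]:
            if _contains(annotation.regions.get(cls, {}).get(chrom, []), pos):
                label = cls
                break
        labels.append(label)
        counts[label] += 1
    return labels, counts


def region_chi_square(
    counts: dict[str, int], region_lengths: dict[str, int]
) -> dict[str, dict[str, float]]:
    """Per-region 1-df chi-square of observed vs length-proportional counts.

    Expected count per region is total * (region bp / total bp); each
    region is tested against its complement (region vs rest).
    """
    usable = {k: v for k, v in region_lengths.items() if v > 0}
    dropped = set(region_lengths) - set(usable)
    if dropped:
        warnings.warn(f"zero-length region classes excluded: {sorted(dropped)}")
    total_len = sum(usable.values())
    total = sum(counts.get(k, 0) for k in usable)
    results: dict[str, dict[str, float]] = {}
    for region, length in usable.items():
        expected = total * length / total_len
        observed = counts.get(region, 0)
        if total == 0:
            results[region] = {"observed": 0, "expected": 0.0, "chi2": 0.0, "p": 1.0}
            continue
        comp_obs = total - observed
        comp_exp = total - expected
        statistic = (observed - expected) ** 2 / expected
        if comp_exp > 0:
            statistic += (comp_obs - comp_exp) ** 2 / comp_exp
        results[region] = {
            "observed": float(observed),
            "expected": float(expected),
            "chi2": float(statistic),
            "p": float(stats.chi2.sf(statistic, df=1)),
        }
    return results


@dataclass
class PermutationResult:
    """Observed overlap count against a resampled null."""

    observed: float
    null_mean: float
    null: np.ndarray
    p: float
    ratio: float
    n_permutations: int

    def __post_init__(self) -> None:
        self.null = np.asarray(self.null, dtype=float)


class _TrackIndex:
    """Merged track intervals with O(log n) fragment-overlap queries."""

    def __init__(self, intervals):
        merged = _merge(intervals)
        self.starts = np.array([s for s, _ in merged], dtype=np.int64)
        self.ends = np.array([e for _, e in merged], dtype=np.int64)

    def overlaps(self, frag_starts: np.ndarray, frag_ends: np.ndarray) -> np.ndarray:
        if self.starts.size == 0:
            return np.zeros(frag_starts.shape, dtype=bool)
        before = np.searchsorted(self.starts, frag_ends, side="left")
        done = np.searchsorted(self.ends, frag_starts, side="right")
        return before > done


def _empirical_p(
    observed: float, null: np.ndarray, alternative: str
) -> float:
    n = null.size
    upper = (1 + int((null >= observed).sum())) / (n + 1)
    lower = (1 + int((null <= observed).sum())) / (n + 1)
    if alternative == "greater":
        return upper
    if alternative == "less":
        return lower
    return min(1.0, 2.0 * min(upper, lower))


def permutation_enrichment(
    calls,
    track_intervals,
    chrom_length: int,
    *,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Test overlap of calls with a track against random placement.

    ``calls`` is a sequence of (start, end) spans on one chromosome of
    ``chrom_length`` bp; ``track_intervals`` a sequence of (start, end).
    Each null draw samples one length-matched fragment per observed call
    uniformly over valid positions and counts fragments overlapping the
    track by at least 1 bp.  Empirical p uses the add-one formula so it is
    never 0; the two-sided p doubles the smaller tail, capped at 1.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; p resolution is coarse")
    rng = np.random.default_rng() if rng is None else rng
    spans = np.array([(s, e) for s, e in calls], dtype=np.int64).reshape(-1, 2)
    lengths = spans[:, 1] - spans[:, 0]
    if (lengths <= 0).any():
        raise ValueError("calls must have positive length")
    if lengths.max(initial=0) > chrom_length:
        raise ValueError("call longer than chromosome")
    index = _TrackIndex(track_intervals)
    observed = int(index.overlaps(spans[:, 0], spans[:, 1]).sum())
    if index.starts.size == 0:
        return PermutationResult(
            observed=observed,
            null_mean=0.0,
            null=np.zeros(n_permutations),
            p=1.0,
            ratio=0.0,
            n_permutations=n_permutations,
        )
    m = lengths.size
    max_start = (chrom_length - lengths).astype(np.float64) + 1.0
    null = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        frag_starts = (rng.random(m) * max_start).astype(np.int64)
        null[i] = index.overlaps(frag_starts, frag_starts + lengths).sum()
    null_mean = float(null.mean())
    ratio = observed / null_mean if null_mean > 0 else float("inf") if observed else 0.0
    return PermutationResult(
        observed=observed,
        null_mean=null_mean,
        null=null,
        p=_empirical_p(observed, null, alternative),
        ratio=ratio,
        n_permutations=n_permutations,
    )


def homolog_fraction_permutation(
    calls,
    status_fn,
    chrom_length: int,
    *,
    fragment_length: int = 400,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> PermutationResult:
    """Compare a per-fragment status fraction of calls against random fragments.

    ``status_fn(start, end) -> bool`` decides the status (e.g. "has no
    cross-species homolog") of an arbitrary fragment.  The observed
    fraction over calls is compared with the fraction over equally many
    random ``fragment_length``-bp fragments per null draw.
    """
    rng = np.random.default_rng() if rng is None else rng
    spans = [(s, e) for s, e in calls]
    if not spans:
        raise ValueError("no calls supplied")
    observed = float(np.mean([bool(status_fn(s, e)) for s, e in spans]))
    m = len(spans)
    null = np.empty(n_permutations, dtype=float)
    hi = chrom_length - fragment_length + 1
    for i in range(n_permutations):
        starts = rng.integers(0, hi, size=m)
        null[i] = np.mean([
            bool(status_fn(int(s), int(s) + fragment_length)) for s in starts
        ])
    null_mean = float(null.mean())
    ratio = observed / null_mean if null_mean > 0 else float("inf") if observed else 0.0
    return PermutationResult(
        observed=observed,
        null_mean=null_mean,
        null=null,
        p=_empirical_p(observed, null, alternative),
        ratio=ratio,
        n_permutations=n_permutations,
    )


def sign_test_ratios(ratios, *, null_value: float = 1.0) -> dict[str, float]:
    """Sign test of per-track observed/expected ratios against 1.

    Ties at exactly 1 are dropped.  Reports the one-sided (depletion) and
    two-sided binomial p.
    """
    ratios = np.asarray(list(ratios), dtype=float)
    below = int((ratios < null_value).sum())
    above = int((ratios > null_value).sum())
    k = below + above
    if k == 0:
        return {"n_below": 0, "n_above": 0, "p_one_sided": 1.0, "p_two_sided": 1.0}
    if k < 6:
        warnings.warn("fewer than 6 informative tracks; sign test has low power")
    one = stats.binomtest(below, k, 0.5, alternative="greater").pvalue
    two = stats.binomtest(below, k, 0.5, alternative="two-sided").pvalue
    return {
        "n_below": below,
        "n_above": above,
        "p_one_sided": float(one),
        "p_two_sided": float(two),
    }


def age_group_trend(
    group_calls: dict[str, list],
    tracks: dict[str, list],
    chrom_length: int,
    *,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Depletion trend of duplication age groups across element tracks.

    For every group x track the observed/expected overlap ratio is computed
    by :func:`permutation_enrichment`; per group a sign test asks whether
    ratios sit below 1 across tracks; a Friedman test (tracks as blocks)
    compares groups, followed by pairwise Wilcoxon signed-rank tests with
    Bonferroni-adjusted alpha.
    """
    rng = np.random.default_rng() if rng is None else rng
    if len(group_calls) < 2 or len(tracks) < 2:
        raise ValueError("need at least two groups and two tracks")
    groups = list(group_calls)
    track_ids = list(tracks)
    ratios = {g: [] for g in groups}
    for track_id in track_ids:
        for g in groups:
            res = permutation_enrichment(
                group_calls[g],
                tracks[track_id],
                chrom_length,
                n_permutations=n_permutations,
                rng=rng,
            )
            ratios[g].append(res.ratio)
    sign_tests = {g: sign_test_ratios(ratios[g]) for g in groups}
    samples = [np.asarray(ratios[g]) for g in groups]
    if all(np.allclose(s, samples[0]) for s in samples[1:]):
        fried_stat, fried_p = 0.0, 1.0  # identical groups: no evidence of trend
    elif len(track_ids) >= 3 and len(groups) >= 3:
        fried_stat, fried_p = stats.friedmanchisquare(*samples)
    else:
        fried_stat, fried_p = float("nan"), float("nan")
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise = {}
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            diff = np.asarray(ratios[gi]) - np.asarray(ratios[gj])
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(ratios[gi], ratios[gj]).pvalue)
            pairwise[(gi, gj)] = {
                "p": p,
                "p_bonferroni": min(1.0, p * n_pairs),
            }
    return {
        "ratios": ratios,
        "sign_tests": sign_tests,
        "friedman": {"statistic": float(fried_stat), "p": float(fried_p)},
        "pairwise_wilcoxon": pairwise,
    }
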