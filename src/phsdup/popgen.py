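"""Frequency-spectrum statistics for duplication catalogs.

Under the standard neutral model the expected number of variants carried by
exactly i of n sampled genomes is proportional to 1/i, so with S variants
in total the expected singleton count is S/a where a = sum_{i=1}^{n-1} 1/i.
An excess of observed singletons over S/a indicates that new duplications
are prevented from rising in frequency, the signature of purifying
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

__all__ = [
    "harmonic_number",
    "SiteFrequencySpectrum",
    "DiversityStats",
    "neutral_expectation",
    "singleton_excess_test",
    "proportion_test",
    "false_positive_estimate",
    "diversity",
    "percent",
]


def harmonic_number(n: int) -> float:
    """Sum of 1/i for i = 1..n."""
    if n < 1:
        raise ValueError("harmonic number needs n >= 1")
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage with half-up rounding (the convention of printed tables)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    value = Decimal(100 * numerator / denominator)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class SiteFrequencySpectrum:
    """Counts of events by number of carrier genomes (folded not needed:
    duplication presence is polarized by the reference)."""

    n: int  # sampled genomes
    counts: np.ndarray  # counts[i-1] = events carried by i genomes, i=1..n-1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 genomes")
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.n - 1,):
            raise ValueError(f"counts must have length n-1 = {self.n - 1}")

    @classmethod
    def from_frequencies(cls, frequencies, n: int) -> "SiteFrequencySpectrum":
        counts = np.zeros(n - 1, dtype=int)
        for f in frequencies:
            if not 1 <= f <= n - 1:
                raise ValueError(f"frequency {f} outside 1..{n - 1}")
            counts[f - 1] += 1
        return cls(n=n, counts=counts)

    @property
    def S(self) -> int:
        return int(self.counts.sum())

    @property
    def a(self) -> float:
        """Harmonic normalizer sum_{i=1}^{n-1} 1/i."""
        return harmonic_number(self.n - 1)

    @property
    def singletons(self) -> int:
        return int(self.counts[0])


def neutral_expectation(S: float, n: int) -> dict:
    """Expected neutral frequency-class counts for S events in n genomes.

    Expected count in class i is S/(a*i); classes sum to S exactly.  The
    singleton expectation S/a and its complement are returned both as real
    numbers and rounded integers (matching printed tables).
    """
    if n < 2:
        raise ValueError("need n >= 2 genomes")
    if S < 0:
        raise ValueError("S must be nonnegative")
    a = harmonic_number(n - 1)
    classes = np.arange(1, n)
    expected = S / (a * classes)
    singleton = S / a
    return {
        "a": a,
        "expected_counts": expected,
        "singleton": singleton,
        "nonsingleton": S - singleton,
        "singleton_rounded": int(round(singleton)),
        "nonsingleton_rounded": int(round(S - singleton)),
    }


def singleton_excess_test(
    observed_singleton: int,
    observed_nonsingleton: int,
    n: int,
) -> tuple[float, float]:
    """One-df chi-square of the singleton/nonsingleton split vs neutrality.

    The expected split is (S/a, S - S/a) for S = observed total.  No
    continuity correction.  Returns (statistic, two-sided p).
    """
    S = observed_singleton + observed_nonsingleton
    expectation = neutral_expectation(S, n)
    expected = np.array([expectation["singleton"], expectation["nonsingleton"]])
    if (expected < 5).any():
        warnings.warn("expected class count below 5; chi-square approximation weak")
    observed = np.array([observed_singleton, observed_nonsingleton], dtype=float)
    if S == 0:
        return 0.0, 1.0
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))


def proportion_test(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table -> (odds ratio, p)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    result = stats.fisher_exact(table, alternative="two-sided")
    return float(result.statistic), float(result.pvalue)


def false_positive_estimate(
    n_undetermined: int,
    singletons_undetermined: int,
    n_validated: int,
    singletons_validated: int,
    n_total: int,
) -> float:
    """False-positive percentage from the singleton-proportion contrast.

    Treating in-silico validated calls as true positives, the excess
    singleton proportion of the undetermined set over the validated set,
    scaled by the undetermined count and the total, estimates the fraction
    of false-positive calls:

        N_und * (s_und/N_und - s_val/N_val) / N_total * 100

    Reported as a percentage rounded half-up to one decimal; a negative
    contrast (validated set more singleton-rich) returns 0 with a warning.
    """
    if n_undetermined + n_validated != n_total:
        raise ValueError("undetermined + validated must equal total")
    if min(n_undetermined, n_validated, n_total) <= 0:
        raise ValueError("counts must be positive")
    contrast = (
        singletons_undetermined / n_undetermined - singletons_validated / n_validated
    )
    value = n_undetermined * contrast / n_total
    if value < 0:
        warnings.warn("validated set more singleton-rich; estimate truncated at 0")
        return 0.0
    return percent(value, 1.0)


@dataclass(frozen=True)
class DiversityStats:
    pi: float  # mean pairwise differences per site
    theta_w: float  # Watterson estimator S / (a * L)
    n_segregating: int


def diversity(site_frequencies, n: int, L: int) -> DiversityStats:
    """Nucleotide diversity and Watterson's theta from a biallelic site table.

    ``site_frequencies`` lists, for each segregating site, the number of
    genomes (1..n-1) carrying the derived allele.  pi sums
    2*i*(n-i)/(n*(n-1)) per site; theta_W = S/(a*L).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    freqs = np.asarray(list(site_frequencies), dtype=float)
    if freqs.size and ((freqs < 1) | (freqs > n - 1)).any():
        raise ValueError("site frequencies must be in 1..n-1")
    pi = float((2.0 * freqs * (n - freqs) / (n * (n - 1))).sum() / L)
    S = int(freqs.size)
    theta = S / (harmonic_number(n - 1) * L)
    return DiversityStats(pi=pi, theta_w=theta, n_segregating=S)


def diversity_from_sequences(sequences) -> DiversityStats:
    """pi and theta_W from aligned equal-length haploid sequences."""
    seqs = [s.upper() for s in sequences]
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be aligned to equal length")
    if L == 0:
        raise ValueError("L must be positive")
    freqs = []
    for col in zip(*seqs):
        alleles = sorted(set(col))
        if len(alleles) == 2:
            freqs.append(min(col.count(alleles[0]), col.count(alleles[1])))
        elif len(alleles) > 2:
            # multiallelic sites contribute their pairwise differences to pi
            # but are rare; treated as segregating with minor count 1
            freqs.append(1)
    return diversity(freqs, n, L)
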