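"""Independent brute-force oracles used to check the implementation.

Each oracle is deliberately written with a different algorithmic approach
from the code under test (hash-table counting, naive scans, explicit path
enumeration with Biopython translation) so agreement is informative.
"""

from __future__ import annotations

from itertools import permutations
from math import log

from Bio.Seq import Seq


def kmer_repeat_positions(seq: str, k: int) -> set[int]:
    """All positions whose k-mer occurs more than once (hash-table count)."""
    counts: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        counts.setdefault(seq[i : i + k], []).append(i)
    out: set[int] = set()
    for positions in counts.values():
        if len(positions) > 1:
            out.update(positions)
    return out


def gap_partition(positions: list[int], gap: int) -> list[list[int]]:
    """Naive O(n^2) partition of sorted positions into <=gap chains."""
    groups: list[list[int]] = []
    for pos in sorted(positions):
        placed = False
        for group in groups:
            if any(abs(pos - other) <= gap for other in group) and pos - group[-1] <= gap:
                group.append(pos)
                placed = True
                break
        if not placed:
            groups.append([pos])
    return groups


def high_copy_regions_bruteforce(
    ratios, run_threshold: float = 1.25, peak_threshold: float = 2.0
) -> list[tuple[int, int]]:
    """Two-pass scan: enumerate all maximal >run runs, keep those with a >peak.

    Returns (start_window, end_window) half-open window index pairs.
    """
    n = len(ratios)
    above = [r > run_threshold for r in ratios]
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return [(i, j) for i, j in runs if max(ratios[i:j]) > peak_threshold]


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_bruteforce(seq_a: str, seq_b: str) -> tuple[float, float, float, float, float, float]:
    """Independent NG86: Biopython translation, explicit path enumeration.

    Returns (dN, dS, N_sites, S_sites, N_diffs, S_diffs).  Stop-codon
    neighbors count as nonsynonymous sites; minimal mutational paths are
    equally weighted, with stop treated as its own residue.
    """
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        if _translate(ca) == "*" or _translate(cb) == "*":
            continue
        for codon in (ca, cb):
            syn = 0.0
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    mutant = codon[:pos] + base + codon[pos + 1 :]
                    if _translate(mutant) == _translate(codon):
                        syn += 1.0
            s_sites += syn / 3.0 / 2.0
            n_sites += (9.0 - syn) / 3.0 / 2.0
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if diff:
            paths = list(permutations(diff))
            for path in paths:
                cur = ca
                for p in path:
                    nxt = cur[:p] + cb[p] + cur[p + 1 :]
                    if _translate(cur) == _translate(nxt):
                        s_diffs += 1.0 / len(paths)
                    else:
                        n_diffs += 1.0 / len(paths)
                    cur = nxt
    def jc(p: float) -> float:
        return 0.0 if p == 0 else -0.75 * log(1 - 4 * p / 3)

    ds = jc(s_diffs / s_sites) if s_sites else 0.0
    dn = jc(n_diffs / n_sites) if n_sites else 0.0
    return dn, ds, n_sites, s_sites, n_diffs, s_diffs


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    from math import comb

    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)
    p_obs = comb(row1, a) * comb(row2, col1 - a) / denom
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p_x = comb(row1, x) * comb(row2, col1 - x) / denom
        if p_x <= p_obs * (1 + 1e-12):
            total += p_x
    return min(1.0, total)
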