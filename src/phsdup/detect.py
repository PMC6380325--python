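"""Duplication evidence independent of PHS.

Three sources of evidence are implemented:

* read depth in 200-bp windows, normalized by the genome-wide mean, with
  high-copy regions called as runs of windows above 1.25x containing at
  least one window above 2x;
* split-read clusters at tandem-duplication breakpoints, filtered on the
  strand-balanced support score ``S1 = (n_forward + 1) * (n_reverse + 1)``
  which must exceed 15;
* qPCR delta-delta-Ct copy numbers, with amplicons above 2^0.5 (~1.41)
  flagged as duplicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "windows_from_bins",
    "HighCopyRegion",
    "SplitReadCluster",
    "TandemDuplication",
    "compute_depth_profile",
    "call_high_copy_regions",
    "call_tandem_duplications",
    "qpcr_copy_number",
    "somatic_phs_upper_bound",
    "QPCR_DUPLICATION_THRESHOLD",
]

QPCR_DUPLICATION_THRESHOLD = 2.0**0.5


@dataclass
class DepthProfile:
    """Window depth ratios for one genome (haploid baseline 1.0).

    ``step`` is the distance between window starts; ``step == window``
    (the default) gives non-overlapping tiling, ``step < window`` gives
    sliding windows as copy-number estimators conventionally use.
    """

    genome_id: int
    window: int
    depth: np.ndarray
    mean_depth: float
    ratios: np.ndarray
    step: int | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.step is None:
            self.step = self.window


def windows_from_bins(
    bin_depth, bin_size: int, window: int = 200, *, step: int | None = None
) -> np.ndarray:
    """Aggregate fine-grained bin depths into (possibly sliding) windows.

    ``bin_depth`` holds per-bp depth averaged over consecutive
    ``bin_size``-bp bins; ``window`` and ``step`` must be multiples of the
    bin size.  Overlapping windows built from the same bins share their
    sampling noise, as windows counted from the same mapped reads do.
    """
    bin_depth = np.asarray(bin_depth, dtype=float)
    step = window if step is None else step
    if window % bin_size or step % bin_size:
        raise ValueError("window and step must be multiples of bin_size")
    per = window // bin_size
    stride = step // bin_size
    if bin_depth.size < per:
        raise ValueError("depth track shorter than one window")
    csum = np.concatenate([[0.0], np.cumsum(bin_depth)])
    sums = csum[per:] - csum[:-per]
    return sums[::stride] / per


@dataclass(frozen=True)
class HighCopyRegion:
    chrom: str
    start: int  # window-aligned, 0-based half-open bp
    end: int
    max_ratio: float
    mean_ratio: float


@dataclass(frozen=True)
class SplitReadCluster:
    chrom: str
    left: int  # 0-based breakpoint pair
    right: int
    n_forward: int
    n_reverse: int

    @property
    def s1(self) -> int:
        """Strand-balanced support score (n+ + 1) * (n- + 1)."""
        return (self.n_forward + 1) * (self.n_reverse + 1)


@dataclass(frozen=True)
class TandemDuplication:
    chrom: str
    start: int
    end: int
    genome_id: int
    s1: int


def compute_depth_profile(
    depth,
    *,
    genome_id: int = 0,
    window: int = 200,
    step: int | None = None,
    repeat_window_mask=None,
    trim_elevated: bool = False,
    trim_factor: float = 1.5,
) -> DepthProfile:
    """Normalize per-window depth by the genome-wide mean.

    ``repeat_window_mask`` (boolean, True = repeat-masked window) excludes
    windows from the mean, mirroring depth estimation on a repeat-masked
    reference; ratios are still reported for every window.

    With ``trim_elevated`` the mean is recomputed iteratively excluding
    windows above ``trim_factor`` times the current mean — the standard
    copy-number normalization step that keeps duplicated regions from
    inflating the single-copy baseline.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.ndim != 1 or depth.size == 0:
        raise ValueError("depth track must be a nonempty 1-d array")
    if repeat_window_mask is not None:
        keep = ~np.asarray(repeat_window_mask, dtype=bool)
        if keep.shape != depth.shape:
            raise ValueError("mask shape mismatch")
    else:
        keep = np.ones(depth.shape, dtype=bool)
    if not keep.any():
        raise ValueError("all windows masked")
    mean = float(depth[keep].mean())
    if trim_elevated:
        for _ in range(20):
            trimmed = keep & (depth < trim_factor * mean)
            if not trimmed.any():
                break
            new_mean = float(depth[trimmed].mean())
            if abs(new_mean - mean) < 1e-9:
                break
            mean = new_mean
    if mean <= 0:
        raise ValueError("genome-wide mean depth is zero")
    return DepthProfile(genome_id, window, depth, mean, depth / mean, step=step)


def call_high_copy_regions(
    profile: DepthProfile,
    chrom: str = "ref",
    *,
    run_threshold: float = 1.25,
    peak_threshold: float = 2.0,
) -> list[HighCopyRegion]:
    """Call high-copy regions from a depth profile.

    A candidate region is a maximal run of consecutive windows whose ratio
    strictly exceeds ``run_threshold``; it is emitted iff it contains at
    least one window whose ratio strictly exceeds ``peak_threshold``.
    Region boundaries snap to window-start edges; with sliding windows the
    region spans from the first window's start to the last window's end.
    """
    ratios = profile.ratios
    window, step = profile.window, profile.step or profile.window
    regions: list[HighCopyRegion] = []
    i, n = 0, ratios.size
    while i < n:
        if ratios[i] > run_threshold:
            j = i
            while j < n and ratios[j] > run_threshold:
                j += 1
            run = ratios[i:j]
            if run.max() > peak_threshold:
                regions.append(
                    HighCopyRegion(
                        chrom=chrom,
                        start=i * step,
                        end=(j - 1) * step + window,
                        max_ratio=float(run.max()),
                        mean_ratio=float(run.mean()),
                    )
                )
            i = j
        else:
            i += 1
    return regions


def call_tandem_duplications(
    clusters,
    *,
    genome_id: int = 0,
    min_s1_exclusive: int = 15,
    reference_length: int | None = None,
) -> list[TandemDuplication]:
    """Filter split-read clusters on the S1 score (strictly greater than 15).

    Accepts ``SplitReadCluster`` objects or ``(left, right, n+, n-)``
    tuples (chromosome then taken as ``"ref"``).
    """
    calls: list[TandemDuplication] = []
    for cluster in clusters:
        if not isinstance(cluster, SplitReadCluster):
            left, right, fwd, rev = cluster
            cluster = SplitReadCluster("ref", left, right, fwd, rev)
        if cluster.left < 0 or cluster.right < cluster.left:
            raise ValueError(f"invalid breakpoints {cluster.left}, {cluster.right}")
        if reference_length is not None and cluster.right > reference_length:
            raise ValueError("breakpoint beyond reference end")
        if cluster.s1 > min_s1_exclusive:
            calls.append(
                TandemDuplication(
                    cluster.chrom, cluster.left, cluster.right, genome_id, cluster.s1
                )
            )
    return sorted(calls, key=lambda t: (t.chrom, t.start, t.end))


def qpcr_copy_number(
    ct_table: pd.DataFrame,
    *,
    calibrator_strain: str,
    reference_amplicon: str = "single_copy",
    duplication_threshold: float = QPCR_DUPLICATION_THRESHOLD,
    z_before_exponentiation: bool = False,
) -> pd.DataFrame:
    """Estimate per-amplicon copy numbers from qPCR Ct values.

    Expects a long-format table with columns ``amplicon``, ``strain``,
    ``replicate``, ``ct`` containing three technical replicates per
    amplicon per strain, including the single-copy normalization fragment
    (``reference_amplicon``) for every strain and all amplicons for the
    calibrator strain.

    Per strain: dCt(amplicon) = mean Ct(amplicon) - mean Ct(single-copy
    fragment); ddCt = dCt(calibrator) - dCt(test); copy number = 2**ddCt,
    flagged as a duplication when strictly above ``duplication_threshold``
    (2**0.5 by default).  ddCt z-scores across amplicons within a strain are
    reported alongside; with ``z_before_exponentiation`` the z-scores are
    exponentiated instead (the alternative reading of the normalization).
    """
    required = {"amplicon", "strain", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")
    strains = ct_table["strain"].unique()
    if calibrator_strain not in strains:
        raise ValueError(f"calibrator strain {calibrator_strain!r} absent from table")

    counts = ct_table.groupby(["strain", "amplicon"])["ct"].count()
    if (counts != 3).any():
        warnings.warn("expected 3 technical replicates per amplicon per strain")

    mean_ct = ct_table.groupby(["strain", "amplicon"])["ct"].mean()
    rows = []
    for strain in strains:
        if (strain, reference_amplicon) not in mean_ct.index:
            raise ValueError(f"single-copy fragment missing for strain {strain!r}")
    calib_ref = mean_ct[(calibrator_strain, reference_amplicon)]
    for strain in strains:
        if strain == calibrator_strain:
            continue
        strain_ref = mean_ct[(strain, reference_amplicon)]
        for amplicon in ct_table.loc[ct_table["strain"] == strain, "amplicon"].unique():
            if amplicon == reference_amplicon:
                continue
            if (calibrator_strain, amplicon) not in mean_ct.index:
                raise ValueError(
                    f"amplicon {amplicon!r} missing for calibrator strain"
                )
            dct_test = mean_ct[(strain, amplicon)] - strain_ref
            dct_cal = mean_ct[(calibrator_strain, amplicon)] - calib_ref
            rows.append(
                {
                    "amplicon": amplicon,
                    "strain": strain,
                    "delta_ct": dct_test,
                    "calibrator_delta_ct": dct_cal,
                    "ddct": dct_cal - dct_test,
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["ddct_z"] = result.groupby("strain")["ddct"].transform(
        lambda x: (x - x.mean()) / x.std(ddof=1) if len(x) > 1 and x.std(ddof=1) > 0
        else x * 0.0
    )
    basis = result["ddct_z"] if z_before_exponentiation else result["ddct"]
    result["copy_number"] = 2.0 ** basis
    result["is_duplication"] = result["copy_number"] > duplication_threshold
    return result


def somatic_phs_upper_bound(
    cell_divisions: int = 15,
    mutation_rate: float = 1.3e-9,
    genome_size: float = 1.1e8,
) -> float:
    """Expected ceiling on heterozygous sites from somatic mutation alone.

    A haploid embryo genome reflects fewer than ~15 cell divisions at a
    somatic rate below 1.3e-9 per site per division over a ~110-Mb genome,
    bounding somatic heterozygous sites well under 3 — so somatic mutation
    cannot explain the observed PHS load.
    """
    return cell_divisions * mutation_rate * genome_size
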