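"""Two-sample peak comparison.

Two layers of comparison between occupancy experiments:

* signal-level unique/common classification — each peak of one set is
  compared against the *signal* of the other experiment in a fixed window
  around the peak center, regardless of whether the other experiment called
  a peak there.  A peak is unique when the rpm ratio reaches a fold
  threshold and an exact conditional binomial test on the window read
  counts is significant;
* binary overlap — peaks from two experiments are "common" when their
  centers lie within a slack distance (default 100 bp), with a
  hypergeometric test for the size of the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome_io import Peak, PeakSet, SignalTrack
from .rounding import percent

__all__ = [
    "ClassificationParams",
    "PeakLabel",
    "ClassificationResult",
    "window_counts",
    "count_ratio_test",
    "classify_peaks",
    "binary_overlap",
    "overlap_summary",
    "hypergeom_overlap_test",
]


@dataclass(frozen=True)
class ClassificationParams:
    """Window width, fold threshold and significance level for uniqueness."""

    window: int = 200
    fold_threshold: float = 4.0
    alpha: float = 1e-4

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PeakLabel:
    peak: Peak
    label: str  # unique_to_A | unique_to_B | common
    fold_observed: float
    p_value: float


@dataclass
class ClassificationResult:
    labels_a: list[PeakLabel]
    labels_b: list[PeakLabel]
    params: ClassificationParams
    summary: dict = field(default_factory=dict)


def window_counts(
    track: SignalTrack, chrom: str, center: int, window: int
) -> tuple[int, float]:
    """Read count and rpm in [center - window//2, center + window//2),
    clipped to the chromosome."""
    if not (0 <= center < track.layout.length(chrom)):
        raise ValueError(f"center {center} outside {chrom}")
    start = center - window // 2
    end = center + window // 2
    count = track.count_in(chrom, start, end)
    return count, 1e6 * count / track.library_size


def count_ratio_test(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Exact two-sided conditional binomial test of equal rpm.

    Conditional on n = count_a + count_b, count_a ~ Binomial(n, q) with
    q = lib_a/(lib_a+lib_b) under the null of equal reads-per-million.
    Two-sided p is twice the smaller one-sided tail, capped at 1; n = 0
    carries no evidence and returns 1.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("negative counts")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    n = count_a + count_b
    if n == 0:
        return 1.0
    q = lib_a / (lib_a + lib_b)
    lower = stats.binom.cdf(count_a, n, q)
    upper = stats.binom.sf(count_a - 1, n, q)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _label_one_side(
    own: PeakSet,
    own_track: SignalTrack,
    other_track: SignalTrack,
    params: ClassificationParams,
    unique_label: str,
) -> list[PeakLabel]:
    labels = []
    # rpm floor at the equivalent of half a read: avoids infinite fold when
    # the other experiment has no reads in the window
    floor_other = 1e6 * 0.5 / other_track.library_size
    for p in own:
        c_own, rpm_own = window_counts(own_track, p.chrom, p.center, params.window)
        c_oth, rpm_oth = window_counts(other_track, p.chrom, p.center, params.window)
        fold = rpm_own / max(rpm_oth, floor_other)
        pval = count_ratio_test(
            c_own, c_oth, own_track.library_size, other_track.library_size
        )
        is_unique = fold >= params.fold_threshold and pval <= params.alpha
        labels.append(
            PeakLabel(p, unique_label if is_unique else "common", fold, pval)
        )
    return labels


def classify_peaks(
    set_a: PeakSet,
    set_b: PeakSet,
    track_a: SignalTrack,
    track_b: SignalTrack,
    params: ClassificationParams = ClassificationParams(),
) -> ClassificationResult:
    """Label every peak of each set unique or common against the other's signal."""
    labels_a = _label_one_side(set_a, track_a, track_b, params, "unique_to_A")
    labels_b = _label_one_side(set_b, track_b, track_a, params, "unique_to_B")
    summary = {}
    for name, labels, uniq in (
        (set_a.name, labels_a, "unique_to_A"),
        (set_b.name, labels_b, "unique_to_B"),
    ):
        n_unique = sum(1 for l in labels if l.label == uniq)
        summary[name] = {
            "total": len(labels),
            "unique": n_unique,
            "common": len(labels) - n_unique,
        }
    return ClassificationResult(labels_a, labels_b, params, summary)


def binary_overlap(
    set_a: PeakSet, set_b: PeakSet, slack: int = 100
) -> tuple[list[tuple[int, int]], int, int]:
    """Center-distance pairing: peaks a, b are common iff
    |center(a) - center(b)| <= slack.

    Returns (pairs as (index_a, index_b), number of A peaks with >=1
    partner, number of B peaks with >=1 partner).  Multi-pairings count a
    peak once in its set's count.
    """
    by_chrom_b: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    centers_b = np.array([p.center for p in set_b], dtype=np.int64)
    idx_b = np.arange(len(set_b.peaks))
    chroms_b = np.array([p.chrom for p in set_b])
    for chrom in np.unique(chroms_b):
        mask = chroms_b == chrom
        order = np.argsort(centers_b[mask], kind="stable")
        by_chrom_b[str(chrom)] = (centers_b[mask][order], idx_b[mask][order])

    pairs: list[tuple[int, int]] = []
    for ia, p in enumerate(set_a.peaks):
        if p.chrom not in by_chrom_b:
            continue
        cb, ib = by_chrom_b[p.chrom]
        lo = np.searchsorted(cb, p.center - slack, side="left")
        hi = np.searchsorted(cb, p.center + slack, side="right")
        for j in range(lo, hi):
            pairs.append((ia, int(ib[j])))
    common_a = len({ia for ia, _ in pairs})
    common_b = len({ib for _, ib in pairs})
    return pairs, common_a, common_b


def overlap_summary(
    common_a: int, total_a: int, common_b: int, total_b: int, decimals: int = 0
) -> tuple[float, float]:
    """Percent of each set with a partner, at the requested precision."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= common_a <= total_a and 0 <= common_b <= total_b):
        raise ValueError("common counts exceed totals")
    return percent(common_a, total_a, decimals), percent(common_b, total_b, decimals)


def hypergeom_overlap_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k successes among n draws from a population of N containing K successes.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent hypergeometric parameters k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))
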