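"""Functional-category annotation of peaks against a gene annotation.

Seven categories partition the genome: promoter (1 kb upstream of the TSS,
strand-aware), TTS (1 kb downstream of the termination site), 5'UTR, 3'UTR,
(coding) exon, intron, and intergenic as the remainder.  When a position
falls in several features of overlapping transcripts, a fixed precedence
promoter > tts > utr5 > utr3 > exon > intron decides — the small, explicitly
windowed classes are never swallowed by introns of neighbouring genes.

Enrichment of a peak set in a category is tested with an exact one-sided
binomial against the genomic background fraction, and two peak sets are
compared per category by the product of two one-sided binomial tails
computed at their pooled ("combined") frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import GeneModel, GenomeLayout, PeakSet

__all__ = [
    "CATEGORIES",
    "AnnotationIndex",
    "CategoryEnrichment",
    "CategoryComparison",
    "classify_location",
    "genome_category_fractions",
    "category_binomial_test",
    "category_enrichment_table",
    "compare_category_between_sets",
    "tss_distance_histogram",
]

# precedence order: earlier wins
CATEGORIES = ("promoter", "tts", "utr5", "utr3", "exon", "intron", "intergenic")
_CAT_CODE = {c: i for i, c in enumerate(CATEGORIES)}
PROMOTER_UPSTREAM = 1000
TTS_DOWNSTREAM = 1000


class AnnotationIndex:
    """Per-chromosome, per-category sorted feature intervals for point queries."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        layout: GenomeLayout,
        promoter_upstream: int = PROMOTER_UPSTREAM,
        tts_downstream: int = TTS_DOWNSTREAM,
    ):
        self.layout = layout
        self.genes = list(genes)
        self.promoter_upstream = promoter_upstream
        self.tts_downstream = tts_downstream
        blocks: dict[str, dict[str, list[tuple[int, int]]]] = {
            c: {cat: [] for cat in CATEGORIES[:-1]} for c in layout.names
        }
        for g in genes:
            L = layout.length(g.chrom)
            b = blocks[g.chrom]

            def clipped(iv: tuple[int, int]) -> tuple[int, int] | None:
                s, e = max(0, iv[0]), min(L, iv[1])
                return (s, e) if s < e else None

            for cat, ivs in (
                ("promoter", [g.promoter(promoter_upstream)]),
                ("tts", [g.tts_region(tts_downstream)]),
                ("utr5", g.utr5_blocks()),
                ("utr3", g.utr3_blocks()),
                ("exon", g.coding_exon_blocks()),
                ("intron", g.intron_blocks()),
            ):
                for iv in ivs:
                    civ = clipped(iv)
                    if civ:
                        b[cat].append(civ)
        # merge and freeze as arrays for searchsorted queries
        self._index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for chrom, per_cat in blocks.items():
            self._index[chrom] = {}
            for cat, ivs in per_cat.items():
                merged = _merge(ivs)
                self._index[chrom][cat] = (
                    np.array([s for s, _ in merged], dtype=np.int64),
                    np.array([e for _, e in merged], dtype=np.int64),
                )

    def _in_category(self, chrom: str, pos: int, cat: str) -> bool:
        starts, ends = self._index[chrom][cat]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def classify(self, chrom: str, pos: int) -> str:
        for cat in CATEGORIES[:-1]:
            if self._in_category(chrom, pos, cat):
                return cat
        return "intergenic"

    def classify_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized classification of many positions on one chromosome."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), len(CATEGORIES) - 1, dtype=np.int8)
        undecided = np.ones(len(positions), dtype=bool)
        for code, cat in enumerate(CATEGORIES[:-1]):
            starts, ends = self._index[chrom][cat]
            if len(starts) == 0:
                continue
            i = np.searchsorted(starts, positions, side="right") - 1
            hit = (i >= 0) & (positions < ends[np.clip(i, 0, None)])
            newly = hit & undecided
            out[newly] = code
            undecided &= ~hit
        return np.array(CATEGORIES)[out]


def _merge(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(blocks):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def classify_location(
    chrom: str, pos: int, index: AnnotationIndex
) -> str:
    """Category of a single position under the fixed precedence."""
    return index.classify(chrom, pos)


def genome_category_fractions(
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    tts_downstream: int = TTS_DOWNSTREAM,
) -> dict[str, float]:
    """bp fraction of the genome in each category.

    Paints a per-base label array per chromosome in reverse precedence order
    (so higher-precedence features overwrite), then counts — an
    implementation deliberately different from the point-query path so the
    two can cross-check each other.
    """
    counts = {cat: 0 for cat in CATEGORIES}
    for chrom, L in layout:
        arr = np.full(L, _CAT_CODE["intergenic"], dtype=np.int8)
        chrom_genes = [g for g in genes if g.chrom == chrom]
        for cat in reversed(CATEGORIES[:-1]):
            for g in chrom_genes:
                if cat == "promoter":
                    ivs = [g.promoter(promoter_upstream)]
                elif cat == "tts":
                    ivs = [g.tts_region(tts_downstream)]
                elif cat == "utr5":
                    ivs = g.utr5_blocks()
                elif cat == "utr3":
                    ivs = g.utr3_blocks()
                elif cat == "exon":
                    ivs = g.coding_exon_blocks()
                else:
                    ivs = g.intron_blocks()
                for s, e in ivs:
                    arr[max(0, s) : min(L, e)] = _CAT_CODE[cat]
        binc = np.bincount(arr, minlength=len(CATEGORIES))
        for cat, code in _CAT_CODE.items():
            counts[cat] += int(binc[code])
    total = layout.total_length
    return {cat: counts[cat] / total for cat in CATEGORIES}


def category_binomial_test(k: int, n_total: int, p0: float, side: str = "greater") -> float:
    """Exact one-sided binomial tail for k category peaks out of n_total."""
    if not (0 <= k <= n_total):
        raise ValueError("k outside [0, n_total]")
    if not (0 < p0 < 1):
        raise ValueError("background fraction must lie strictly in (0, 1)")
    if side == "greater":
        return float(stats.binom.sf(k - 1, n_total, p0))
    if side == "less":
        return float(stats.binom.cdf(k, n_total, p0))
    raise ValueError(f"side must be 'greater' or 'less', got {side!r}")


@dataclass(frozen=True)
class CategoryEnrichment:
    category: str
    peak_fraction: float
    genome_fraction: float
    fold: float
    p_value: float
    n_peaks: int
    side: str


def category_enrichment_table(
    peakset: PeakSet,
    index: AnnotationIndex,
    genome_fractions: dict[str, float] | None = None,
) -> list[CategoryEnrichment]:
    """Per-category peak-center fractions vs genomic background, with
    one-sided binomial p in the direction of the observed deviation."""
    if len(peakset) == 0:
        raise ValueError("empty peak set")
    if genome_fractions is None:
        genome_fractions = genome_category_fractions(index.genes, index.layout,
                                                     index.promoter_upstream,
                                                     index.tts_downstream)
    labels: list[str] = []
    by_chrom: dict[str, list[int]] = {}
    for p in peakset:
        by_chrom.setdefault(p.chrom, []).append(p.center)
    cat_counts = {cat: 0 for cat in CATEGORIES}
    for chrom, centers in by_chrom.items():
        for cat in index.classify_many(chrom, np.array(centers)):
            cat_counts[str(cat)] += 1
    n = len(peakset)
    rows = []
    for cat in CATEGORIES:
        k = cat_counts[cat]
        frac = k / n
        g = genome_fractions[cat]
        fold = frac / g if g > 0 else float("inf")
        side = "greater" if frac >= g else "less"
        p = category_binomial_test(k, n, g, side) if 0 < g < 1 else float("nan")
        rows.append(CategoryEnrichment(cat, frac, g, fold, p, k, side))
    return rows


@dataclass(frozen=True)
class CategoryComparison:
    """Counts for one category in two peak sets sharing a pooled null."""

    m: int        # total peaks, set 1
    n: int        # total peaks, set 2
    m_prime: int  # set-1 peaks in the category
    n_prime: int  # set-2 peaks in the category

    def __post_init__(self):
        if not (0 <= self.m_prime <= self.m and 0 <= self.n_prime <= self.n):
            raise ValueError("category counts exceed totals")
        if self.m + self.n == 0:
            raise ValueError("both sets empty")

    @property
    def combined_frequency(self) -> float:
        return (self.m_prime + self.n_prime) / (self.m + self.n)


def compare_category_between_sets(cc: CategoryComparison) -> float:
    """Product-of-binomials comparison of one category between two sets.

    Under the null the two sets form a single population with combined
    frequency f = (m'+n')/(m+n); the statistic is the product of the two
    one-sided binomial tails of (m, m') and (n, n') at f, each taken in the
    direction of that set's deviation from f, capped at 1.  When a set sits
    exactly at f its tail is taken on the 'greater' side (it is >= 0.5
    either way).
    """
    f = cc.combined_frequency
    if f in (0.0, 1.0):
        return 1.0  # both sets at the boundary: no deviation to test
    side_m = "greater" if cc.m_prime / cc.m >= f else "less"
    side_n = "greater" if cc.n_prime / cc.n >= f else "less"
    p = category_binomial_test(cc.m_prime, cc.m, f, side_m) * category_binomial_test(
        cc.n_prime, cc.n, f, side_n
    )
    return float(min(1.0, p))


def tss_distance_histogram(
    peakset: PeakSet,
    genes: Sequence[GeneModel],
    bin_size: int = 500,
    max_distance: int = 10000,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed peak-center distances to the nearest TSS.

    Sign is strand-aware: negative = upstream of the TSS.  Each peak
    contributes once (nearest TSS only); peaks farther than max_distance
    are dropped.  Returns (bin_edges, counts) with half-open bins
    [edge, edge+bin_size); a peak exactly on a TSS lands in [0, bin_size).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not genes:
        raise ValueError("no genes")
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {g.chrom for g in genes}:
        items = sorted((g.tss, 1 if g.strand == "+" else -1) for g in genes if g.chrom == chrom)
        tss_by_chrom[chrom] = (
            np.array([t for t, _ in items], dtype=np.int64),
            np.array([s for _, s in items], dtype=np.int64),
        )
    edges = np.arange(-max_distance, max_distance + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for p in peakset:
        if p.chrom not in tss_by_chrom:
            continue
        tss, signs = tss_by_chrom[p.chrom]
        i = int(np.searchsorted(tss, p.center))
        # nearest of the two flanking TSSs; tie toward the left (lower coord)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                d = abs(p.center - tss[j])
                if best is None or d < best[0]:
                    best = (d, j)
        if best is None:
            continue
        j = best[1]
        signed = (p.center - tss[j]) * signs[j]
        if -max_distance <= signed < max_distance:
            counts[(signed + max_distance) // bin_size] += 1
    return edges, counts
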