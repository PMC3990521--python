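"""Seeded synthetic-data generators for every input the pipeline consumes.

The generator emulates the downstream products of a two-experiment ChIP-seq
study on a small genome: a random sequence, non-overlapping gene models, a
chromatin-state segmentation with controlled per-state coverage, two peak
sets with planted common/unique structure (unique loci exist in BOTH signal
tracks at a configured intensity ratio, mirroring the intensity-ratio
definition of uniqueness rather than presence/absence), Poisson read noise
deposited into per-base signal tracks, motifs planted at a configured
fraction of peaks, and differentially-expressed gene lists with a
configured peak-overlap fraction.  Every stage records its ground truth so
downstream classification, motif association and expression linkage can be
scored exactly.

Peak intervals are scrubbed of *unplanted* motif occurrences so that the
planted motif fraction is recoverable exactly; outside peaks the background
sequence keeps whatever motif words arise by chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression_link import map_peaks_to_genes
from .genome_io import (
    GeneList,
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    Peak,
    PeakSet,
    SignalTrack,
    StateSegmentation,
)
from .motif import IUPAC_CODES, IUPACMotif

__all__ = ["SimulationConfig", "SimulationResult", "simulate_genome",
           "simulate_genes", "simulate_segmentation", "simulate_peaksets",
           "simulate_gene_lists", "simulate_all", "CHROMHMM15_LABELS",
           "CHROMHMM15_FRACTIONS"]

# 15-state chromHMM-style label set with genome fractions shaped like a
# fibroblast segmentation (promoters and enhancers rare, heterochromatin
# dominant), normalized to sum to 1.
CHROMHMM15_LABELS = (
    "1_Active_Promoter", "2_Weak_Promoter", "3_Poised_Promoter",
    "4_Strong_Enhancer", "5_Strong_Enhancer", "6_Weak_Enhancer",
    "7_Weak_Enhancer", "8_Insulator", "9_Txn_Transition",
    "10_Txn_Elongation", "11_Weak_Txn", "12_Repressed",
    "13_Heterochrom_lo", "14_Repetitive_CNV", "15_Repetitive_CNV",
)
_RAW = np.array([0.6, 0.5, 0.1, 0.3, 1.3, 0.8, 1.9, 0.9, 0.5, 4.4, 12.8,
                 6.4, 65.0, 0.1, 0.1])
CHROMHMM15_FRACTIONS = tuple(float(x) for x in _RAW / _RAW.sum())

# stage tags mixed into the seed so each generator is independently
# deterministic under the config seed
_STAGE = {"genome": 1, "genes": 2, "segmentation": 3, "peaks": 4, "lists": 5}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (2000, 6000)
    max_exons: int = 5
    n_peaks_a: int = 120
    n_peaks_b: int = 80
    frac_shared: float = 0.5
    unique_fold: float = 8.0
    peak_width: int = 200
    min_peak_spacing: int = 800
    state_labels: tuple[str, ...] = CHROMHMM15_LABELS
    state_fractions: tuple[float, ...] = CHROMHMM15_FRACTIONS
    seg_mean_length: int = 1000
    motif_string: str = "TGASTCA"
    frac_peaks_with_motif: float = 0.4
    background_gc: float = 0.41
    reads_per_peak: float = 200.0
    background_reads: int = 20_000
    library_size_a: int = 1_000_000
    library_size_b: int = 1_000_000
    list_size: int = 20
    frac_list_occupied: float = 0.35
    promoter_up: int = 1000

    def __post_init__(self):
        for name in ("frac_shared", "frac_peaks_with_motif", "background_gc",
                     "frac_list_occupied"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.unique_fold <= 1:
            raise ValueError("unique_fold must exceed 1")
        if len(self.state_labels) != len(self.state_fractions):
            raise ValueError("state_labels and state_fractions differ in length")
        if abs(sum(self.state_fractions) - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")
        if len(self.motif_string) > self.peak_width:
            raise ValueError("motif longer than peak width")
        IUPACMotif("config", self.motif_string)  # validates characters
        if self.n_peaks_a <= 0 or self.n_peaks_b <= 0:
            raise ValueError("peak counts must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE[stage]])


def layout_from_config(config: SimulationConfig) -> GenomeLayout:
    return GenomeLayout(
        [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)]
    )


def simulate_genome(config: SimulationConfig) -> tuple[GenomeLayout, dict[str, str]]:
    """i.i.d. bases at the configured GC content; deterministic under seed."""
    rng = _rng(config, "genome")
    layout = layout_from_config(config)
    gc = config.background_gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {}
    for chrom, L in layout:
        arr = rng.choice(bases, size=L, p=probs)
        seqs[chrom] = arr.tobytes().decode("ascii")
    return layout, seqs


def _partition_place(
    rng: np.random.Generator, region_length: int, widths: list[int], gap: int
) -> list[int]:
    """Non-overlapping placement of len(widths) intervals with >= gap bp
    between them, uniform over admissible configurations."""
    n = len(widths)
    used = sum(widths) + gap * (n + 1)
    free = region_length - used
    if free < 0:
        raise ValueError(
            f"cannot place {n} intervals of total width {sum(widths)} in "
            f"{region_length} bp; reduce the count"
        )
    offsets = np.sort(rng.integers(0, free + 1, size=n))
    starts = []
    acc = gap
    for i, w in enumerate(widths):
        starts.append(int(offsets[i]) + acc)
        acc += w + gap
    return starts


def _allocate_counts(rng: np.random.Generator, layout: GenomeLayout, n: int) -> dict[str, int]:
    """Spread n items over chromosomes proportional to length (largest remainder)."""
    lengths = np.array([L for _, L in layout], dtype=float)
    quota = n * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    return {name: int(c) for (name, _), c in zip(layout, counts)}


def simulate_genes(layout: GenomeLayout, config: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping coding genes with 1..max_exons exons and a CDS whose
    bounds lie on exonic sequence; strands drawn uniformly."""
    rng = _rng(config, "genes")
    if config.n_genes == 0:
        return []
    per_chrom = _allocate_counts(rng, layout, config.n_genes)
    lo, hi = config.gene_length_range
    genes: list[GeneModel] = []
    for chrom, L in layout:
        n = per_chrom[chrom]
        if n == 0:
            continue
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n)]
        starts = _partition_place(rng, L, lengths, gap=200)
        for tx_start, glen in zip(starts, lengths):
            tx_end = tx_start + glen
            exons = _random_exons(rng, tx_start, tx_end, config.max_exons)
            cds_start, cds_end = _random_cds(rng, exons)
            genes.append(
                GeneModel(
                    gene_id=f"gene{len(genes) + 1:04d}",
                    chrom=chrom,
                    strand="+" if rng.integers(2) == 0 else "-",
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exons=exons,
                )
            )
    return genes


def _random_exons(
    rng: np.random.Generator, tx_start: int, tx_end: int, max_exons: int
) -> tuple[tuple[int, int], ...]:
    glen = tx_end - tx_start
    k = int(rng.integers(1, max_exons + 1))
    if k == 1 or glen < 2 * k * 100:
        return ((tx_start, tx_end),)
    # 2k-1 alternating exon/intron blocks, each >= 60 bp
    for _ in range(30):
        cuts = np.sort(rng.choice(np.arange(60, glen - 60), size=2 * k - 2, replace=False))
        blocks = np.diff(np.concatenate([[0], cuts, [glen]]))
        if (blocks >= 60).all():
            break
    else:
        return ((tx_start, tx_end),)
    exons = []
    pos = tx_start
    for i, b in enumerate(blocks):
        if i % 2 == 0:
            exons.append((pos, pos + int(b)))
        pos += int(b)
    return tuple(exons)


def _random_cds(
    rng: np.random.Generator, exons: tuple[tuple[int, int], ...]
) -> tuple[int, int]:
    exonic = sum(e - s for s, e in exons)
    if exonic < 40:
        return exons[0][0], exons[-1][1]
    a = int(rng.integers(0, exonic // 4))
    b = int(rng.integers(3 * exonic // 4, exonic))

    def genomic(offset: int) -> int:
        for s, e in exons:
            if offset < e - s:
                return s + offset
            offset -= e - s
        return exons[-1][1]

    return genomic(a), genomic(b - 1) + 1


def simulate_segmentation(
    layout: GenomeLayout, config: SimulationConfig
) -> StateSegmentation:
    """Exponential-length segments with labels drawn with probability
    proportional to each label's remaining bp quota, so realized coverage
    tracks the target fractions."""
    rng = _rng(config, "segmentation")
    labels = list(config.state_labels)
    fractions = np.array(config.state_fractions)
    segments: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, L in layout:
        quota = fractions * L
        segs: list[tuple[int, int, str]] = []
        pos = 0
        while pos < L:
            length = int(rng.exponential(config.seg_mean_length))
            length = max(100, min(length, 10 * config.seg_mean_length))
            length = min(length, L - pos)
            remaining = np.clip(quota, 0, None)
            if remaining.sum() <= 0:
                i = int(np.argmax(quota))
            else:
                i = int(rng.choice(len(labels), p=remaining / remaining.sum()))
            quota[i] -= length
            if segs and segs[-1][2] == labels[i]:
                segs[-1] = (segs[-1][0], pos + length, labels[i])
            else:
                segs.append((pos, pos + length, labels[i]))
            pos += length
        segments[chrom] = segs
    return StateSegmentation(layout, segments, labels)


@dataclass
class SimulationResult:
    config: SimulationConfig
    layout: GenomeLayout
    sequences: dict[str, str]
    genes: list[GeneModel]
    segmentation: StateSegmentation
    peakset_a: PeakSet
    peakset_b: PeakSet
    track_a: SignalTrack
    track_b: SignalTrack
    truth: pd.DataFrame
    gene_list_up: GeneList | None = None
    gene_list_down: GeneList | None = None
    list_truth: pd.DataFrame | None = None


def _sample_word(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        sorted(IUPAC_CODES[c])[int(rng.integers(len(IUPAC_CODES[c])))] for c in pattern
    )


def _scrub_interval(
    rng: np.random.Generator, seq: list[str], motif: IUPACMotif, lo: int, hi: int
) -> None:
    """Remove every motif occurrence (either strand) whose word starts in
    [lo, hi) by mutating the middle base to one outside the allowed set."""
    L = len(motif)
    patterns = [motif.pattern, motif.reverse_complement]
    for _ in range(20):  # iterate: a fix could create a new overlapping match
        dirty = False
        for pat in patterns:
            for s in range(max(0, lo), min(len(seq) - L + 1, hi)):
                word = "".join(seq[s : s + L])
                if all(b in IUPAC_CODES[c] for b, c in zip(word, pat)):
                    mid = s + L // 2
                    allowed_f = IUPAC_CODES[motif.pattern[L // 2]]
                    allowed_r = IUPAC_CODES[motif.reverse_complement[L // 2]]
                    choices = sorted(set("ACGT") - allowed_f - allowed_r)
                    if not choices:  # fully degenerate position: move over one
                        mid = s
                        choices = sorted(
                            set("ACGT")
                            - IUPAC_CODES[motif.pattern[0]]
                            - IUPAC_CODES[motif.reverse_complement[0]]
                        )
                    seq[mid] = choices[int(rng.integers(len(choices)))]
                    dirty = True
        if not dirty:
            return


def simulate_peaksets(
    layout: GenomeLayout,
    sequences: dict[str, str],
    config: SimulationConfig,
) -> tuple[PeakSet, PeakSet, SignalTrack, SignalTrack, pd.DataFrame, dict[str, str]]:
    """Planted common/unique peak loci with Poisson reads and motifs.

    Returns (peakset A, peakset B, track A, track B, truth table, sequences
    with motifs planted).  Truth has one row per locus: its interval, label
    (common / unique_A / unique_B), expected read counts in each track,
    motif presence, and the peak's index within each set (-1 when the locus
    was not called in that set).
    """
    rng = _rng(config, "peaks")
    n_common = round(config.frac_shared * min(config.n_peaks_a, config.n_peaks_b))
    n_ua = config.n_peaks_a - n_common
    n_ub = config.n_peaks_b - n_common
    n_loci = n_common + n_ua + n_ub
    w = config.peak_width

    per_chrom = _allocate_counts(rng, layout, n_loci)
    loci: list[tuple[str, int]] = []
    for chrom, L in layout:
        n = per_chrom[chrom]
        if n == 0:
            continue
        starts = _partition_place(
            rng, L, [w] * n, gap=max(0, config.min_peak_spacing - w)
        )
        loci.extend((chrom, s) for s in starts)

    label_pool = (
        ["common"] * n_common + ["unique_A"] * n_ua + ["unique_B"] * n_ub
    )
    labels = list(rng.permutation(label_pool))

    n_motif = round(config.frac_peaks_with_motif * n_loci)
    motif_mask = np.zeros(n_loci, dtype=bool)
    motif_mask[rng.choice(n_loci, size=n_motif, replace=False)] = True

    # plant/scrub motifs
    motif = IUPACMotif("planted", config.motif_string)
    Lm = len(motif)
    seq_lists = {c: list(s) for c, s in sequences.items()}
    for i, (chrom, start) in enumerate(loci):
        _scrub_interval(rng, seq_lists[chrom], motif, start - Lm + 1, start + w)
        if motif_mask[i]:
            center = start + w // 2
            word = _sample_word(rng, motif.pattern)
            pos = center - Lm // 2
            seq_lists[chrom][pos : pos + Lm] = list(word)
    sequences_out = {c: "".join(s) for c, s in seq_lists.items()}

    # expected read counts per locus per track; library-size-proportional so
    # "common" means equal rpm even with unequal libraries
    lib_ref = max(config.library_size_a, config.library_size_b)
    scale_a = config.library_size_a / lib_ref
    scale_b = config.library_size_b / lib_ref
    r = config.reads_per_peak
    lam_a = np.empty(n_loci)
    lam_b = np.empty(n_loci)
    for i, lab in enumerate(labels):
        if lab == "common":
            lam_a[i], lam_b[i] = r * scale_a, r * scale_b
        elif lab == "unique_A":
            lam_a[i], lam_b[i] = r * scale_a, r / config.unique_fold * scale_b
        else:
            lam_a[i], lam_b[i] = r / config.unique_fold * scale_a, r * scale_b

    track_a = SignalTrack(layout, config.library_size_a)
    track_b = SignalTrack(layout, config.library_size_b)
    for track, lam in ((track_a, lam_a), (track_b, lam_b)):
        for i, (chrom, start) in enumerate(loci):
            n_reads = int(rng.poisson(lam[i]))
            if n_reads:
                track.add_reads(chrom, rng.integers(start, start + w, size=n_reads))
        # uniform background spread across the genome
        bg_per_chrom = _allocate_counts(rng, layout, config.background_reads)
        for chrom, L in layout:
            nb = bg_per_chrom[chrom]
            if nb:
                track.add_reads(chrom, rng.integers(0, L, size=nb))

    def make_peak(track: SignalTrack, chrom: str, start: int) -> Peak:
        iv = GenomicInterval(chrom, start, start + w)
        return Peak(iv, summit=iv.center, rpm=track.rpm_in(chrom, start, start + w))

    rows = []
    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    for i, (chrom, start) in enumerate(loci):
        lab = labels[i]
        ia = ib = -1
        if lab in ("common", "unique_A"):
            ia = len(peaks_a)
            peaks_a.append(make_peak(track_a, chrom, start))
        if lab in ("common", "unique_B"):
            ib = len(peaks_b)
            peaks_b.append(make_peak(track_b, chrom, start))
        rows.append(
            dict(locus=i, chrom=chrom, start=start, end=start + w, label=lab,
                 has_motif=bool(motif_mask[i]), lam_a=lam_a[i], lam_b=lam_b[i],
                 idx_a=ia, idx_b=ib)
        )
    truth = pd.DataFrame(rows)
    set_a = PeakSet("setA", peaks_a, total_mapped_reads=config.library_size_a)
    set_b = PeakSet("setB", peaks_b, total_mapped_reads=config.library_size_b)
    return set_a, set_b, track_a, track_b, truth, sequences_out


def simulate_gene_lists(
    genes: list[GeneModel],
    peakset: PeakSet,
    config: SimulationConfig,
) -> tuple[GeneList, GeneList, pd.DataFrame]:
    """Two gene lists ("up" and "down") in which a configured fraction of
    members overlap peaks (body or promoter).  The lists are disjoint when
    the occupied/unoccupied gene pools are large enough; otherwise each is
    sampled independently and may share members."""
    rng = _rng(config, "lists")
    occupancy = map_peaks_to_genes(peakset, genes, promoter_up=config.promoter_up)
    occupied = sorted(o.gene_id for o in occupancy if o.n_peaks > 0)
    free = sorted(o.gene_id for o in occupancy if o.n_peaks == 0)
    k = round(config.frac_list_occupied * config.list_size)
    if k > len(occupied) or config.list_size - k > len(free):
        raise ValueError(
            f"requested overlap fraction unachievable: need {k} occupied "
            f"/ {config.list_size - k} unoccupied genes, have "
            f"{len(occupied)} / {len(free)}"
        )
    used: set[str] = set()

    def pick(pool: list[str], count: int) -> set[str]:
        if count == 0:
            return set()
        fresh = [g for g in pool if g not in used]
        source = fresh if len(fresh) >= count else pool
        chosen = set(rng.choice(source, size=count, replace=False))
        used.update(chosen)
        return chosen

    up = GeneList("up", pick(occupied, k) | pick(free, config.list_size - k))
    down = GeneList("down", pick(occupied, k) | pick(free, config.list_size - k))
    occupied_set = set(occupied)
    rows = [
        dict(list=name, gene_id=g, occupied=g in occupied_set)
        for name, gl in (("up", up), ("down", down))
        for g in sorted(gl.gene_ids)
    ]
    return up, down, pd.DataFrame(rows)


def simulate_all(config: SimulationConfig, with_lists: bool = True) -> SimulationResult:
    """Run every generator stage; the one-call entry point for tests and
    the analysis drivers."""
    layout, sequences = simulate_genome(config)
    genes = simulate_genes(layout, config)
    segmentation = simulate_segmentation(layout, config)
    set_a, set_b, track_a, track_b, truth, sequences = simulate_peaksets(
        layout, sequences, config
    )
    result = SimulationResult(
        config=config, layout=layout, sequences=sequences, genes=genes,
        segmentation=segmentation, peakset_a=set_a, peakset_b=set_b,
        track_a=track_a, track_b=track_b, truth=truth,
    )
    if with_lists and genes:
        up, down, list_truth = simulate_gene_lists(genes, set_a, config)
        result.gene_list_up = up
        result.gene_list_down = down
        result.list_truth = list_truth
    return result
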