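"""Domain types and readers/writers for the formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) throughout the
package; refFlat txStart is already 0-based so it is taken as-is.  Every
reader validates against a :class:`GenomeLayout` — out-of-bounds records
are errors, never silently clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "SignalTrack",
    "GeneModel",
    "StateSegmentation",
    "GeneList",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_peak_table",
    "write_peak_table",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_state_segmentation",
    "write_state_segmentation",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_track",
    "write_track",
    "read_gene_list",
    "write_gene_list",
]


class GenomeLayout:
    """Ordered chromosome names and lengths; the coordinate frame for everything."""

    def __init__(self, chroms: Sequence[tuple[str, int]]):
        if not chroms:
            raise ValueError("no chromosomes")
        names = [c for c, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in chroms:
            if int(length) <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")
        self._order = list(names)
        self._lengths = {c: int(n) for c, n in chroms}

    @property
    def names(self) -> list[str]:
        return list(self._order)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self):
        return ((c, self._lengths[c]) for c in self._order)

    def __len__(self) -> int:
        return len(self._order)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        L = self.length(chrom)
        if not (0 <= start < end <= L):
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of bounds (chrom length {L})"
            )

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and list(self) == list(other)

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self)} chroms, {self.total_length} bp)"


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def center(self) -> int:
        """Midpoint, floor((start+end)/2); the anchor for all center-based assignment."""
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called occupancy interval with its summit and rpm intensity."""

    interval: GenomicInterval
    summit: int
    rpm: float

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit outside peak interval")
        if self.rpm < 0:
            raise ValueError("negative rpm")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def center(self) -> int:
        return self.interval.center


@dataclass
class PeakSet:
    name: str
    peaks: list[Peak]
    total_mapped_reads: int = 1

    def __post_init__(self):
        if not self.name:
            raise ValueError("PeakSet name must be non-empty")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def validate(self, layout: GenomeLayout) -> None:
        for p in self.peaks:
            layout.check_interval(p.chrom, p.interval.start, p.interval.end)


class SignalTrack:
    """Per-chromosome read-start counts at fixed bin width.

    rpm over an interval is 1e6 * (reads in interval) / library_size.
    """

    def __init__(
        self,
        layout: GenomeLayout,
        library_size: int,
        bin_width: int = 1,
        counts: dict[str, np.ndarray] | None = None,
    ):
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.layout = layout
        self.library_size = int(library_size)
        self.bin_width = int(bin_width)
        if counts is None:
            counts = {
                c: np.zeros(-(-n // bin_width), dtype=np.int64) for c, n in layout
            }
        else:
            for c, n in layout:
                expected = -(-n // bin_width)
                if c not in counts or len(counts[c]) != expected:
                    raise ValueError(f"counts for {c} missing or wrong length")
                if (counts[c] < 0).any():
                    raise ValueError("negative counts")
        self.counts = counts

    def add_reads(self, chrom: str, positions: np.ndarray) -> None:
        bins = np.asarray(positions, dtype=np.int64) // self.bin_width
        np.add.at(self.counts[chrom], bins, 1)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Reads whose start lies in [start, end), clipped to the chromosome."""
        L = self.layout.length(chrom)
        start = max(0, start)
        end = min(L, end)
        if start >= end:
            return 0
        b0 = start // self.bin_width
        b1 = -(-end // self.bin_width)
        return int(self.counts[chrom][b0:b1].sum())

    def rpm_in(self, chrom: str, start: int, end: int) -> float:
        return 1e6 * self.count_in(chrom, start, end) / self.library_size

    @property
    def total_reads(self) -> int:
        return int(sum(a.sum() for a in self.counts.values()))


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(blocks):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect_blocks(
    blocks: Iterable[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    return [(max(s, lo), min(e, hi)) for s, e in blocks if max(s, lo) < min(e, hi)]


@dataclass(frozen=True)
class GeneModel:
    """One transcript: strand, tx/CDS bounds, exon blocks.

    UTRs are strand-aware and exon-restricted: on the + strand the 5'UTR is
    the exonic sequence in [tx_start, cds_start) and the 3'UTR the exonic
    sequence in [cds_end, tx_end); on the - strand the two swap.  A
    transcript with cds_start == cds_end (non-coding) has no UTRs and its
    whole exonic extent counts as exon.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: tx/CDS bounds out of order")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e
        if self.exons[0][0] < self.tx_start or self.exons[-1][1] > self.tx_end:
            raise ValueError(f"{self.gene_id}: exons outside tx bounds")

    @property
    def tss(self) -> int:
        """TSS base position (on the transcribed strand)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    def promoter(self, upstream: int = 1000) -> tuple[int, int]:
        """Upstream window ending at the TSS, clipped at 0 (half-open)."""
        if self.strand == "+":
            return (max(0, self.tx_start - upstream), self.tx_start)
        return (self.tx_end, self.tx_end + upstream)

    def tts_region(self, downstream: int = 1000) -> tuple[int, int]:
        """Window from the transcription termination site extending downstream."""
        if self.strand == "+":
            return (self.tx_end, self.tx_end + downstream)
        return (max(0, self.tx_start - downstream), self.tx_start)

    def utr5_blocks(self) -> list[tuple[int, int]]:
        if not self.is_coding:
            return []
        if self.strand == "+":
            return _intersect_blocks(self.exons, self.tx_start, self.cds_start)
        return _intersect_blocks(self.exons, self.cds_end, self.tx_end)

    def utr3_blocks(self) -> list[tuple[int, int]]:
        if not self.is_coding:
            return []
        if self.strand == "+":
            return _intersect_blocks(self.exons, self.cds_end, self.tx_end)
        return _intersect_blocks(self.exons, self.tx_start, self.cds_start)

    def coding_exon_blocks(self) -> list[tuple[int, int]]:
        if not self.is_coding:
            return list(self.exons)
        return _intersect_blocks(self.exons, self.cds_start, self.cds_end)

    def intron_blocks(self) -> list[tuple[int, int]]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 < s1:
                out.append((e0, s1))
        return out


class StateSegmentation:
    """Non-overlapping labeled segments tiling each chromosome exactly."""

    def __init__(
        self,
        layout: GenomeLayout,
        segments: dict[str, list[tuple[int, int, str]]],
        labels: Sequence[str],
    ):
        self.layout = layout
        self.labels = list(labels)
        label_set = set(self.labels)
        self.segments: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, L in layout:
            segs = sorted(segments.get(chrom, []))
            if not segs:
                raise ValueError(f"no segments on {chrom}")
            pos = 0
            for s, e, lab in segs:
                if lab not in label_set:
                    raise ValueError(f"unknown state label {lab!r}")
                if s != pos:
                    kind = "overlap" if s < pos else "gap"
                    raise ValueError(f"{kind} at {chrom}:{pos} (segment starts {s})")
                if e <= s:
                    raise ValueError(f"empty segment at {chrom}:{s}")
                pos = e
            if pos != L:
                raise ValueError(f"{chrom} not fully covered ({pos} < {L})")
            self.segments[chrom] = segs
        self._fractions = self._compute_fractions()
        # searchsorted indices for center assignment
        self._starts = {
            c: np.array([s for s, _, _ in segs], dtype=np.int64)
            for c, segs in self.segments.items()
        }
        self._labels_arr = {
            c: np.array([lab for _, _, lab in segs]) for c, segs in self.segments.items()
        }

    def _compute_fractions(self) -> dict[str, float]:
        bp = {lab: 0 for lab in self.labels}
        for segs in self.segments.values():
            for s, e, lab in segs:
                bp[lab] += e - s
        total = self.layout.total_length
        return {lab: bp[lab] / total for lab in self.labels}

    @property
    def label_fractions(self) -> dict[str, float]:
        """Genome bp fraction per label; sums to 1 exactly by construction."""
        return dict(self._fractions)

    def state_at(self, chrom: str, pos: int) -> str:
        """Label of the segment containing pos (half-open segments)."""
        self.layout.check_interval(chrom, pos, pos + 1)
        i = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        return str(self._labels_arr[chrom][i])

    def states_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self._starts[chrom], positions, side="right") - 1
        return self._labels_arr[chrom][idx]


@dataclass
class GeneList:
    name: str
    gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError(f"gene list {self.name!r} is empty")

    def resolve(self, genes: Sequence[GeneModel]) -> tuple[set[str], set[str]]:
        """Split ids into (resolved, unresolved) against an annotation."""
        known = {g.gene_id for g in genes}
        resolved = self.gene_ids & known
        unresolved = self.gene_ids - known
        if unresolved:
            logger.warning(
                "gene list %s: %d unresolvable ids: %s",
                self.name,
                len(unresolved),
                sorted(unresolved)[:10],
            )
        return resolved, unresolved


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Two-column TSV (name, length) in file order."""
    chroms: list[tuple[str, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        try:
            length = int(parts[1])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer length {parts[1]!r}")
        chroms.append((parts[0], length))
    return GenomeLayout(chroms)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in layout))


PEAK_COLUMNS = ("chrom", "start", "end", "summit", "rpm")


def read_peak_table(
    path: str | Path, layout: GenomeLayout, name: str | None = None,
    total_mapped_reads: int = 1,
) -> PeakSet:
    """Headered 5-column TSV: chrom, start, end, summit, rpm (0-based half-open)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    peaks = []
    for row in df.itertuples(index=False):
        if row.chrom not in layout:
            raise ValueError(f"{path}: unknown chromosome {row.chrom!r}")
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        layout.check_interval(iv.chrom, iv.start, iv.end)
        peaks.append(Peak(iv, int(row.summit), float(row.rpm)))
    return PeakSet(
        name or Path(path).stem, peaks, total_mapped_reads=total_mapped_reads
    )


def write_peak_table(peakset: PeakSet, path: str | Path) -> None:
    lines = ["\t".join(PEAK_COLUMNS)]
    for p in peakset:
        lines.append(
            f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.summit}\t{p.rpm:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_annotation(path: str | Path, layout: GenomeLayout) -> list[GeneModel]:
    """refFlat-like 10-column TSV (no header): geneName, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds."""
    genes: list[GeneModel] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 10:
            raise ValueError(f"{path}:{lineno}: expected 10 fields, got {len(f)}")
        starts = [int(x) for x in f[8].rstrip(",").split(",")]
        ends = [int(x) for x in f[9].rstrip(",").split(",")]
        if len(starts) != int(f[7]) or len(ends) != int(f[7]):
            raise ValueError(f"{path}:{lineno}: exonCount mismatch")
        if f[1] not in layout:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {f[1]!r}")
        gene = GeneModel(
            gene_id=f[0],
            chrom=f[1],
            strand=f[2],
            tx_start=int(f[3]),
            tx_end=int(f[4]),
            cds_start=int(f[5]),
            cds_end=int(f[6]),
            exons=tuple(zip(starts, ends)),
        )
        layout.check_interval(gene.chrom, gene.tx_start, gene.tx_end)
        genes.append(gene)
    if not genes:
        logger.warning("%s: annotation contains no genes", path)
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = []
    for g in genes:
        starts = ",".join(str(s) for s, _ in g.exons) + ","
        ends = ",".join(str(e) for _, e in g.exons) + ","
        lines.append(
            "\t".join(
                [
                    g.gene_id,
                    g.chrom,
                    g.strand,
                    str(g.tx_start),
                    str(g.tx_end),
                    str(g.cds_start),
                    str(g.cds_end),
                    str(len(g.exons)),
                    starts,
                    ends,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_state_segmentation(
    path: str | Path, layout: GenomeLayout, labels: Sequence[str]
) -> StateSegmentation:
    """chromHMM-style dense BED4 (chrom, start, end, label)."""
    segments: dict[str, list[tuple[int, int, str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ValueError(f"{path}:{lineno}: expected BED4")
        segments.setdefault(f[0], []).append((int(f[1]), int(f[2]), f[3]))
    return StateSegmentation(layout, segments, labels)


def write_state_segmentation(seg: StateSegmentation, path: str | Path) -> None:
    lines = []
    for chrom, _ in seg.layout:
        for s, e, lab in seg.segments[chrom]:
            lines.append(f"{chrom}\t{s}\t{e}\t{lab}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path, layout: GenomeLayout | None = None) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if layout is not None:
        for chrom, L in layout:
            if chrom not in seqs:
                raise ValueError(f"{path}: missing sequence for {chrom}")
            if len(seqs[chrom]) != L:
                raise ValueError(
                    f"{path}: {chrom} length {len(seqs[chrom])} != layout {L}"
                )
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    strands: Sequence[str] | None = None,
) -> None:
    """BED3, or BED6 (name, score 0, strand) when names/strands are given."""
    lines = []
    for i, iv in enumerate(intervals):
        if names is not None:
            strand = strands[i] if strands is not None else "."
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{strand}")
        else:
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_track(track: SignalTrack, path: str | Path) -> None:
    """Sparse TSV of non-zero bins: chrom, bin_start, count; header carries
    bin width and library size."""
    lines = [f"#bin_width={track.bin_width}\tlibrary_size={track.library_size}"]
    for chrom, _ in track.layout:
        arr = track.counts[chrom]
        nz = np.nonzero(arr)[0]
        for b in nz:
            lines.append(f"{chrom}\t{b * track.bin_width}\t{arr[b]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_track(path: str | Path, layout: GenomeLayout) -> SignalTrack:
    lines = Path(path).read_text().splitlines()
    header = lines[0]
    if not header.startswith("#bin_width="):
        raise ValueError(f"{path}: missing track header")
    fields = dict(kv.split("=") for kv in header[1:].split("\t"))
    track = SignalTrack(
        layout, library_size=int(fields["library_size"]), bin_width=int(fields["bin_width"])
    )
    for line in lines[1:]:
        if not line.strip():
            continue
        chrom, pos, count = line.split("\t")
        track.counts[chrom][int(pos) // track.bin_width] = int(count)
    return track


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    ids = {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return GeneList(name or Path(path).stem, ids)


def write_gene_list(gene_list: GeneList, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(gene_list.gene_ids)))
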