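"""IUPAC motif scanning and motif/peak-set association.

Built-in motifs are the TPA-response element TGASTCA (S = G or C), the
canonical AP-1/c-Jun binding site, and the AP-1-like variant TGAATCA.
Scanning reports every match position on the forward strand plus
reverse-complement matches mapped back to forward coordinates; positions
are deduplicated per (chrom, start) so palindromic patterns — TGASTCA's
reverse-complement word set equals itself — count once.  Ambiguity codes
expand to explicit {A,C,G,T} classes, so an N in the subject sequence never
matches anything.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .genome_io import PeakSet
from .peak_compare import hypergeom_overlap_test

__all__ = [
    "IUPACMotif",
    "MotifHit",
    "TRE",
    "AP1_LIKE",
    "scan_motif",
    "peaks_with_motif",
    "motif_hypergeom",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class IUPACMotif:
    name: str
    pattern: str

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def reverse_complement(self) -> str:
        return self.pattern.translate(_COMPLEMENT)[::-1]

    def _regex(self, pattern: str) -> re.Pattern:
        body = "".join(f"[{''.join(sorted(IUPAC_CODES[c]))}]" for c in pattern)
        return re.compile(f"(?=({body}))")  # lookahead: overlapping matches

    def matches_word(self, word: str) -> bool:
        word = word.upper()
        return len(word) == len(self.pattern) and all(
            b in IUPAC_CODES[c] for b, c in zip(word, self.pattern)
        )


TRE = IUPACMotif("TRE", "TGASTCA")
AP1_LIKE = IUPACMotif("AP1_like", "TGAATCA")


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int  # forward-strand coordinate of the leftmost matched base
    strand: str
    word: str


def scan_motif(
    sequences: dict[str, str], motif: IUPACMotif, both_strands: bool = True
) -> list[MotifHit]:
    """All motif occurrences, forward plus (optionally) reverse strand,
    deduplicated per (chrom, start); forward wins ties."""
    fwd = motif._regex(motif.pattern)
    rev = motif._regex(motif.reverse_complement)
    hits: list[MotifHit] = []
    for chrom in sequences:
        seq = sequences[chrom].upper()
        seen: set[int] = set()
        for m in fwd.finditer(seq):
            hits.append(MotifHit(chrom, m.start(), "+", m.group(1)))
            seen.add(m.start())
        if both_strands and motif.reverse_complement != motif.pattern:
            for m in rev.finditer(seq):
                if m.start() not in seen:
                    hits.append(MotifHit(chrom, m.start(), "-", m.group(1)))
        elif both_strands:
            # pattern is its own reverse complement under degeneracy: the
            # reverse-strand scan can add nothing
            pass
    hits.sort(key=lambda h: (h.chrom, h.start))
    return hits


def peaks_with_motif(
    peakset: PeakSet,
    sequences: dict[str, str],
    motif: IUPACMotif,
    flank: int = 0,
) -> tuple[PeakSet, list[bool]]:
    """Flag each peak carrying >= 1 motif fully inside
    [start - flank, end + flank); returns (flagged subset, per-peak flags)."""
    hits = scan_motif(sequences, motif)
    starts_by_chrom: dict[str, list[int]] = {}
    for h in hits:
        starts_by_chrom.setdefault(h.chrom, []).append(h.start)
    import numpy as np

    arrs = {c: np.array(sorted(v), dtype=np.int64) for c, v in starts_by_chrom.items()}
    L = len(motif)
    flags = []
    for p in peakset:
        if p.interval.end > len(sequences[p.chrom]):
            raise ValueError(f"peak beyond sequence on {p.chrom}")
        arr = arrs.get(p.chrom)
        if arr is None:
            flags.append(False)
            continue
        lo = p.interval.start - flank
        hi = p.interval.end + flank - L  # hit start must leave room for the word
        i = np.searchsorted(arr, lo, side="left")
        flags.append(bool(i < len(arr) and arr[i] <= hi))
    subset = PeakSet(
        f"{peakset.name}_{motif.name}",
        [p for p, f in zip(peakset.peaks, flags) if f],
        total_mapped_reads=peakset.total_mapped_reads,
    )
    return subset, flags


def motif_hypergeom(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric association of motif-bearing peaks in a
    subset of n peaks against a population of N peaks of which K bear the
    motif."""
    return hypergeom_overlap_test(k, K, n, N)
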