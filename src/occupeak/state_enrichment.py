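"""Chromatin-state enrichment of peak sets.

Peaks are assigned to the chromatin state containing their center; per-state
enrichment is the fraction of peak centers in a state divided by the state's
genome bp fraction, with an exact one-sided binomial p-value taken in the
direction of the deviation (depletion is tested on the 'less' side).  States
can be pooled into named groups (e.g. the two promoter states, the four
enhancer states); group rows are computed on pooled counts and fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .feature_annotation import category_binomial_test
from .genome_io import Peak, PeakSet, StateSegmentation

__all__ = [
    "StateEnrichmentRow",
    "assign_state",
    "filter_top_peaks",
    "state_enrichment_table",
]


@dataclass(frozen=True)
class StateEnrichmentRow:
    state: str
    n_peaks: int
    peak_fraction: float
    genome_fraction: float
    fold: float
    p_value: float
    side: str
    is_group: bool = False


def assign_state(peak: Peak, segmentation: StateSegmentation) -> str:
    """State label of the segment containing the peak center (half-open)."""
    return segmentation.state_at(peak.chrom, peak.center)


def filter_top_peaks(peakset: PeakSet, rpm_min: float = 1.0) -> PeakSet:
    """Retain peaks with rpm strictly above rpm_min, order preserved."""
    return PeakSet(
        f"{peakset.name}_top",
        [p for p in peakset if p.rpm > rpm_min],
        total_mapped_reads=peakset.total_mapped_reads,
    )


def state_enrichment_table(
    peakset: PeakSet,
    segmentation: StateSegmentation,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> list[StateEnrichmentRow]:
    """Per-state (and per-group) peak fraction, genome fraction, fold and
    one-sided binomial p-value."""
    if len(peakset) == 0:
        raise ValueError("empty peak set")
    genome_frac = segmentation.label_fractions
    counts = {lab: 0 for lab in segmentation.labels}
    by_chrom: dict[str, list[int]] = {}
    for p in peakset:
        by_chrom.setdefault(p.chrom, []).append(p.center)
    for chrom, centers in by_chrom.items():
        labs, n = np.unique(
            segmentation.states_at(chrom, np.array(centers, dtype=np.int64)),
            return_counts=True,
        )
        for lab, k in zip(labs, n):
            counts[str(lab)] += int(k)
    n_total = len(peakset)

    def make_row(label: str, k: int, g: float, is_group: bool) -> StateEnrichmentRow:
        frac = k / n_total
        fold = frac / g if g > 0 else float("inf")
        side = "greater" if frac >= g else "less"
        p = category_binomial_test(k, n_total, g, side) if 0 < g < 1 else 1.0
        return StateEnrichmentRow(label, k, frac, g, fold, p, side, is_group)

    rows = [make_row(lab, counts[lab], genome_frac[lab], False) for lab in segmentation.labels]
    if groups:
        for gname, members in groups.items():
            unknown = set(members) - set(segmentation.labels)
            if unknown:
                raise ValueError(f"group {gname!r} references unknown states {sorted(unknown)}")
            k = sum(counts[m] for m in members)
            g = sum(genome_frac[m] for m in members)
            rows.append(make_row(gname, k, g, True))
    return rows
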