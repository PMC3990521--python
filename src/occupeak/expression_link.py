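"""Peak-to-gene linkage and gene-list occupancy summaries.

A peak is linked to a gene when its interval intersects the gene body
extended by a strand-aware promoter window (default 1 kb upstream).  For a
list of differentially expressed genes the summary reports how many listed
genes are occupied, how many distinct binding sites (peaks) those genes
account for, and how many of those binding sites carry a motif — each with
the percentage its natural denominator implies (occupied genes over listed
genes; binding sites over all peaks; motif sites over linked sites).

Significance of the binding-site count comes from a Monte-Carlo null that
re-places the same number of peaks (widths preserved) uniformly on the
genome and converts the observed count to a z-score with a normal
upper-tail p; motif association uses the exact hypergeometric test against
the full peak population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .genome_io import GeneList, GeneModel, GenomeLayout, PeakSet
from .peak_compare import hypergeom_overlap_test
from .rounding import percent

__all__ = [
    "GeneOccupancy",
    "LinkSummary",
    "MCNullResult",
    "map_peaks_to_genes",
    "summarize_gene_list",
    "random_peak_null",
    "gene_list_site_statistic",
]


@dataclass
class GeneOccupancy:
    gene_id: str
    n_peaks: int
    peak_indices: list[int]
    has_motif_peak: bool = False


def _extended_span(g: GeneModel, promoter_up: int) -> tuple[int, int]:
    if g.strand == "+":
        return (max(0, g.tx_start - promoter_up), g.tx_end)
    return (g.tx_start, g.tx_end + promoter_up)


def map_peaks_to_genes(
    peakset: PeakSet,
    genes: Sequence[GeneModel],
    promoter_up: int = 1000,
    motif_flags: Sequence[bool] | None = None,
) -> list[GeneOccupancy]:
    """Every (peak, gene) intersection of peak intervals with
    promoter-extended gene spans; one GeneOccupancy per gene, peaks may link
    several genes."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, p in enumerate(peakset):
        by_chrom.setdefault(p.chrom, []).append((p.interval.start, p.interval.end, i))
    occ = []
    for g in genes:
        s, e = _extended_span(g, promoter_up)
        linked = [
            i for ps, pe, i in by_chrom.get(g.chrom, []) if ps < e and s < pe
        ]
        has_motif = bool(motif_flags) and any(motif_flags[i] for i in linked)
        occ.append(GeneOccupancy(g.gene_id, len(linked), sorted(linked), has_motif))
    return occ


@dataclass
class LinkSummary:
    list_name: str
    n_genes: int
    n_genes_occupied: int
    pct_genes_occupied: float
    n_binding_sites: int
    pct_binding_sites: float  # of all peaks in the set
    n_motif_sites: int
    pct_motif_sites: float  # of the linked binding sites
    n_motif_genes: int
    hypergeom_motif_p: float | None = None
    mc_null: "MCNullResult | None" = None
    unresolved_ids: set[str] = field(default_factory=set)


def summarize_gene_list(
    gene_list: GeneList,
    occupancy: Sequence[GeneOccupancy],
    peakset: PeakSet,
    motif_flags: Sequence[bool] | None = None,
    site_pct_decimals: int = 1,
) -> LinkSummary:
    """Occupancy summary of one gene list against a peak set."""
    known = {o.gene_id for o in occupancy}
    listed = gene_list.gene_ids & known
    unresolved = gene_list.gene_ids - known
    if not listed:
        raise ValueError(f"gene list {gene_list.name!r} resolves to no genes")
    occ_by_id = {o.gene_id: o for o in occupancy}
    occupied = [occ_by_id[g] for g in listed if occ_by_id[g].n_peaks > 0]
    linked_sites: set[int] = set()
    for o in occupied:
        linked_sites.update(o.peak_indices)
    n_sites = len(linked_sites)
    if motif_flags is not None:
        motif_sites = {i for i in linked_sites if motif_flags[i]}
        n_motif_sites = len(motif_sites)
        n_motif_genes = sum(1 for o in occupied if o.has_motif_peak)
        total_motif = sum(bool(f) for f in motif_flags)
        hyper_p = (
            hypergeom_overlap_test(n_motif_sites, total_motif, n_sites, len(peakset))
            if n_sites > 0
            else 1.0
        )
        pct_motif = percent(n_motif_sites, n_sites) if n_sites else 0.0
    else:
        n_motif_sites, n_motif_genes, hyper_p, pct_motif = 0, 0, None, 0.0
    n_listed = len(gene_list.gene_ids)
    return LinkSummary(
        list_name=gene_list.name,
        n_genes=n_listed,
        n_genes_occupied=len(occupied),
        pct_genes_occupied=percent(len(occupied), n_listed),
        n_binding_sites=n_sites,
        pct_binding_sites=percent(n_sites, len(peakset), site_pct_decimals),
        n_motif_sites=n_motif_sites,
        pct_motif_sites=pct_motif,
        n_motif_genes=n_motif_genes,
        hypergeom_motif_p=hyper_p,
        unresolved_ids=unresolved,
    )


@dataclass(frozen=True)
class MCNullResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_normal: float
    p_empirical: float
    n_reps: int
    seed: int


PeakArrays = tuple[np.ndarray, np.ndarray, np.ndarray]  # chrom idx, start, end


def gene_list_site_statistic(
    genes: Sequence[GeneModel],
    gene_list: GeneList,
    layout: GenomeLayout,
    promoter_up: int = 1000,
) -> Callable[[PeakArrays], float]:
    """Statistic: number of peaks intersecting any listed gene's extended span.

    Operates on (chrom_index, start, end) arrays so the Monte-Carlo null can
    avoid building Peak objects per replicate.
    """
    order = {c: i for i, c in enumerate(layout.names)}
    listed = gene_list.gene_ids
    spans: list[tuple[int, int, int]] = []
    for g in genes:
        if g.gene_id in listed:
            s, e = _extended_span(g, promoter_up)
            spans.append((order[g.chrom], s, e))
    span_chrom = np.array([c for c, _, _ in spans], dtype=np.int64)
    span_s = np.array([s for _, s, _ in spans], dtype=np.int64)
    span_e = np.array([e for _, _, e in spans], dtype=np.int64)

    def stat(arrays: PeakArrays) -> float:
        pc, ps, pe = arrays
        hit = np.zeros(len(ps), dtype=bool)
        for ci in np.unique(span_chrom):
            mask = pc == ci
            if not mask.any():
                continue
            ss = span_s[span_chrom == ci]
            ee = span_e[span_chrom == ci]
            # peak overlaps any span: start < span_end and span_start < end
            hit[mask] = (
                (ps[mask][:, None] < ee[None, :]) & (ss[None, :] < pe[mask][:, None])
            ).any(axis=1)
        return float(hit.sum())

    return stat


def peakset_arrays(peakset: PeakSet, layout: GenomeLayout) -> PeakArrays:
    order = {c: i for i, c in enumerate(layout.names)}
    return (
        np.array([order[p.chrom] for p in peakset], dtype=np.int64),
        np.array([p.interval.start for p in peakset], dtype=np.int64),
        np.array([p.interval.end for p in peakset], dtype=np.int64),
    )


def random_peak_null(
    statistic: Callable[[PeakArrays], float],
    peakset: PeakSet,
    layout: GenomeLayout,
    n_reps: int = 1000,
    seed: int = 0,
) -> MCNullResult:
    """Monte-Carlo null re-placing |peakset| peaks uniformly on the genome.

    Each replicate keeps every peak's width, draws its chromosome with
    probability proportional to length and its start uniformly so the peak
    fits, recomputes the statistic, and summarizes the observed value as
    z = (obs - mean)/sd with a normal upper-tail p.  The empirical rank p
    (1 + #{null >= obs}) / (n_reps + 1) is reported alongside.
    """
    if n_reps < 30:
        raise ValueError("n_reps must be at least 30")
    rng = np.random.default_rng(seed)
    widths = np.array([p.interval.width for p in peakset], dtype=np.int64)
    lengths = np.array([L for _, L in layout], dtype=np.int64)
    probs = lengths / lengths.sum()
    observed = statistic(peakset_arrays(peakset, layout))
    null = np.empty(n_reps)
    for r in range(n_reps):
        ci = rng.choice(len(lengths), size=len(widths), p=probs)
        max_start = np.maximum(lengths[ci] - widths, 0)
        starts = (rng.random(len(widths)) * (max_start + 1)).astype(np.int64)
        null[r] = statistic((ci, starts, starts + widths))
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: statistic constant across replicates")
    z = (observed - mean) / sd
    return MCNullResult(
        observed=observed,
        null_mean=mean,
        null_sd=sd,
        z=z,
        p_normal=float(stats.norm.sf(z)),
        p_empirical=float((1 + (null >= observed).sum()) / (n_reps + 1)),
        n_reps=n_reps,
        seed=seed,
    )
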