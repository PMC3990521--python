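"""End-to-end orchestration over synthetic or on-disk inputs.

`run_pipeline` executes simulate -> classify -> annotate -> states -> motif
-> link, writes each stage's tables as TSV under an output directory, and
emits a manifest (seed, parameters, sha256 checksum of every output) so a
re-run with the same configuration is byte-identical.  The `render_*`
functions format the summary tables with the count-and-percentage cell
style used in occupancy reports ("6,398 (36%)").
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import genome_io as gio
from .expression_link import (
    LinkSummary,
    gene_list_site_statistic,
    map_peaks_to_genes,
    random_peak_null,
    summarize_gene_list,
)
from .feature_annotation import (
    AnnotationIndex,
    CategoryComparison,
    category_enrichment_table,
    compare_category_between_sets,
    genome_category_fractions,
    tss_distance_histogram,
)
from .motif import IUPACMotif, peaks_with_motif, scan_motif
from .peak_compare import ClassificationParams, ClassificationResult, classify_peaks
from .rounding import format_count_pct
from .state_enrichment import filter_top_peaks, state_enrichment_table
from .synthetic import SimulationConfig, SimulationResult, simulate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "render_classification_summary",
            "render_overlap_summary", "render_link_summaries",
            "write_simulation_inputs"]

DEFAULT_STATE_GROUPS = {
    "Transcribing_promoter": ("1_Active_Promoter", "2_Weak_Promoter"),
    "All_enhancer": (
        "4_Strong_Enhancer", "5_Strong_Enhancer", "6_Weak_Enhancer", "7_Weak_Enhancer"
    ),
}


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    motif_patterns: tuple[tuple[str, str], ...] = (("TRE", "TGASTCA"),)
    state_groups: dict = field(default_factory=lambda: dict(DEFAULT_STATE_GROUPS))
    promoter_up: int = 1000
    mc_reps: int = 500
    top_rpm_min: float = 1.0
    with_motif: bool = True  # False emulates a run without genome sequence
    tss_bin: int = 500
    tss_range: int = 10000


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_classification_summary(result: ClassificationResult) -> pd.DataFrame:
    """Total / unique / common counts per set with rendered percentages."""
    rows = []
    for name, s in result.summary.items():
        rows.append(
            {
                "peak_set": name,
                "total_peaks": s["total"],
                "unique_peaks": format_count_pct(s["unique"], s["total"]),
                "common_peaks": format_count_pct(s["common"], s["total"]),
            }
        )
    return pd.DataFrame(rows)


def render_overlap_summary(
    name_a: str, name_b: str, common_a: int, total_a: int, common_b: int,
    total_b: int, n_motif_common: int = 0, decimals: int = 1,
) -> pd.DataFrame:
    from .peak_compare import overlap_summary

    pct_a, pct_b = overlap_summary(common_a, total_a, common_b, total_b, decimals)
    row = {
        "peak_set": name_a,
        "common_sites": common_a,
        f"pct_of_{name_a}": pct_a,
        f"pct_of_{name_b}": pct_b,
    }
    if n_motif_common:
        row["motif_in_common"] = format_count_pct(n_motif_common, common_a)
    return pd.DataFrame([row])


def render_link_summaries(summaries: list[LinkSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "gene_list": s.list_name,
                "n_genes": s.n_genes,
                "genes_occupied": format_count_pct(s.n_genes_occupied, s.n_genes),
                "binding_sites": f"{s.n_binding_sites:,} ({s.pct_binding_sites}%)",
                "mc_p": None if s.mc_null is None else s.mc_null.p_normal,
                "motif_sites": format_count_pct(s.n_motif_sites, s.n_binding_sites)
                if s.n_binding_sites
                else "0 (0%)",
                "hypergeom_motif_p": s.hypergeom_motif_p,
            }
        )
    return pd.DataFrame(rows)


def write_simulation_inputs(sim: SimulationResult, outdir: Path) -> list[Path]:
    """Write every generated input in its on-disk exchange format."""
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        written.append(path)

    emit("genome.chrom.sizes", gio.write_chrom_sizes, sim.layout)
    emit("genome.fa", gio.write_fasta, sim.sequences)
    emit("genes.refflat", gio.write_gene_annotation, sim.genes)
    emit("states.bed", gio.write_state_segmentation, sim.segmentation)
    emit("peaks_A.tsv", gio.write_peak_table, sim.peakset_a)
    emit("peaks_B.tsv", gio.write_peak_table, sim.peakset_b)
    emit("track_A.tsv", gio.write_track, sim.track_a)
    emit("track_B.tsv", gio.write_track, sim.track_b)
    truth_path = outdir / "truth.tsv"
    sim.truth.to_csv(truth_path, sep="\t", index=False)
    written.append(truth_path)
    if sim.gene_list_up is not None:
        emit("genes_up.txt", gio.write_gene_list, sim.gene_list_up)
        emit("genes_down.txt", gio.write_gene_list, sim.gene_list_down)
        lt = outdir / "list_truth.tsv"
        sim.list_truth.to_csv(lt, sep="\t", index=False)
        written.append(lt)
    return written


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage on a synthetic dataset and write the report bundle.

    Returns the manifest dict (also written to manifest.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)

    logger.info("stage simulate: seed=%d", config.simulation.seed)
    sim = simulate_all(config.simulation)
    written += write_simulation_inputs(sim, outdir / "inputs")

    logger.info("stage classify")
    cls = classify_peaks(
        sim.peakset_a, sim.peakset_b, sim.track_a, sim.track_b, config.classification
    )
    labels = pd.DataFrame(
        [
            {
                "peak_set": name,
                "chrom": l.peak.chrom,
                "start": l.peak.interval.start,
                "end": l.peak.interval.end,
                "label": l.label,
                "fold": round(l.fold_observed, 4),
                "p_value": l.p_value,
            }
            for name, labs in (
                (sim.peakset_a.name, cls.labels_a),
                (sim.peakset_b.name, cls.labels_b),
            )
            for l in labs
        ]
    )
    save(labels, "peak_labels.tsv")
    save(render_classification_summary(cls), "classification_summary.tsv")

    logger.info("stage annotate")
    index = AnnotationIndex(sim.genes, sim.layout, config.promoter_up)
    genome_frac = genome_category_fractions(sim.genes, sim.layout, config.promoter_up)
    enrich_rows = []
    per_set_counts = {}
    for ps in (sim.peakset_a, sim.peakset_b):
        table = category_enrichment_table(ps, index, genome_frac)
        per_set_counts[ps.name] = {r.category: r.n_peaks for r in table}
        for r in table:
            enrich_rows.append(
                {
                    "peak_set": ps.name, "category": r.category,
                    "pct_peaks": round(100 * r.peak_fraction, 4),
                    "pct_genome": round(100 * r.genome_fraction, 4),
                    "fold": round(r.fold, 4), "side": r.side, "p_value": r.p_value,
                }
            )
    save(pd.DataFrame(enrich_rows), "category_enrichment.tsv")
    cmp_rows = []
    for cat in per_set_counts[sim.peakset_a.name]:
        cc = CategoryComparison(
            m=len(sim.peakset_a), n=len(sim.peakset_b),
            m_prime=per_set_counts[sim.peakset_a.name][cat],
            n_prime=per_set_counts[sim.peakset_b.name][cat],
        )
        cmp_rows.append(
            {
                "category": cat, "m_prime": cc.m_prime, "n_prime": cc.n_prime,
                "combined_frequency": round(cc.combined_frequency, 6),
                "p_value": compare_category_between_sets(cc),
            }
        )
    save(pd.DataFrame(cmp_rows), "category_comparison.tsv")
    edges, counts = tss_distance_histogram(
        sim.peakset_a, sim.genes, config.tss_bin, config.tss_range
    )
    save(
        pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}),
        "tss_histogram.tsv",
    )

    logger.info("stage states")
    state_rows = []
    for label, ps in (
        ("all_A", sim.peakset_a),
        ("top_A", filter_top_peaks(sim.peakset_a, config.top_rpm_min)),
        ("all_B", sim.peakset_b),
    ):
        if len(ps) == 0:
            logger.warning("state stage: %s empty after filtering, skipped", label)
            continue
        for r in state_enrichment_table(ps, sim.segmentation, config.state_groups):
            state_rows.append(
                {
                    "peak_set": label, "state": r.state, "is_group": r.is_group,
                    "n_peaks": r.n_peaks,
                    "pct_peaks": round(100 * r.peak_fraction, 4),
                    "pct_genome": round(100 * r.genome_fraction, 4),
                    "fold": round(r.fold, 4), "side": r.side, "p_value": r.p_value,
                }
            )
    save(pd.DataFrame(state_rows), "state_enrichment.tsv")

    motif_flags: list[bool] | None = None
    if config.with_motif:
        logger.info("stage motif")
        mname, mpat = config.motif_patterns[0]
        motif = IUPACMotif(mname, mpat)
        hits = scan_motif(sim.sequences, motif)
        save(
            pd.DataFrame(
                [
                    {"chrom": h.chrom, "start": h.start, "end": h.start + len(motif),
                     "name": motif.name, "score": 0, "strand": h.strand}
                    for h in hits
                ]
            ),
            "motif_hits.tsv",
        )
        _, motif_flags = peaks_with_motif(sim.peakset_a, sim.sequences, motif)
        save(
            pd.DataFrame(
                {
                    "chrom": [p.chrom for p in sim.peakset_a],
                    "start": [p.interval.start for p in sim.peakset_a],
                    "end": [p.interval.end for p in sim.peakset_a],
                    "has_motif": motif_flags,
                }
            ),
            "peak_motif_flags.tsv",
        )
    else:
        logger.warning("no genome sequence configured: motif stage skipped")

    logger.info("stage link")
    link_summaries = []
    if sim.gene_list_up is not None:
        occupancy = map_peaks_to_genes(
            sim.peakset_a, sim.genes, config.promoter_up, motif_flags
        )
        for gl in (sim.gene_list_up, sim.gene_list_down):
            summary = summarize_gene_list(gl, occupancy, sim.peakset_a, motif_flags)
            stat = gene_list_site_statistic(sim.genes, gl, sim.layout, config.promoter_up)
            summary.mc_null = random_peak_null(
                stat, sim.peakset_a, sim.layout, config.mc_reps,
                seed=config.simulation.seed + 7,
            )
            link_summaries.append(summary)
        save(render_link_summaries(link_summaries), "link_summary.tsv")

    manifest = {
        "seed": config.simulation.seed,
        "simulation": asdict(config.simulation),
        "classification": asdict(config.classification),
        "mc_reps": config.mc_reps,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
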