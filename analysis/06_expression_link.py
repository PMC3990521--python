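#!/usr/bin/env python
"""Link peaks to genes (body or 1 kb promoter) and summarize occupancy of
the up-/down-regulated gene lists: occupied genes, associated binding
sites, motif-bearing sites, Monte-Carlo random-peak z-score p-values and
hypergeometric motif association.
"""

import argparse

from _data import RESULTS, load_study
from occupeak.expression_link import (
    gene_list_site_statistic,
    map_peaks_to_genes,
    random_peak_null,
    summarize_gene_list,
)
from occupeak.motif import TRE, peaks_with_motif
from occupeak.pipeline import render_link_summaries


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--mc-reps", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    st = load_study()
    _, flags = peaks_with_motif(st.peakset_a, st.sequences, TRE)
    occupancy = map_peaks_to_genes(st.peakset_a, st.genes, 1000, flags)

    summaries = []
    for gl in (st.gene_list_up, st.gene_list_down):
        s = summarize_gene_list(gl, occupancy, st.peakset_a, flags)
        stat = gene_list_site_statistic(st.genes, gl, st.layout)
        s.mc_null = random_peak_null(
            stat, st.peakset_a, st.layout, args.mc_reps, seed=args.seed
        )
        summaries.append(s)
        mc = s.mc_null
        print(
            f"{gl.name}: {s.n_genes_occupied}/{s.n_genes} genes occupied "
            f"({s.pct_genes_occupied}%), {s.n_binding_sites} binding sites "
            f"({s.pct_binding_sites}% of peaks), "
            f"{s.n_motif_sites} motif sites ({s.pct_motif_sites}%); "
            f"MC z = {mc.z:.2f}, p = {mc.p_normal:.3g} "
            f"(null {mc.null_mean:.1f} +/- {mc.null_sd:.1f}, {mc.n_reps} reps); "
            f"motif hypergeometric p = {s.hypergeom_motif_p:.3g}"
        )

    render_link_summaries(summaries).to_csv(
        RESULTS / "link_summary.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
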