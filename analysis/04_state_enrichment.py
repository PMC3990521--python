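#!/usr/bin/env python
"""Chromatin-state classification of peak centers: per-state coverage of
each peak set (all of A, the top-intensity subset rpm > 1, all of B)
against genomic state fractions, with grouped promoter/enhancer rows.
"""

import pandas as pd

from _data import RESULTS, load_study
from occupeak.pipeline import DEFAULT_STATE_GROUPS
from occupeak.state_enrichment import filter_top_peaks, state_enrichment_table


def main():
    st = load_study()
    sets = [
        ("all_A", st.peakset_a),
        ("top_A", filter_top_peaks(st.peakset_a, 1.0)),
        ("all_B", st.peakset_b),
    ]
    rows = []
    for label, ps in sets:
        for r in state_enrichment_table(ps, st.segmentation, DEFAULT_STATE_GROUPS):
            rows.append(
                {
                    "peak_set": label,
                    "state": r.state,
                    "group": r.is_group,
                    "n_peaks": r.n_peaks,
                    "pct_peaks": round(100 * r.peak_fraction, 2),
                    "pct_genome": round(100 * r.genome_fraction, 2),
                    "fold": round(r.fold, 2),
                    "p_value": r.p_value,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "state_enrichment.tsv", sep="\t", index=False)
    for label, ps in sets:
        print(f"{label}: {len(ps)} peaks")
    print(df[df.peak_set == "all_A"].to_string(index=False))


if __name__ == "__main__":
    main()
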