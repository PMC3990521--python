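"""Shared loading of the simulated study written by 01_simulate.py."""

from pathlib import Path
from types import SimpleNamespace

import pandas as pd

from occupeak import genome_io as gio
from occupeak.synthetic import CHROMHMM15_LABELS

RESULTS = Path(__file__).resolve().parent.parent / "results"
INPUTS = RESULTS / "simulated_inputs"


def load_study() -> SimpleNamespace:
    if not INPUTS.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    layout = gio.read_chrom_sizes(INPUTS / "genome.chrom.sizes")
    ns = SimpleNamespace(
        layout=layout,
        sequences=gio.read_fasta(INPUTS / "genome.fa", layout),
        genes=gio.read_gene_annotation(INPUTS / "genes.refflat", layout),
        segmentation=gio.read_state_segmentation(
            INPUTS / "states.bed", layout, CHROMHMM15_LABELS
        ),
        peakset_a=gio.read_peak_table(INPUTS / "peaks_A.tsv", layout, name="setA"),
        peakset_b=gio.read_peak_table(INPUTS / "peaks_B.tsv", layout, name="setB"),
        track_a=gio.read_track(INPUTS / "track_A.tsv", layout),
        track_b=gio.read_track(INPUTS / "track_B.tsv", layout),
        truth=pd.read_csv(INPUTS / "truth.tsv", sep="\t"),
        gene_list_up=gio.read_gene_list(INPUTS / "genes_up.txt", "up"),
        gene_list_down=gio.read_gene_list(INPUTS / "genes_down.txt", "down"),
    )
    return ns
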