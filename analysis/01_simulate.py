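#!/usr/bin/env python
"""Generate the synthetic two-experiment occupancy study.

Writes every downstream input (genome, genes, chromatin states, two peak
sets with signal tracks, gene lists) plus the planted ground truth under
results/simulated_inputs/.
"""

import argparse

from _data import INPUTS
from occupeak.pipeline import write_simulation_inputs
from occupeak.synthetic import SimulationConfig, simulate_all


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    sim = simulate_all(cfg)
    files = write_simulation_inputs(sim, INPUTS)

    print(f"genome: {len(sim.layout)} chromosomes, {sim.layout.total_length:,} bp")
    print(f"genes: {len(sim.genes)}; chromatin states: {len(sim.segmentation.labels)}")
    counts = sim.truth.label.value_counts()
    print(
        f"peak loci: {len(sim.truth)} "
        f"(common {counts.get('common', 0)}, unique_A {counts.get('unique_A', 0)}, "
        f"unique_B {counts.get('unique_B', 0)}); "
        f"motif planted at {sim.truth.has_motif.sum()} loci"
    )
    print(f"wrote {len(files)} files under {INPUTS}")


if __name__ == "__main__":
    main()
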