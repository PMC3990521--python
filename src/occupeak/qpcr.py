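"""qPCR arithmetic: relative expression by the 2^-ddCt method and
MNase-protection enrichment normalized to naked genomic DNA.

Amplification efficiency is fixed at the classic value of 2 per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CtMeasurement", "ddct_fold", "mnase_enrichment", "MNaseResult"]


@dataclass(frozen=True)
class CtMeasurement:
    sample: str
    target_gene: str
    reference_gene: str
    ct_target: float
    ct_reference: float
    replicate: int = 1

    def __post_init__(self):
        for ct in (self.ct_target, self.ct_reference):
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError(f"Ct values must be finite and positive, got {ct}")


def ddct_fold(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Fold change 2^-ddCt: target normalized to the reference gene, sample
    normalized to the control condition."""
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


@dataclass(frozen=True)
class MNaseResult:
    amplicon: str
    enrichments: tuple[float, ...]
    mean: float
    sem: float | None  # None with a single replicate


def mnase_enrichment(
    ct_chromatin: Sequence[float],
    ct_naked: Sequence[float],
    amplicon: str = "",
) -> MNaseResult:
    """Per-replicate protection 2^-(Ct_chromatin - Ct_naked) over paired
    measurements, with mean and SEM across replicates."""
    if len(ct_chromatin) != len(ct_naked):
        raise ValueError("chromatin and naked-DNA replicates must be paired")
    if not ct_chromatin:
        raise ValueError("no replicates")
    enr = tuple(
        2.0 ** (-(c - n)) for c, n in zip(ct_chromatin, ct_naked)
    )
    arr = np.asarray(enr)
    sem = float(stats.sem(arr, ddof=1)) if len(enr) >= 2 else None
    return MNaseResult(amplicon, enr, float(arr.mean()), sem)
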