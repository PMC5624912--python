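"""Quantitative validation arithmetic: qPCR relative quantification and
immunofluorescence ROI normalization.

``delta_cq`` / ``depletion_fold`` implement the delta-delta-Cq method used to
verify glial depletion of a purified neuron preparation: transcript
abundance is referenced to a housekeeping gene (Snap25 in the reference
workflow) within each sample, and fold change between two samples assumes
perfect doubling per PCR cycle (efficiency 2.0, no correction).

``normalize_rois`` reproduces the image-quantification rule: background is
the mean of the four weakest neuronal ROIs of the image, and values are
background-subtracted (clamped at 0) then scaled to the image maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QPCRRecord",
    "delta_cq",
    "depletion_fold",
    "normalize_rois",
    "read_qpcr_table",
]


@dataclass(frozen=True)
class QPCRRecord:
    """One quantification-cycle measurement."""

    sample_id: str
    gene: str
    cq: float

    def __post_init__(self) -> None:
        if not 0 < self.cq <= 45:
            raise ValueError(f"Cq {self.cq} outside (0, 45]")


def delta_cq(
    records: Iterable[QPCRRecord], sample: str, target: str, reference: str
) -> float:
    """Cq(target) - Cq(reference) within one sample, replicates averaged first."""
    by_gene: dict[str, list[float]] = {}
    for r in records:
        if r.sample_id == sample:
            by_gene.setdefault(r.gene, []).append(r.cq)
    for gene in (target, reference):
        if gene not in by_gene:
            raise KeyError(f"gene {gene!r} not measured in sample {sample!r}")
    return float(np.mean(by_gene[target]) - np.mean(by_gene[reference]))


def depletion_fold(dcq_before: float, dcq_after: float) -> float:
    """Fold depletion between two delta-Cq values: ``2 ** (after - before)``.

    Assumes amplification efficiency 2 per cycle. Values below 1 indicate
    enrichment rather than depletion and are reported as such.
    """
    if not (np.isfinite(dcq_before) and np.isfinite(dcq_after)):
        raise ValueError("delta-Cq inputs must be finite")
    return float(2.0 ** (dcq_after - dcq_before))


def normalize_rois(intensities: Sequence[float]) -> np.ndarray:
    """Background-subtract and max-normalize ROI intensities.

    Background = mean of the 4 weakest ROIs; each value maps to
    ``max(v - background, 0) / max_over_image(v - background)``. Requires at
    least 5 ROIs; an image with no dynamic range (max equals background) is
    an error.
    """
    values = np.asarray(intensities, dtype=float)
    if values.ndim != 1 or values.size < 5:
        raise ValueError("need at least 5 ROIs (4 background + >=1 measured)")
    if np.any(values <= 0):
        raise ValueError("ROI intensities must be positive")
    background = np.sort(values)[:4].mean()
    shifted = np.clip(values - background, 0.0, None)
    top = shifted.max()
    if top == 0:
        raise ValueError("no dynamic range: all ROIs at or below background")
    return shifted / top


def read_qpcr_table(path) -> list[QPCRRecord]:
    """Read a ``sample,gene,replicate,cq`` CSV into records."""
    frame = pd.read_csv(path)
    return [
        QPCRRecord(str(r["sample"]), str(r["gene"]), float(r["cq"]))
        for _, r in frame.iterrows()
    ]
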