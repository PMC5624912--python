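"""Gene-selection filters defining each clustering round.

Three regimes are used, in order of appearance in the workflow:

1. *High expression* — genes with mean FPKM >= a threshold across all cells
   (default 200); drives the first-level clustering of all 96 neurons.
2. *Group selective* — the three-criterion filter applied before second-level
   clustering of the gustatory group: a gene is kept iff it is (i) detected in
   at least ``min_cells_detected`` in-group cells, (ii) expressed at in-group
   mean FPKM >= ``min_mean_fpkm``, and (iii) enriched in-group by a fold
   ratio >= ``min_fold`` relative to the out-group.
3. *Detection* — genes passing FPKM >= (or >) a level in at least N cells;
   the permissive noise filter used for the large-gene-set PCAs.

Fold ratios are computed on means of raw FPKM with a small pseudocount added
to numerator and denominator so a zero out-group mean yields a finite ratio.
"Detected" for criterion (i) means FPKM above ``detect_threshold_fpkm``
(default 0, i.e. any expression), the weakest faithful reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import ExpressionMatrix, GeneList

__all__ = [
    "FilterSpec",
    "filter_high_expression",
    "filter_group_selective",
    "filter_detected",
    "restrict_to_list",
    "detected_genes",
]


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds for the group-selective filter.

    Defaults reproduce the taste-selective criteria: detected (>0 FPKM) in at
    least 2 in-group neurons, in-group mean FPKM >= 1, and in/out fold >= 5.
    """

    min_mean_fpkm: float = 1.0
    min_cells_detected: int = 2
    detect_threshold_fpkm: float = 0.0
    min_fold: float = 5.0
    pseudocount: float = 0.01
    scope: str = "group_vs_rest"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        for name in ("min_mean_fpkm", "detect_threshold_fpkm", "min_fold"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


def _as_sorted(mat: ExpressionMatrix, keep: np.ndarray) -> set[str]:
    return {mat.gene_ids[i] for i in np.flatnonzero(keep)}


def filter_high_expression(mat: ExpressionMatrix, min_mean_fpkm: float) -> set[str]:
    """Genes whose mean FPKM across *all* cells is >= threshold (inclusive)."""
    if mat.n_genes == 0 or mat.n_cells == 0:
        raise ValueError("expression matrix is empty")
    means = mat.values.mean(axis=1)
    return _as_sorted(mat, means >= min_mean_fpkm)


def filter_group_selective(
    mat: ExpressionMatrix,
    in_group: Iterable[str],
    out_group: Iterable[str],
    spec: FilterSpec = FilterSpec(),
) -> set[str]:
    """Three-criterion selective filter of ``in_group`` against ``out_group``.

    A gene is kept iff detected (FPKM > ``detect_threshold_fpkm``) in at
    least ``min_cells_detected`` in-group cells, its in-group mean FPKM is
    >= ``min_mean_fpkm``, and ``(in_mean + eps) / (out_mean + eps)`` is
    >= ``min_fold`` with ``eps = spec.pseudocount``.
    """
    in_group = list(in_group)
    out_group = list(out_group)
    if not in_group or not out_group:
        raise ValueError("both groups must be non-empty")
    overlap = set(in_group) & set(out_group)
    if overlap:
        raise ValueError(f"in/out groups overlap: {sorted(overlap)}")
    vin = mat.values[:, mat.cell_index(in_group)]
    vout = mat.values[:, mat.cell_index(out_group)]
    detected = (vin > spec.detect_threshold_fpkm).sum(axis=1)
    in_mean = vin.mean(axis=1)
    out_mean = vout.mean(axis=1)
    eps = spec.pseudocount
    fold = (in_mean + eps) / (out_mean + eps)
    keep = (
        (detected >= spec.min_cells_detected)
        & (in_mean >= spec.min_mean_fpkm)
        & (fold >= spec.min_fold)
    )
    return _as_sorted(mat, keep)


def filter_detected(
    mat: ExpressionMatrix,
    cells: Iterable[str],
    min_fpkm: float,
    min_cells: int,
    strict: bool = False,
) -> set[str]:
    """Genes with FPKM >= (or, with ``strict``, >) ``min_fpkm`` in at least
    ``min_cells`` of the given cells."""
    cells = list(cells)
    if min_cells > len(cells):
        raise ValueError(
            f"min_cells={min_cells} exceeds the {len(cells)} cells supplied"
        )
    v = mat.values[:, mat.cell_index(cells)]
    hits = (v > min_fpkm) if strict else (v >= min_fpkm)
    return _as_sorted(mat, hits.sum(axis=1) >= min_cells)


def detected_genes(mat: ExpressionMatrix) -> set[str]:
    """Genes expressed (FPKM > 0) in at least one cell."""
    return _as_sorted(mat, (mat.values > 0).any(axis=1))


def restrict_to_list(
    mat: ExpressionMatrix,
    genes: GeneList,
    cells: Iterable[str],
    min_mean_fpkm: float,
) -> set[str]:
    """Intersect a gene list with the matrix, then mean-filter over ``cells``.

    List members absent from the matrix are silently excluded (counted in the
    log); an empty intersection yields a warning and an empty set.
    """
    import logging

    logger = logging.getLogger(__name__)
    present = [g for g in mat.gene_ids if g in genes.symbols]
    missing = len(genes.symbols) - len(present)
    if missing:
        logger.info(
            "%d of %d symbols in list %r absent from matrix",
            missing, len(genes.symbols), genes.name,
        )
    if not present:
        logger.warning("gene list %r has empty intersection with matrix", genes.name)
        return set()
    cells = list(cells)
    v = mat.values[np.ix_(mat.gene_index(present), mat.cell_index(cells))]
    means = v.mean(axis=1)
    return {g for g, m in zip(present, means) if m >= min_mean_fpkm}
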