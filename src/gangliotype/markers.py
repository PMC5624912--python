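"""Marker ranking and small-panel classification of cells.

`rank_markers` scores cluster-selective genes: candidates must pass the
group-selective filter (cluster vs. rest) and are ranked by descending
``log2(fold) x in-cluster detected fraction`` — monotone in both selectivity
and prevalence, the two properties exemplar markers need. Ties break
alphabetically by gene id.

`classify_by_panel` reproduces the post-hoc assignment of independently
profiled cells to transcriptome clusters from presence/absence calls on a
small receptor panel (P2rx2, P2rx3, Htr3a, Gabra1 in the reference
workflow): neurons lacking both P2rx2 and P2rx3 look somatosensory; P2rx3
without P2rx2 looks like sub-cluster T2; P2rx2 without Htr3a looks like T1;
P2rx2 with Htr3a can be either T1 or T3 and receives the joint label
``"T1-or-T3"`` (the panel cannot separate those two sub-clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .filters import FilterSpec, filter_group_selective
from .io import ExpressionMatrix

__all__ = [
    "PanelRule",
    "default_panel_rules",
    "rank_markers",
    "call_marker_presence",
    "classify_by_panel",
    "heatmap_matrix",
    "PRESENT",
    "ABSENT",
]

PRESENT = "present"
ABSENT = "absent"


@dataclass(frozen=True)
class PanelRule:
    """One ordered rule: genes that must be present/absent, and the label."""

    require_present: tuple[str, ...]
    require_absent: tuple[str, ...]
    label: str

    def matches(self, calls: Mapping[str, str]) -> bool:
        return all(calls[g] == PRESENT for g in self.require_present) and all(
            calls[g] == ABSENT for g in self.require_absent
        )

    def genes(self) -> set[str]:
        return set(self.require_present) | set(self.require_absent)


def default_panel_rules() -> list[PanelRule]:
    """The shipped receptor-panel rules; first match wins, catch-all last."""
    return [
        PanelRule((), ("P2rx2", "P2rx3"), "somatosensory"),
        PanelRule(("P2rx3",), ("P2rx2",), "T2"),
        PanelRule(("P2rx2",), ("Htr3a",), "T1"),
        PanelRule(("P2rx2", "Htr3a"), (), "T1-or-T3"),
    ]


def rank_markers(
    mat: ExpressionMatrix,
    assign: ClusterAssignment,
    cluster: str,
    spec: FilterSpec = FilterSpec(),
) -> pd.DataFrame:
    """Ranked marker table for one cluster against all other assigned cells.

    Returns a DataFrame with columns ``gene_id, in_mean_fpkm, out_mean_fpkm,
    fold, fraction_detected_in, fraction_detected_out, score`` sorted by
    descending score then gene id.
    """
    in_cells = assign.members(cluster)
    if len(in_cells) < 2:
        raise ValueError(f"cluster {cluster!r} absent or has fewer than 2 cells")
    out_cells = [
        c for c, l in assign.assigned().items() if l != cluster and c in mat.cell_ids
    ]
    if not out_cells:
        raise ValueError("no out-group cells to rank against")
    keep = filter_group_selective(mat, in_cells, out_cells, spec)
    genes = sorted(keep)
    if not genes:
        return pd.DataFrame(
            columns=[
                "gene_id", "in_mean_fpkm", "out_mean_fpkm", "fold",
                "fraction_detected_in", "fraction_detected_out", "score",
            ]
        )
    vin = mat.values[np.ix_(mat.gene_index(genes), mat.cell_index(in_cells))]
    vout = mat.values[np.ix_(mat.gene_index(genes), mat.cell_index(out_cells))]
    in_mean = vin.mean(axis=1)
    out_mean = vout.mean(axis=1)
    eps = spec.pseudocount
    fold = (in_mean + eps) / (out_mean + eps)
    frac_in = (vin > spec.detect_threshold_fpkm).mean(axis=1)
    frac_out = (vout > spec.detect_threshold_fpkm).mean(axis=1)
    score = np.log2(fold) * frac_in
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "in_mean_fpkm": in_mean,
            "out_mean_fpkm": out_mean,
            "fold": fold,
            "fraction_detected_in": frac_in,
            "fraction_detected_out": frac_out,
            "score": score,
        }
    )
    table = table.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def call_marker_presence(fpkm: float, threshold: float) -> str:
    """``"present"`` iff FPKM >= threshold (inclusive), else ``"absent"``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return PRESENT if fpkm >= threshold else ABSENT


def classify_by_panel(
    calls: Mapping[str, str], rules: Sequence[PanelRule] | None = None
) -> str:
    """First matching rule's label; ``"ambiguous"`` if nothing matches.

    ``calls`` must cover every gene any rule references; a missing call is an
    error naming the gene. The rule list is evaluated in order and is a pure
    function of the calls.
    """
    if rules is None:
        rules = default_panel_rules()
    needed = set().union(*(r.genes() for r in rules)) if rules else set()
    missing = needed - set(calls)
    if missing:
        raise KeyError(f"missing presence call for gene {sorted(missing)[0]!r}")
    for rule in rules:
        if rule.matches(calls):
            return rule.label
    return "ambiguous"


def heatmap_matrix(
    mat: ExpressionMatrix,
    genes: Sequence[str],
    cell_order: Sequence[str],
) -> np.ndarray:
    """log2(FPKM + 1) submatrix in the requested gene/cell order."""
    sub = mat.values[np.ix_(mat.gene_index(genes), mat.cell_index(cell_order))]
    return np.log2(sub + 1.0)
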