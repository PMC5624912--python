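"""Model/Results interface to the two end-to-end workflows.

`TranscriptomeModel` wraps the two-level transcriptome classification: a
first-level Pearson/UPGMA clustering of all cells on highly expressed genes
(mean FPKM >= 200 by default), cross-checked by PCA over all detected genes;
then a second-level clustering of the gustatory group on taste-selective
genes (the three-criterion filter), with its own PCA cross-check, a
fold-threshold robustness sweep, an optional transcription-factor-restricted
PCA, and per-sub-cluster marker tables. ``fit()`` returns a
:class:`TranscriptomeResults` carrying assignments, trees, gene sets, PCA
scores, concordance ARIs and a ``summary()`` table.

`CalciumResponseModel` wraps calcium-recording analysis: per-cell QC,
response scoring, replicate summaries, and UPGMA functional clustering of
(ATP, 5HT, GABA-inhibition) feature vectors.

Both models are deterministic functions of their inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .calcium import (
    CalciumTrace,
    StimulusSchedule,
    cluster_responses,
    summarize_recording,
)
from .cluster import (
    ClusterAssignment,
    Dendrogram,
    PCAResult,
    UNASSIGNED,
    adjusted_rand_index,
    concordance_report,
    correlation_distance,
    cut_tree,
    run_pca,
    upgma,
)
from .filters import (
    FilterSpec,
    detected_genes,
    filter_detected,
    filter_group_selective,
    filter_high_expression,
    restrict_to_list,
)
from .io import ExpressionMatrix, GeneList, read_expression_matrix
from .markers import rank_markers

__all__ = ["TranscriptomeModel", "TranscriptomeResults",
           "CalciumResponseModel", "CalciumResults"]


def _report_hash(report: dict) -> str:
    blob = json.dumps(report, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

@dataclass
class TranscriptomeResults:
    """Fitted two-level classification."""

    model: "TranscriptomeModel"
    level1_genes: set[str]
    level1_tree: Dendrogram
    level1_assignment: ClusterAssignment
    level1_pca: PCAResult
    level1_concordance: dict
    target_cluster: str
    taste_cells: list[str]
    level2_genes: set[str]
    level2_tree: Dendrogram
    level2_assignment: ClusterAssignment
    level2_pca: PCAResult
    level2_pca_genes: set[str]
    level2_concordance: dict
    sweep: dict
    tf_pca: PCAResult | None
    tf_genes: set[str] | None
    marker_tables: dict[str, pd.DataFrame]

    # -- derived ---------------------------------------------------------
    @property
    def level1_sizes(self) -> dict[str, int]:
        return self.level1_assignment.sizes()

    @property
    def level2_sizes(self) -> dict[str, int]:
        return self.level2_assignment.sizes()

    def report(self) -> dict:
        rep = {
            "version": __version__,
            "config": self.model.config_dict(),
            "n_genes": self.model.matrix.n_genes,
            "n_cells": self.model.matrix.n_cells,
            "n_detected_genes": len(detected_genes(self.model.matrix)),
            "level1": {
                "n_genes": len(self.level1_genes),
                "sizes": self.level1_sizes,
                "pca_concordance_ari": self.level1_concordance["ari"],
            },
            "target_cluster": self.target_cluster,
            "level2": {
                "n_genes": len(self.level2_genes),
                "sizes": self.level2_sizes,
                "n_unassigned": self.level2_sizes.get(UNASSIGNED, 0),
                "pca_n_genes": len(self.level2_pca_genes),
                "pca_concordance_ari": self.level2_concordance["ari"],
            },
            "fold_sweep": {
                str(k): v for k, v in self.sweep["gene_counts"].items()
            },
            "fold_sweep_pairwise_ari": self.sweep["pairwise_ari"],
            "tf_pca_n_genes": len(self.tf_genes) if self.tf_genes is not None else None,
        }
        rep["report_sha256"] = _report_hash(rep)
        return rep

    def summary(self) -> str:
        rep = self.report()
        lines = [
            "Two-level transcriptome classification",
            "=" * 54,
            f"cells: {rep['n_cells']}    genes: {rep['n_genes']} "
            f"({rep['n_detected_genes']} detected)",
            "",
            f"Level 1 (mean FPKM >= {self.model.level1_min_mean_fpkm:g}): "
            f"{rep['level1']['n_genes']} genes",
        ]
        for name, size in sorted(self.level1_sizes.items()):
            lines.append(f"  {name:<12} {size:>4} cells")
        lines.append(
            f"  PCA concordance ARI: {rep['level1']['pca_concordance_ari']:.3f}"
        )
        lines += [
            "",
            f"Level 2 on {self.target_cluster} "
            f"({len(self.taste_cells)} cells): {rep['level2']['n_genes']} "
            f"selective genes (fold >= {self.model.level2_spec.min_fold:g})",
        ]
        for name, size in sorted(self.level2_sizes.items()):
            lines.append(f"  {name:<12} {size:>4} cells")
        lines.append(
            f"  PCA concordance ARI: {rep['level2']['pca_concordance_ari']:.3f} "
            f"({rep['level2']['pca_n_genes']} genes)"
        )
        sweep = ", ".join(
            f"fold {k}: {v} genes" for k, v in rep["fold_sweep"].items()
        )
        lines += ["", f"Robustness sweep: {sweep}",
                  f"  min pairwise ARI across thresholds: "
                  f"{min(self.sweep['pairwise_ari'].values()):.3f}"]
        if self.tf_genes is not None:
            lines.append(f"TF-restricted PCA: {len(self.tf_genes)} genes")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> Path:
        """Write assignments, gene sets, trees, scores and report.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        assignments = {
            c: {
                "level1": self.level1_assignment.labels[c],
                "level2": self.level2_assignment.labels.get(c, ""),
            }
            for c in self.model.matrix.cell_ids
        }
        with open(outdir / "assignments.csv", "w") as fh:
            fh.write("cell_id,level1,level2\n")
            for c, row in assignments.items():
                fh.write(f"{c},{row['level1']},{row['level2']}\n")
        (outdir / "genes_level1.txt").write_text(
            "".join(g + "\n" for g in sorted(self.level1_genes))
        )
        (outdir / "genes_level2.txt").write_text(
            "".join(g + "\n" for g in sorted(self.level2_genes))
        )
        (outdir / "tree_level1.nwk").write_text(self.level1_tree.to_newick() + "\n")
        (outdir / "tree_level2.nwk").write_text(self.level2_tree.to_newick() + "\n")
        scores = pd.DataFrame(
            self.level1_pca.scores,
            index=self.level1_pca.cell_ids,
            columns=[f"PC{i + 1}" for i in range(self.level1_pca.scores.shape[1])],
        )
        scores.to_csv(outdir / "pca_scores.csv", index_label="cell_id")
        for cluster, table in self.marker_tables.items():
            table.to_csv(outdir / f"markers_{cluster}.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(self.report(), indent=1, sort_keys=True, default=str) + "\n"
        )
        return outdir


class TranscriptomeModel:
    """Two-level gene-filtered clustering of an FPKM matrix.

    Parameters
    ----------
    matrix
        Genes x cells FPKM matrix.
    level1_min_mean_fpkm
        High-expression threshold for the first-level gene set (default 200).
    level1_k
        Number of first-level clusters (default 2: the major split).
    level2_spec
        Three-criterion selective filter for the second level.
    level2_k, level2_min_cluster_size
        Number of retained sub-clusters and the minimum size below which a
        branch is left "unassigned" (defaults 3 and 3).
    fold_sweep
        Fold thresholds for the robustness sweep (default (2, 5, 10)).
    tf_list
        Optional transcription-factor list for the TF-restricted PCA.
    target_cluster
        Level-1 cluster to sub-cluster; default the larger one.
    log
        Correlate/PCA on log2(FPKM+1) (default) or raw FPKM.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        *,
        level1_min_mean_fpkm: float = 200.0,
        level1_k: int = 2,
        level2_spec: FilterSpec = FilterSpec(),
        level2_k: int = 3,
        level2_min_cluster_size: int = 3,
        level2_pca_min_fpkm: float = 10.0,
        level2_pca_min_cells: int = 3,
        fold_sweep: Sequence[float] = (2.0, 5.0, 10.0),
        tf_list: GeneList | None = None,
        tf_min_mean_fpkm: float = 1.0,
        target_cluster: str | None = None,
        pca_components: int = 2,
        log: bool = True,
    ) -> None:
        self.matrix = matrix
        self.level1_min_mean_fpkm = level1_min_mean_fpkm
        self.level1_k = level1_k
        self.level2_spec = level2_spec
        self.level2_k = level2_k
        self.level2_min_cluster_size = level2_min_cluster_size
        self.level2_pca_min_fpkm = level2_pca_min_fpkm
        self.level2_pca_min_cells = level2_pca_min_cells
        self.fold_sweep = tuple(fold_sweep)
        self.tf_list = tf_list
        self.tf_min_mean_fpkm = tf_min_mean_fpkm
        self.target_cluster = target_cluster
        self.pca_components = pca_components
        self.log = log

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "TranscriptomeModel":
        return cls(ExpressionMatrix.from_frame(frame), **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "TranscriptomeModel":
        return cls(read_expression_matrix(path), **kwargs)

    def config_dict(self) -> dict:
        return {
            "level1_min_mean_fpkm": self.level1_min_mean_fpkm,
            "level1_k": self.level1_k,
            "level2_spec": vars(self.level2_spec).copy(),
            "level2_k": self.level2_k,
            "level2_min_cluster_size": self.level2_min_cluster_size,
            "level2_pca_min_fpkm": self.level2_pca_min_fpkm,
            "level2_pca_min_cells": self.level2_pca_min_cells,
            "fold_sweep": list(self.fold_sweep),
            "tf_list": self.tf_list.name if self.tf_list else None,
            "tf_min_mean_fpkm": self.tf_min_mean_fpkm,
            "target_cluster": self.target_cluster,
            "pca_components": self.pca_components,
            "log": self.log,
        }

    # -- fitting ---------------------------------------------------------
    def _cluster(
        self, cells: list[str], genes: Iterable[str], k: int, min_size: int
    ) -> tuple[Dendrogram, ClusterAssignment]:
        sub = self.matrix.subset(cells=cells)
        dist, ids = correlation_distance(sub, genes, log=self.log)
        tree = upgma(dist, ids)
        return tree, cut_tree(tree, k=k, min_cluster_size=min_size)

    def fit(self) -> TranscriptomeResults:
        mat = self.matrix

        # level 1: highly expressed genes, all cells
        level1_genes = filter_high_expression(mat, self.level1_min_mean_fpkm)
        if len(level1_genes) < 2:
            raise ValueError(
                "fewer than 2 genes pass the level-1 high-expression filter"
            )
        tree1, assign1 = self._cluster(
            list(mat.cell_ids), level1_genes, self.level1_k, 1
        )
        detected = detected_genes(mat)
        pca1 = run_pca(mat, detected, self.pca_components, log=self.log)
        concord1 = concordance_report(assign1, pca1, self.level1_k)

        # pick the cluster to sub-classify (default: the larger one)
        target = self.target_cluster or max(
            assign1.sizes(), key=lambda l: assign1.sizes()[l]
        )
        taste_cells = assign1.members(target)
        rest_cells = [c for c in mat.cell_ids if c not in set(taste_cells)]

        # level 2: taste-selective genes, taste cells only
        level2_genes = filter_group_selective(
            mat, taste_cells, rest_cells, self.level2_spec
        )
        if len(level2_genes) < 2:
            raise ValueError("fewer than 2 genes pass the selective filter")
        tree2, assign2 = self._cluster(
            taste_cells, level2_genes, self.level2_k, self.level2_min_cluster_size
        )

        pca2_genes = filter_detected(
            mat.subset(cells=taste_cells),
            taste_cells,
            self.level2_pca_min_fpkm,
            self.level2_pca_min_cells,
        )
        pca2 = run_pca(
            mat.subset(cells=taste_cells), pca2_genes, self.pca_components,
            log=self.log,
        )
        concord2 = concordance_report(assign2, pca2, self.level2_k)

        # robustness sweep over the fold threshold
        sweep_counts: dict[float, int] = {}
        sweep_assign: dict[float, ClusterAssignment] = {}
        for fold in self.fold_sweep:
            spec = FilterSpec(
                min_mean_fpkm=self.level2_spec.min_mean_fpkm,
                min_cells_detected=self.level2_spec.min_cells_detected,
                detect_threshold_fpkm=self.level2_spec.detect_threshold_fpkm,
                min_fold=fold,
                pseudocount=self.level2_spec.pseudocount,
            )
            genes_f = filter_group_selective(mat, taste_cells, rest_cells, spec)
            sweep_counts[fold] = len(genes_f)
            _, sweep_assign[fold] = self._cluster(
                taste_cells, genes_f, self.level2_k, self.level2_min_cluster_size
            )
        pairwise = {}
        folds = list(self.fold_sweep)
        for i, fa in enumerate(folds):
            for fb in folds[i + 1:]:
                pairwise[f"{fa:g}vs{fb:g}"] = adjusted_rand_index(
                    sweep_assign[fa], sweep_assign[fb]
                )

        # TF-restricted PCA
        tf_pca = tf_genes = None
        if self.tf_list is not None:
            tf_genes = restrict_to_list(
                mat, self.tf_list, taste_cells, self.tf_min_mean_fpkm
            )
            if len(tf_genes) >= self.pca_components:
                tf_pca = run_pca(
                    mat.subset(cells=taste_cells), tf_genes,
                    self.pca_components, log=self.log,
                )

        # marker tables per retained sub-cluster
        taste_mat = self.matrix.subset(cells=taste_cells)
        marker_tables = {
            cluster: rank_markers(taste_mat, assign2, cluster, self.level2_spec)
            for cluster in sorted(assign2.sizes())
            if cluster != UNASSIGNED
        }

        return TranscriptomeResults(
            model=self,
            level1_genes=level1_genes,
            level1_tree=tree1,
            level1_assignment=assign1,
            level1_pca=pca1,
            level1_concordance=concord1,
            target_cluster=target,
            taste_cells=taste_cells,
            level2_genes=level2_genes,
            level2_tree=tree2,
            level2_assignment=assign2,
            level2_pca=pca2,
            level2_pca_genes=pca2_genes,
            level2_concordance=concord2,
            sweep={"gene_counts": sweep_counts, "pairwise_ari": pairwise,
                   "assignments": sweep_assign},
            tf_pca=tf_pca,
            tf_genes=tf_genes,
            marker_tables=marker_tables,
        )


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

@dataclass
class CalciumResults:
    """Scored recording: QC, response table, functional clusters."""

    model: "CalciumResponseModel"
    response_table: pd.DataFrame
    assignment: ClusterAssignment
    tree: Dendrogram

    @property
    def qc_pass_count(self) -> int:
        return int(self.response_table["qc_pass"].sum())

    @property
    def cluster_sizes(self) -> dict[str, int]:
        return self.assignment.sizes()

    def report(self) -> dict:
        rep = {
            "version": __version__,
            "n_cells": len(self.response_table),
            "qc_pass": self.qc_pass_count,
            "consistent": int(self.response_table["consistent"].sum()),
            "cluster_sizes": self.cluster_sizes,
            "k": self.model.k,
        }
        rep["report_sha256"] = _report_hash(rep)
        return rep

    def summary(self) -> str:
        rep = self.report()
        lines = [
            "Ca2+ response scoring and functional clustering",
            "=" * 54,
            f"cells: {rep['n_cells']}   QC pass: {rep['qc_pass']}   "
            f"replicate-consistent: {rep['consistent']}",
            f"functional clusters (k={rep['k']}):",
        ]
        for name, size in sorted(rep["cluster_sizes"].items()):
            members = self.assignment.members(name)
            sub = self.response_table[self.response_table["cell_id"].isin(members)]
            lines.append(
                f"  {name:<4} {size:>4} cells   "
                f"ATP dF/F {sub['dff_atp_mean'].mean():.3f}   "
                f"5HT dF/F {sub['dff_5ht_mean'].mean():.3f}   "
                f"inhibition {sub['inhibition_mean'].mean():.1f}%"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.response_table.to_csv(outdir / "response_table.csv", index=False)
        with open(outdir / "functional_clusters.csv", "w") as fh:
            fh.write("cell_id,cluster\n")
            for c, l in self.assignment.labels.items():
                fh.write(f"{c},{l}\n")
        (outdir / "tree_functional.nwk").write_text(self.tree.to_newick() + "\n")
        (outdir / "report.json").write_text(
            json.dumps(self.report(), indent=1, sort_keys=True) + "\n"
        )
        return outdir


class CalciumResponseModel:
    """Score a set of calcium traces under a two-block stimulus schedule."""

    def __init__(
        self,
        traces: Sequence[CalciumTrace],
        schedule: StimulusSchedule,
        *,
        k: int = 4,
        drift_tolerance: float = 0.10,
    ) -> None:
        self.traces = list(traces)
        self.schedule = schedule
        self.k = k
        self.drift_tolerance = drift_tolerance

    def fit(self) -> CalciumResults:
        table = summarize_recording(
            self.traces, self.schedule, self.drift_tolerance
        )
        assignment, tree = cluster_responses(table, k=self.k)
        # cells excluded from clustering are reported unassigned
        labels = dict(assignment.labels)
        for c in table["cell_id"]:
            labels.setdefault(c, UNASSIGNED)
        return CalciumResults(
            model=self,
            response_table=table,
            assignment=ClusterAssignment(labels),
            tree=tree,
        )
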