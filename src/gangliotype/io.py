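"""Expression-matrix and gene-list I/O.

Defines the canonical in-memory containers shared by every analysis stage:
:class:`ExpressionMatrix` (genes x cells FPKM with identifiers and optional
per-cell labels) and :class:`GeneList` (a named, deduplicated set of gene
symbols, e.g. a transcription-factor list).

Supported on-disk formats:

* TSV/CSV — first column gene id, first row cell ids, dense numeric body.
* MatrixMarket triplet — ``matrix.mtx`` (1-based indices) with companion
  ``genes.txt`` and ``cells.txt`` name files, one id per line.
* Gene lists — plain text, one symbol per line, ``#`` comment lines ignored.
* Cell labels — two-column CSV ``cell_id,label``.

Gene and cell identifiers are matched case-sensitively and must be unique;
missing values are not permitted (the FPKM matrix is dense by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "GeneList",
    "FormatError",
    "ValidationError",
    "read_expression_matrix",
    "write_expression_matrix",
    "load_gene_list",
    "attach_labels",
    "read_labels",
    "write_labels",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file (duplicate identifiers, bad triplet layout...)."""


class ValidationError(ValueError):
    """Input violates a data-model invariant (e.g. negative FPKM)."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Dense genes x cells FPKM matrix with identifiers and optional labels.

    Parameters
    ----------
    values
        Non-negative float array of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique identifiers matching the matrix dimensions.
    cell_labels
        Optional ``cell_id -> label`` map covering a subset of the cells.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"identifier/dimension mismatch: {len(self.gene_ids)} gene ids, "
                f"{len(self.cell_ids)} cell ids for a {self.values.shape} matrix"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite FPKM at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative FPKM at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        unknown = set(self.cell_labels) - set(self.cell_ids)
        if unknown:
            raise ValidationError(
                f"labels refer to unknown cell ids: {sorted(unknown)}"
            )

    # -- conveniences -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown gene id: {e.args[0]!r}") from None

    def cell_index(self, cells: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in cells], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown cell id: {e.args[0]!r}") from None

    def subset(
        self,
        genes: Iterable[str] | None = None,
        cells: Iterable[str] | None = None,
    ) -> "ExpressionMatrix":
        """Submatrix in the requested gene/cell order (labels carried over)."""
        gene_ids = list(genes) if genes is not None else list(self.gene_ids)
        cell_ids = list(cells) if cells is not None else list(self.cell_ids)
        gi = self.gene_index(gene_ids)
        ci = self.cell_index(cell_ids)
        labels = {c: self.cell_labels[c] for c in cell_ids if c in self.cell_labels}
        return ExpressionMatrix(
            self.values[np.ix_(gi, ci)], gene_ids, cell_ids, labels
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, cell_labels: Mapping[str, str] | None = None
    ) -> "ExpressionMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            dict(cell_labels or {}),
        )

    def cells_with_label(self, label: str) -> list[str]:
        return [c for c in self.cell_ids if self.cell_labels.get(c) == label]


@dataclass
class GeneList:
    """A named set of gene symbols (case-sensitive, deduplicated)."""

    name: str
    symbols: set[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValidationError(f"gene list {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an FPKM matrix from TSV, CSV, or a MatrixMarket triplet.

    ``format`` is one of ``{"tsv", "csv", "mtx-triplet"}``; if omitted it is
    inferred from the file suffix. For ``mtx-triplet``, ``path`` points at the
    ``.mtx`` file and companion ``genes.txt`` / ``cells.txt`` files must live
    beside it. Row/column order is preserved exactly as on disk.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx-triplet"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise FormatError(f"cannot infer format from suffix of {path.name!r}")

    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        if frame.isna().any().any():
            raise ValidationError(f"missing values in {path.name!r} are not permitted")
        _check_unique([str(i) for i in frame.index], "gene")
        _check_unique([str(c) for c in frame.columns], "cell")
        return ExpressionMatrix.from_frame(frame)

    if format == "mtx-triplet":
        genes_path = path.with_name("genes.txt")
        cells_path = path.with_name("cells.txt")
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"companion name file missing: {p}")
        gene_ids = [l.strip() for l in genes_path.read_text().splitlines() if l.strip()]
        cell_ids = [l.strip() for l in cells_path.read_text().splitlines() if l.strip()]
        mat = scipy.io.mmread(str(path))
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        return ExpressionMatrix(values, gene_ids, cell_ids)

    raise FormatError(f"unknown format {format!r}")


def write_expression_matrix(
    mat: ExpressionMatrix, path: str | Path, format: str | None = None
) -> Path:
    """Write a matrix in any supported format; inverse of the reader."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx-triplet"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise FormatError(f"cannot infer format from suffix of {path.name!r}")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        mat.to_frame().to_csv(path, sep=sep)
    elif format == "mtx-triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(mat.values))
        path.with_name("genes.txt").write_text("".join(g + "\n" for g in mat.gene_ids))
        path.with_name("cells.txt").write_text("".join(c + "\n" for c in mat.cell_ids))
    else:
        raise FormatError(f"unknown format {format!r}")
    return path


def load_gene_list(
    paths: str | Path | Sequence[str | Path], name: str | None = None
) -> GeneList:
    """Union one or more one-symbol-per-line files into a single GeneList.

    Files are merged and deduplicated case-sensitively (the merge semantics
    used for combining transcription-factor databases). ``#`` lines and blank
    lines are ignored. An empty union is an error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    symbols: set[str] = set()
    for p in paths:
        p = Path(p)
        for line in p.read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.add(line)
    if not symbols:
        raise ValidationError("gene-list union is empty")
    listname = name or "+".join(Path(p).stem for p in paths)
    logger.info("loaded gene list %r: %d unique symbols from %d file(s)",
                listname, len(symbols), len(paths))
    return GeneList(listname, symbols)


def attach_labels(
    mat: ExpressionMatrix, labels: Mapping[str, str]
) -> ExpressionMatrix:
    """Return a copy of ``mat`` with ``labels`` merged onto existing labels.

    Unlabeled cells are permitted; every labeled cell id must exist. On
    re-attachment the last write wins (overrides are logged).
    """
    unknown = set(labels) - set(mat.cell_ids)
    if unknown:
        raise KeyError(f"unknown cell id(s) in labels: {sorted(unknown)}")
    merged = dict(mat.cell_labels)
    for cell, label in labels.items():
        if cell in merged and merged[cell] != label:
            logger.info("relabeling cell %r: %r -> %r", cell, merged[cell], label)
        merged[cell] = label
    return ExpressionMatrix(mat.values.copy(), list(mat.gene_ids),
                            list(mat.cell_ids), merged)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``cell_id,label`` CSV (header optional)."""
    frame = pd.read_csv(path, header=None, dtype=str)
    if list(frame.iloc[0]) == ["cell_id", "label"]:
        frame = frame.iloc[1:]
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_labels(labels: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id,label\n")
        for cell, label in labels.items():
            fh.write(f"{cell},{label}\n")
    return path
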