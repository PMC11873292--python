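"""Core domain types for clustered single-cell count data, plus readers/writers.

The in-memory convention is cells x genes. On disk, MatrixMarket follows the
10x Genomics convention (genes x cells) and is transposed at the I/O boundary;
dense TSV files are cells x genes with a gene-id header row and a cell-id
first column.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "ClusterLabeling",
    "NormalizedMatrix",
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "validate_labels",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _check_ids(ids, what: str) -> tuple[str, ...]:
    cleaned = tuple(str(i).strip() for i in ids)
    if any(i == "" for i in cleaned):
        raise ValidationError(f"empty {what} identifier")
    if len(set(cleaned)) != len(cleaned):
        seen, dups = set(), []
        for i in cleaned:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what} ids: {sorted(set(dups))[:5]}")
    return cleaned


class ExpressionMatrix:
    """Raw UMI counts, cells x genes, with unique cell and gene identifiers.

    Entries must be non-negative integers; this is the object the raw-count
    positivity rule (cell positive for a gene iff count > 0) operates on.
    """

    def __init__(self, counts, gene_ids, cell_ids):
        self.gene_ids = _check_ids(gene_ids, "gene")
        self.cell_ids = _check_ids(cell_ids, "cell")
        if sp.issparse(counts):
            coo = counts.tocoo()
            self._validate_entries(coo.data, coo.row, coo.col)
            mat = sp.csr_array(counts.astype(np.int64))
        else:
            arr = np.asarray(counts)
            if arr.ndim != 2:
                raise ValidationError("counts must be a 2-D matrix")
            bad_r, bad_c = np.nonzero(
                ~(np.isfinite(arr) & (arr >= 0) & (np.floor(arr) == arr))
            ) if arr.size else (np.array([], int), np.array([], int))
            if bad_r.size:
                r, c = int(bad_r[0]), int(bad_c[0])
                raise ValidationError(
                    f"invalid count {arr[r, c]!r} at cell index {r}, gene index {c} "
                    "(entries must be non-negative integers)"
                )
            mat = sp.csr_array(arr.astype(np.int64))
        n_cells, n_genes = mat.shape
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        self.counts = mat

    @staticmethod
    def _validate_entries(data, rows, cols):
        arr = np.asarray(data)
        bad = ~(np.isfinite(arr.astype(float)) & (arr >= 0) & (np.floor(arr) == arr))
        if np.any(bad):
            k = int(np.nonzero(bad)[0][0])
            raise ValidationError(
                f"invalid count {arr[k]!r} at cell index {int(rows[k])}, "
                f"gene index {int(cols[k])} (entries must be non-negative integers)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=list(self.cell_ids),
                            columns=list(self.gene_ids))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and self.shape == other.shape
            and (self.counts != other.counts).nnz == 0
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_cells} cells x {self.n_genes} genes)"


@dataclass
class ClusterLabeling:
    """Per-cell categorical cluster assignment.

    ``clusters`` preserves order of first appearance; every named cluster has
    at least one cell by construction.
    """

    labels: dict[str, str]
    clusters: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.labels:
            raise ValidationError("labeling contains no cells")
        seen_order = []
        for c in self.labels.values():
            if c not in seen_order:
                seen_order.append(c)
        if not self.clusters:
            self.clusters = tuple(seen_order)
        else:
            self.clusters = tuple(self.clusters)
            if set(self.clusters) != set(seen_order):
                raise ValidationError(
                    "declared clusters do not match clusters present in labels"
                )

    @classmethod
    def from_sequences(cls, cell_ids, cluster_per_cell) -> "ClusterLabeling":
        cell_ids = list(cell_ids)
        cluster_per_cell = list(cluster_per_cell)
        if len(cell_ids) != len(cluster_per_cell):
            raise ValidationError("cell_ids and cluster assignments differ in length")
        if len(set(cell_ids)) != len(cell_ids):
            raise ValidationError("duplicate cell ids in labeling")
        return cls(dict(zip(cell_ids, (str(c) for c in cluster_per_cell))))

    def cells_in(self, cluster: str) -> list[str]:
        if cluster not in self.clusters:
            raise ValidationError(f"unknown cluster {cluster!r}")
        return [c for c, k in self.labels.items() if k == cluster]

    def indices_in(self, m: ExpressionMatrix, cluster: str) -> np.ndarray:
        if cluster not in self.clusters:
            raise ValidationError(f"unknown cluster {cluster!r}")
        return np.array(
            [i for i, c in enumerate(m.cell_ids) if self.labels.get(c) == cluster],
            dtype=int,
        )

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class NormalizedMatrix:
    """Log-transformed depth-normalized expression with the same ids/shape
    as its source count matrix. value = log(1 + count * scale_total / depth)."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    scale_total: float
    log_base: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError("normalized matrix shape does not match ids")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("normalized values must be finite and >= 0")

    def delogged(self) -> np.ndarray:
        """Invert the log transform: base**value - 1 (counts-per-scale_total)."""
        if math.isclose(self.log_base, math.e):
            return np.expm1(self.values)
        return np.power(self.log_base, self.values) - 1.0


# ---------------------------------------------------------------------------
# Readers / writers


def _require(path: str):
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing input file: {path}")


def _read_single_column(path: str) -> list[str]:
    _require(path)
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0].strip() for line in fh if line.strip()]


def read_counts(path: str, format: str = "mtx-dir") -> ExpressionMatrix:
    """Read a raw count matrix.

    ``mtx-dir``: directory with matrix.mtx (genes x cells, transposed on
    read), genes.tsv and barcodes.tsv. ``dense-tsv``: a single TSV, cells x
    genes, gene-id header, cell-id first column.
    """
    if format == "mtx-dir":
        mtx = os.path.join(path, "matrix.mtx")
        genes_f = os.path.join(path, "genes.tsv")
        barcodes_f = os.path.join(path, "barcodes.tsv")
        for f in (mtx, genes_f, barcodes_f):
            _require(f)
        mat = mmread(mtx)  # genes x cells on disk
        genes = _read_single_column(genes_f)
        cells = _read_single_column(barcodes_f)
        return ExpressionMatrix(sp.coo_array(mat).T.tocsr(), genes, cells)
    if format == "dense-tsv":
        _require(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        return ExpressionMatrix(df.to_numpy(), list(df.columns),
                                [str(i) for i in df.index])
    raise ValueError(f"unknown format {format!r} (expected 'mtx-dir' or 'dense-tsv')")


def write_counts(m: ExpressionMatrix, path: str, format: str = "mtx-dir") -> None:
    """Write a count matrix so that :func:`read_counts` reproduces it exactly."""
    if format == "mtx-dir":
        os.makedirs(path, exist_ok=True)
        mmwrite(
            os.path.join(path, "matrix.mtx"),
            sp.coo_matrix(m.counts.T),  # genes x cells on disk
            field="integer",
        )
        with open(os.path.join(path, "genes.tsv"), "w") as fh:
            fh.writelines(g + "\n" for g in m.gene_ids)
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            fh.writelines(c + "\n" for c in m.cell_ids)
        return
    if format == "dense-tsv":
        m.to_frame().to_csv(path, sep="\t")
        return
    raise ValueError(f"unknown format {format!r} (expected 'mtx-dir' or 'dense-tsv')")


def read_labels(path: str, header: bool = False) -> ClusterLabeling:
    """Read a 2-column TSV (cell_id, cluster). Clusters keep order of first
    appearance. A cell labeled twice or an empty file is an error."""
    _require(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if header and lines:
        lines = lines[1:]
    if not lines:
        raise ValidationError(f"label file {path} contains no rows")
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"malformed label row {ln!r} (need 2 columns)")
        cell, cluster = parts[0].strip(), parts[1].strip()
        if cell in labels:
            raise ValidationError(f"cell {cell!r} labeled more than once")
        labels[cell] = cluster
    return ClusterLabeling(labels)


def write_labels(labeling: ClusterLabeling, path: str) -> None:
    with open(path, "w") as fh:
        for cell, cluster in labeling.labels.items():
            fh.write(f"{cell}\t{cluster}\n")


def validate_labels(m: ExpressionMatrix, labeling: ClusterLabeling) -> None:
    """Check that the labeling covers exactly the matrix's cells."""
    matrix_cells = set(m.cell_ids)
    labeled = set(labeling.labels)
    missing = matrix_cells - labeled
    extra = labeled - matrix_cells
    if missing:
        raise ValidationError(f"cells without label: {sorted(missing)[:5]}")
    if extra:
        raise ValidationError(f"labels for unknown cells: {sorted(extra)[:5]}")
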