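"""Readers and writers for count matrices, annotations, ligand-receptor tables
and interaction results.

Supported on-disk formats are deliberately few: Matrix Market triplet
directories in the 10x layout (``matrix.mtx`` plus ``genes.tsv``/``features.tsv``
and ``barcodes.tsv``), dense delimited tables (genes as rows, barcodes as the
header), and plain TSV/CSV for annotations, ligand-receptor databases and
results. Delimiter autodetection is restricted to tab and comma; anything
else must be passed explicitly to avoid silent misparses.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import (
    DuplicateBarcodeError,
    DuplicateGeneError,
    EmptyResultError,
    MalformedRowError,
    MissingFileError,
    NegativeEntryError,
    NonIntegerEntryError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "LRPair",
    "read_counts",
    "read_annotations",
    "read_lr_database",
    "filter_cells",
    "write_interactions",
    "write_counts_mtx",
    "write_annotations",
]


@dataclass
class CountMatrix:
    """Genes x cells UMI count matrix with identifiers.

    ``counts`` is a dense non-negative integer array of shape
    ``(len(gene_ids), len(barcodes))``. Desk-scale inputs (thousands of cells)
    are held dense; sparse on-disk inputs are densified on read.
    """

    counts: np.ndarray
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        self.validate()

    def validate(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.gene_ids),
            len(self.barcodes),
        ):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} cells"
            )
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(np.isfinite(self.counts)):
                raise NonIntegerEntryError("count matrix contains non-finite entries")
            if np.any(self.counts != np.floor(self.counts)):
                raise NonIntegerEntryError("count matrix contains non-integer entries")
            self.counts = self.counts.astype(np.int64)
        elif not np.issubdtype(self.counts.dtype, np.integer):
            raise NonIntegerEntryError(
                f"count matrix dtype {self.counts.dtype} is not numeric-integral"
            )
        if self.counts.size and self.counts.min() < 0:
            raise NegativeEntryError("count matrix contains negative entries")
        dup_g = _first_duplicate(self.gene_ids)
        if dup_g is not None:
            raise DuplicateGeneError(f"duplicate gene id: {dup_g!r}")
        dup_b = _first_duplicate(self.barcodes)
        if dup_b is not None:
            raise DuplicateBarcodeError(f"duplicate barcode: {dup_b!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def library_sizes(self) -> np.ndarray:
        """Total counts per cell."""
        return self.counts.sum(axis=0)

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return (self.counts > 0).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.barcodes)


@dataclass
class LRPair:
    """A ligand-receptor pair with optional receiver-side co-receptors.

    Example: the MIF-CD74 axis with CXCR4 and CD44 as candidate co-receptors
    forming the receptor complex on the receiver cell.
    """

    ligand: str
    receptor: str
    co_receptors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ligand = self.ligand.strip()
        self.receptor = self.receptor.strip()
        self.co_receptors = [c.strip() for c in self.co_receptors if c.strip()]
        if self.ligand.upper() == self.receptor.upper():
            raise ValueError(f"ligand and receptor are identical: {self.ligand!r}")
        for c in self.co_receptors:
            if c.upper() in (self.ligand.upper(), self.receptor.upper()):
                raise ValueError(
                    f"co-receptor {c!r} duplicates ligand or receptor of pair "
                    f"{self.ligand}-{self.receptor}"
                )


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    with open(path) as fh:
        head = fh.readline()
    # autodetect limited to tab and comma by design
    return "\t" if head.count("\t") >= head.count(",") else ","


def _find_existing(directory: Path, names: list[str]) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise MissingFileError(
        f"none of {names} found in directory {directory}"
    )


def read_counts(
    path: str | os.PathLike,
    format: str = "auto",
    transpose: bool = False,
    delimiter: str | None = None,
) -> CountMatrix:
    """Read a genes x cells UMI count matrix.

    Parameters
    ----------
    path
        For ``mtx_dir``, a directory holding a Matrix Market triplet file
        (``matrix.mtx``) plus gene (``genes.tsv``/``features.tsv``) and
        barcode (``barcodes.tsv``) lists. For ``dense_table``, a delimited
        file whose first column is the gene id and whose header row holds
        barcodes.
    format
        ``"mtx_dir"``, ``"dense_table"``, or ``"auto"`` (directory -> mtx_dir).
    transpose
        Set when the on-disk matrix is cells x genes; output is always
        genes x cells.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"counts path does not exist: {path}")
    if format == "auto":
        format = "mtx_dir" if path.is_dir() else "dense_table"
    if format == "mtx_dir":
        cm = _read_mtx_dir(path)
    elif format == "dense_table":
        cm = _read_dense_table(path, delimiter)
    else:
        raise ValueError(f"unknown counts format: {format!r}")
    if transpose:
        cm = CountMatrix(cm.counts.T.copy(), cm.barcodes, cm.gene_ids)
    return cm


def _read_mtx_dir(directory: Path) -> CountMatrix:
    mtx = _find_existing(directory, ["matrix.mtx", "matrix.mtx.gz"])
    genes_file = _find_existing(
        directory,
        ["genes.tsv", "features.tsv", "genes.tsv.gz", "features.tsv.gz"],
    )
    barcodes_file = _find_existing(directory, ["barcodes.tsv", "barcodes.tsv.gz"])
    mat = scipy.io.mmread(str(mtx))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes_tab = pd.read_csv(genes_file, sep="\t", header=None, dtype=str)
    # 10x features files carry (id, symbol[, type]); prefer the symbol column
    gene_ids = list(genes_tab.iloc[:, 1] if genes_tab.shape[1] >= 2 else genes_tab.iloc[:, 0])
    barcodes = list(pd.read_csv(barcodes_file, sep="\t", header=None, dtype=str).iloc[:, 0])
    return CountMatrix(np.asarray(mat), gene_ids, barcodes)


def _read_dense_table(path: Path, delimiter: str | None) -> CountMatrix:
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))


def read_annotations(
    path: str | os.PathLike,
    delimiter: str | None = None,
    header: str | bool = "auto",
) -> pd.DataFrame:
    """Read a barcode -> cell-type table.

    Returns a two-column DataFrame (``barcode``, ``cell_type``); labels are
    taken verbatim apart from whitespace trimming. With ``header="auto"`` a
    first row reading (barcode, cell_type) is treated as a header.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"annotation path does not exist: {path}")
    if path.stat().st_size == 0:
        logger.warning("annotation file %s is empty", path)
        return pd.DataFrame(columns=["barcode", "cell_type"])
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, skip_blank_lines=True)
    if df.empty:
        logger.warning("annotation file %s is empty", path)
        return pd.DataFrame(columns=["barcode", "cell_type"])
    if df.shape[1] < 2:
        raise MalformedRowError(
            f"annotation table needs 2 columns (barcode, cell_type), got {df.shape[1]}"
        )
    first = [str(x).strip().lower() for x in df.iloc[0, :2]]
    has_header = header is True or (
        header == "auto" and first == ["barcode", "cell_type"]
    )
    if has_header:
        df = df.iloc[1:]
    out = pd.DataFrame(
        {
            "barcode": df.iloc[:, 0].astype(str).str.strip().to_numpy(),
            "cell_type": df.iloc[:, 1].astype(str).str.strip().to_numpy(),
        }
    )
    dup = out["barcode"][out["barcode"].duplicated()]
    if len(dup):
        raise DuplicateBarcodeError(f"duplicate annotated barcode: {dup.iloc[0]!r}")
    return out


def read_lr_database(
    path: str | os.PathLike, delimiter: str | None = None
) -> list[LRPair]:
    """Read a ligand-receptor database table.

    Expected columns: ``ligand``, ``receptor``, optional ``co_receptors``
    (semicolon-separated). Rows whose ligand equals their receptor, or that
    cannot be parsed, raise :class:`MalformedRowError` carrying the line
    number.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"LR database path does not exist: {path}")
    sep = _detect_delimiter(path, delimiter)
    pairs: list[LRPair] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header_row = next(reader, None)
        if header_row is None:
            return pairs
        cols = [c.strip().lower() for c in header_row]
        try:
            i_lig, i_rec = cols.index("ligand"), cols.index("receptor")
        except ValueError as e:
            raise MalformedRowError(
                f"{path} line 1: header must contain 'ligand' and 'receptor' columns"
            ) from e
        i_co = cols.index("co_receptors") if "co_receptors" in cols else None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                ligand = row[i_lig]
                receptor = row[i_rec]
                co_raw = row[i_co] if i_co is not None and i_co < len(row) else ""
                co = [c for c in co_raw.split(";")] if co_raw.strip() else []
                pairs.append(LRPair(ligand, receptor, co))
            except (IndexError, ValueError) as e:
                raise MalformedRowError(f"{path} line {lineno}: {e}") from e
    return pairs


def filter_cells(m: CountMatrix, min_genes: int = 200) -> CountMatrix:
    """Drop cells expressing fewer than ``min_genes`` distinct genes.

    The default of 200 is the conventional empty-droplet / low-quality cell
    threshold for droplet scRNA-seq. Gene set and column order are preserved;
    the operation only subsets columns and is idempotent.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    keep = m.genes_per_cell() >= min_genes
    if not keep.any():
        raise EmptyResultError(
            f"no cell expresses >= {min_genes} genes; review the min_genes threshold"
        )
    if keep.all():
        return m
    barcodes = [b for b, k in zip(m.barcodes, keep) if k]
    return CountMatrix(m.counts[:, keep].copy(), list(m.gene_ids), barcodes)


def write_interactions(scores: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an interaction score table as TSV.

    Columns: ligand, receptor, sender, receiver, strength, p_value, q_value.
    Floats are written repr-faithfully so a read-back round-trips.
    """
    cols = ["ligand", "receptor", "sender", "receiver", "strength", "p_value", "q_value"]
    out = pd.DataFrame(scores, columns=cols) if len(scores) else pd.DataFrame(columns=cols)
    out = out[cols]
    out.to_csv(path, sep="\t", index=False)


def write_counts_mtx(m: CountMatrix, directory: str | os.PathLike) -> None:
    """Write a CountMatrix as an uncompressed 10x-style MTX triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sp = scipy.sparse.coo_matrix(m.counts)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp, field="integer")
    with open(directory / "genes.tsv", "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(m.barcodes) + ("\n" if m.barcodes else ""))


def write_annotations(ann: pd.DataFrame, path: str | os.PathLike) -> None:
    ann[["barcode", "cell_type"]].to_csv(path, sep="\t", index=False, header=False)
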