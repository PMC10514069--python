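"""Expression, ligand-receptor and coordinate I/O, plus assembly of the
coupled inputs (X^L, X^R, A) for one sender -> receiver cell-type pair.

All public containers are addressed by gene/cell ID; positional indexing is
an implementation detail. Matrices are dense float arrays of shape
(genes, cells) and must be non-negative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    CellTypeError,
    DimensionMismatchError,
    DuplicateIDError,
    EmptyInputError,
    EmptyTableError,
    MissingColumnError,
    NegativeEntryError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "LigandReceptorDB",
    "CoupledInputs",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_lr_table",
    "write_lr_table",
    "read_coordinates",
    "normalize_expression",
    "build_coupled_inputs",
    "ordered_type_pairs",
]


@dataclass
class ExpressionMatrix:
    """Non-negative gene x cell expression matrix with ID sidecars.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
    gene_ids, cell_ids : ordered unique identifiers
    cell_types : per-cell type label, aligned to ``cell_ids``
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.cell_ids = [str(c).strip() for c in self.cell_ids]
        self.cell_types = [str(t).strip() for t in self.cell_types]
        if self.values.ndim != 2:
            raise DimensionMismatchError(
                f"expression matrix must be 2-D, got {self.values.ndim}-D"
            )
        ng, nc = self.values.shape
        if ng != len(self.gene_ids):
            raise DimensionMismatchError(
                f"{ng} matrix rows but {len(self.gene_ids)} gene IDs"
            )
        if nc != len(self.cell_ids):
            raise DimensionMismatchError(
                f"{nc} matrix columns but {len(self.cell_ids)} cell IDs"
            )
        if len(self.cell_types) != nc:
            raise DimensionMismatchError(
                f"{len(self.cell_types)} cell-type labels for {nc} cells"
            )
        if len(set(self.gene_ids)) != ng:
            raise DuplicateIDError("duplicate gene IDs")
        if len(set(self.cell_ids)) != nc:
            raise DuplicateIDError("duplicate cell IDs")
        if ng and nc and np.min(self.values) < 0:
            raise NegativeEntryError("expression matrix has a negative entry")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset(
        self, genes: Sequence[str] | None = None, cells: Sequence[str] | None = None
    ) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given gene/cell IDs (input order kept)."""
        gi = self.gene_index(genes) if genes is not None else np.arange(self.n_genes)
        if cells is not None:
            lookup = {c: i for i, c in enumerate(self.cell_ids)}
            ci = np.array([lookup[c] for c in cells], dtype=int)
        else:
            ci = np.arange(self.n_cells)
        return ExpressionMatrix(
            values=self.values[np.ix_(gi, ci)],
            gene_ids=[self.gene_ids[i] for i in gi],
            cell_ids=[self.cell_ids[i] for i in ci],
            cell_types=[self.cell_types[i] for i in ci],
        )


@dataclass
class LigandReceptorDB:
    """A set of ligand->receptor gene pairs and the binary indicator matrix A.

    ``A[i, j] == 1`` iff ``(ligand_universe[i], receptor_universe[j])`` is a
    known pair. A is oriented ligand-rows x receptor-columns throughout the
    package.
    """

    pairs: set[tuple[str, str]]
    ligand_universe: list[str] = field(default_factory=list)
    receptor_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = {(str(l).strip(), str(r).strip()) for l, r in self.pairs}
        if not self.ligand_universe:
            self.ligand_universe = sorted({l for l, _ in self.pairs})
        if not self.receptor_universe:
            self.receptor_universe = sorted({r for _, r in self.pairs})
        lig = set(self.ligand_universe)
        rec = set(self.receptor_universe)
        for l, r in self.pairs:
            if l not in lig or r not in rec:
                raise MissingColumnError(
                    f"pair ({l}, {r}) not covered by the gene universes"
                )

    @property
    def A(self) -> np.ndarray:
        a = np.zeros((len(self.ligand_universe), len(self.receptor_universe)))
        li = {g: i for i, g in enumerate(self.ligand_universe)}
        ri = {g: i for i, g in enumerate(self.receptor_universe)}
        for l, r in self.pairs:
            a[li[l], ri[r]] = 1.0
        return a

    def indicator_for(
        self, ligand_genes: Sequence[str], receptor_genes: Sequence[str]
    ) -> np.ndarray:
        """Indicator sub-matrix aligned to arbitrary gene orderings."""
        a = np.zeros((len(ligand_genes), len(receptor_genes)))
        ri = {g: j for j, g in enumerate(receptor_genes)}
        for i, l in enumerate(ligand_genes):
            for ll, rr in self.pairs:
                if ll == l and rr in ri:
                    a[i, ri[rr]] = 1.0
        return a


@dataclass
class CoupledInputs:
    """The aligned triple (X^L, X^R, A) for one sender -> receiver pair.

    ``XL`` holds ligand genes x sender cells, ``XR`` receptor genes x
    receiver cells, and ``A`` couples XL rows to XR rows.
    """

    XL: ExpressionMatrix
    XR: ExpressionMatrix
    A: np.ndarray
    sender_type: str = "sender"
    receiver_type: str = "receiver"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.XL.n_genes, self.XR.n_genes):
            raise DimensionMismatchError(
                f"A shape {self.A.shape} != ({self.XL.n_genes}, {self.XR.n_genes})"
            )

    @property
    def n_senders(self) -> int:
        return self.XL.n_cells

    @property
    def n_receivers(self) -> int:
        return self.XR.n_cells


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip().split("\t")[0] for ln in fh if ln.strip()]


def read_expression_matrix(
    path_matrix: str | Path,
    path_genes: str | Path | None = None,
    path_cells: str | Path | None = None,
    path_labels: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a gene x cell matrix from Matrix Market triplet or dense TSV/CSV.

    Matrix Market input requires gene and cell sidecar files (one ID per
    line). Dense input carries cell IDs in the header row and gene IDs in
    the first column; sidecars, when given, override those. ``path_labels``
    is a two-column TSV (cell_id, cell_type) joined by cell ID; absent
    labels default to "unknown".
    """
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_genes is None or path_cells is None:
            raise MissingColumnError("Matrix Market input requires gene and cell sidecars")
        mat = scipy.io.mmread(path_matrix)
        values = mat.toarray() if scipy.sparse.issparse(mat) else np.asarray(mat, dtype=float)
        gene_ids = _read_lines(path_genes)
        cell_ids = _read_lines(path_cells)
    else:
        sep = "," if path_matrix.suffix == ".csv" else "\t"
        df = pd.read_csv(path_matrix, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        if path_genes is not None:
            gene_ids = _read_lines(path_genes)
        if path_cells is not None:
            cell_ids = _read_lines(path_cells)
    if values.shape != (len(gene_ids), len(cell_ids)):
        raise DimensionMismatchError(
            f"matrix shape {values.shape} != ({len(gene_ids)}, {len(cell_ids)})"
        )
    if values.size and values.min() < 0:
        raise NegativeEntryError(f"negative entry in {path_matrix}")

    if path_labels is not None:
        lab = pd.read_csv(path_labels, sep="\t", header=None, names=["cell_id", "cell_type"],
                          dtype=str, comment="#")
        if {"cell_id", "cell_type"} <= set(lab.iloc[0].values):
            lab = lab.iloc[1:]  # tolerate a header row
        mapping = dict(zip(lab["cell_id"].str.strip(), lab["cell_type"].str.strip()))
        missing = [c for c in cell_ids if c not in mapping]
        if missing:
            raise DimensionMismatchError(
                f"{len(missing)} cells missing from the label table (e.g. {missing[0]})"
            )
        cell_types = [mapping[c] for c in cell_ids]
    else:
        cell_types = ["unknown"] * len(cell_ids)
    return ExpressionMatrix(values, gene_ids, cell_ids, cell_types)


def write_expression_matrix(
    m: ExpressionMatrix,
    path_matrix: str | Path,
    path_genes: str | Path | None = None,
    path_cells: str | Path | None = None,
    path_labels: str | Path | None = None,
) -> None:
    """Write a matrix in the format implied by the suffix (.mtx or dense TSV)."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        scipy.io.mmwrite(path_matrix, scipy.sparse.coo_matrix(m.values))
        if path_genes is None or path_cells is None:
            raise MissingColumnError("Matrix Market output requires sidecar paths")
        Path(path_genes).write_text("".join(f"{g}\n" for g in m.gene_ids))
        Path(path_cells).write_text("".join(f"{c}\n" for c in m.cell_ids))
    else:
        df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
        df.to_csv(path_matrix, sep="\t")
    if path_labels is not None:
        Path(path_labels).write_text(
            "".join(f"{c}\t{t}\n" for c, t in zip(m.cell_ids, m.cell_types))
        )


def read_lr_table(path: str | Path) -> LigandReceptorDB:
    """Read a ligand-receptor pair table (TSV/CSV with columns ligand, receptor)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "ligand" not in cols or "receptor" not in cols:
        raise MissingColumnError(f"{path} lacks 'ligand'/'receptor' columns")
    df = df[[cols["ligand"], cols["receptor"]]].dropna()
    if df.empty:
        raise EmptyTableError(f"{path} contains no ligand-receptor pairs")
    pairs = {(l.strip(), r.strip()) for l, r in df.itertuples(index=False)}
    return LigandReceptorDB(pairs=pairs)


def write_lr_table(db: LigandReceptorDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ligand\treceptor\n")
        for l, r in sorted(db.pairs):
            fh.write(f"{l}\t{r}\n")


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read per-cell coordinates (TSV: cell_id, x, y)."""
    df = pd.read_csv(path, sep="\t")
    need = {"cell_id", "x", "y"}
    if not need <= set(df.columns):
        raise MissingColumnError(f"{path} lacks columns {need - set(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def normalize_expression(m: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Per-cell count scaling to ``scale`` followed by log1p.

    Each column is rescaled to sum to ``scale`` (all-zero columns are left
    untouched), then log(1 + x) is applied elementwise. This is the standard
    library-size normalization used for UMI count matrices.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = m.values.sum(axis=0)
    factors = np.where(totals > 0, scale / np.where(totals > 0, totals, 1.0), 0.0)
    values = np.log1p(m.values * factors[np.newaxis, :])
    return ExpressionMatrix(values, list(m.gene_ids), list(m.cell_ids), list(m.cell_types))


def build_coupled_inputs(
    m: ExpressionMatrix,
    lr: LigandReceptorDB,
    sender_type: str,
    receiver_type: str,
    min_cells: int = 5,
) -> CoupledInputs:
    """Assemble (X^L, X^R, A) for one ordered sender -> receiver pair.

    X^L keeps ligand genes present in ``m`` with nonzero total expression in
    the sender cells (input row order preserved); X^R analogously for
    receptor genes in receiver cells. A is the indicator sub-matrix aligned
    to the retained rows; pairs whose ligand or receptor was dropped leave
    no 1-entry.
    """
    types = np.asarray(m.cell_types)
    for t in (sender_type, receiver_type):
        n = int((types == t).sum())
        if n == 0:
            raise CellTypeError(f"cell type {t!r} absent from the matrix")
        if n < min_cells:
            raise CellTypeError(
                f"cell type {t!r} has {n} cells, fewer than min_cells={min_cells}"
            )
    sender_cells = [c for c, t in zip(m.cell_ids, m.cell_types) if t == sender_type]
    receiver_cells = [c for c, t in zip(m.cell_ids, m.cell_types) if t == receiver_type]

    lig_set = set(lr.ligand_universe)
    rec_set = set(lr.receptor_universe)

    def _side(gene_filter: set, cells: list[str]) -> ExpressionMatrix:
        genes = [g for g in m.gene_ids if g in gene_filter]
        sub = m.subset(genes=genes, cells=cells)
        keep = sub.values.sum(axis=1) > 0
        return ExpressionMatrix(
            sub.values[keep],
            [g for g, k in zip(sub.gene_ids, keep) if k],
            sub.cell_ids,
            sub.cell_types,
        )

    XL = _side(lig_set, sender_cells)
    XR = _side(rec_set, receiver_cells)
    if XL.n_genes == 0:
        raise EmptyInputError("no expressed ligand genes for the sender cells")
    if XR.n_genes == 0:
        raise EmptyInputError("no expressed receptor genes for the receiver cells")
    A = lr.indicator_for(XL.gene_ids, XR.gene_ids)
    return CoupledInputs(XL=XL, XR=XR, A=A,
                         sender_type=sender_type, receiver_type=receiver_type)


def ordered_type_pairs(cell_types: Iterable[str]) -> list[tuple[str, str]]:
    """All ordered (sender, receiver) pairs of distinct cell types.

    Types are deduplicated keeping first-appearance order; n types yield
    n*(n-1) directed pairs.
    """
    seen: list[str] = []
    for t in cell_types:
        if t not in seen:
            seen.append(t)
    return [p for p in itertools.permutations(seen, 2)]
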