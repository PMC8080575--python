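"""Expression-matrix I/O, normalization, QC filtering, and marker-based cell typing.

The pipeline works on gene x cell matrices of log-scale expression values

    E_ij = log2(TPM_ij / 10 + 1)            (full-length protocol)
    E_ij = log2(pseudoTPM_ij + 1)           (droplet protocol)

where pseudoTPM rescales each cell's UMI counts to a total of 10,000.
"E > 1" is the confident-expression call used throughout QC and the
interaction analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "QCReport",
    "MarkerRule",
    "log_normalize_tpm",
    "pseudo_tpm_normalize",
    "filter_cells_genes",
    "filter_droplet_cells",
    "call_cell_types_by_markers",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_expression_mtx",
    "write_expression_mtx",
]

# Equality clauses ("EPCAM = 0") are evaluated as |E| < this, absorbing float noise.
ZERO_TOL = 1e-12

Transform = Literal["tpm", "pseudotpm", "precomputed"]


class ValidationError(ValueError):
    """Raised when an input matrix violates a declared precondition."""


@dataclass
class ExpressionMatrix:
    """Gene x cell matrix of log-scale expression values.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and cell ids as columns.
        All entries must be finite and >= 0 (log-scale E units).
    cell_meta
        Per-cell metadata indexed by cell id. Conventional columns:
        ``sample`` (donor/sample label), ``platform``, ``group``.
    transform
        Provenance of the values: ``tpm`` (log2(TPM/10+1)),
        ``pseudotpm`` (log2(pseudoTPM+1)) or ``precomputed``.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame
    transform: Transform = "precomputed"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if not self.values.columns.is_unique:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell ids: {dups[:5]}")
        if not self.cell_meta.index.equals(self.values.columns):
            missing = self.values.columns.difference(self.cell_meta.index).tolist()
            if missing:
                raise ValidationError(f"cell_meta missing cells: {missing[:5]}")
            self.cell_meta = self.cell_meta.loc[self.values.columns]
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if arr.size and arr.min() < 0:
            raise ValidationError("expression values must be >= 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, genes=None, cells=None) -> "ExpressionMatrix":
        vals = self.values
        if genes is not None:
            vals = vals.loc[genes]
        if cells is not None:
            vals = vals[list(cells)]
        return ExpressionMatrix(vals, self.cell_meta.loc[vals.columns], self.transform)


@dataclass
class QCReport:
    """Bookkeeping for a filtering step: what went in, what survived, and why."""

    cells_in: int
    cells_out: int
    genes_in: int
    genes_out: int
    removed_cell_ids: list[str]
    removed_gene_ids: list[str]
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.cells_out <= self.cells_in
        assert self.genes_out <= self.genes_in
        assert self.cells_in == self.cells_out + len(self.removed_cell_ids)
        assert self.genes_in == self.genes_out + len(self.removed_gene_ids)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass(frozen=True)
class MarkerRule:
    """A conjunction of per-gene expression clauses defining one cell type.

    Each clause is ``(gene_id, comparator, threshold)`` with comparator one
    of ``>``, ``<`` or ``==``; thresholds are in E units. A cell receives
    ``label`` iff every clause holds.
    """

    label: str
    clauses: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        for gene, op, _ in self.clauses:
            if op not in (">", "<", "=="):
                raise ValidationError(f"unknown comparator {op!r} in rule {self.label!r} ({gene})")


def _default_meta(cell_ids: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))


def _check_nonnegative_finite(df: pd.DataFrame, what: str) -> None:
    arr = df.to_numpy()
    bad = ~np.isfinite(arr) | (arr < 0)
    if bad.any():
        gi, ci = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what} must be finite and >= 0; offending entry at "
            f"gene {df.index[gi]!r}, cell {df.columns[ci]!r} = {arr[gi, ci]!r}"
        )


def tpm_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Rescale a count matrix column-wise to TPM units (each cell sums to 1e6)."""
    _check_nonnegative_finite(counts, "counts")
    totals = counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValidationError(f"all-zero cell columns: {zero}")
    return counts.div(totals, axis=1) * 1e6


def log_normalize_tpm(tpm: pd.DataFrame, cell_meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Transform a TPM matrix to E = log2(TPM/10 + 1).

    The /10 deflation damps the inflation of TPM values in low-complexity
    single-cell libraries before the log transform.
    """
    _check_nonnegative_finite(tpm, "TPM")
    e = np.log2(tpm / 10.0 + 1.0)
    meta = cell_meta if cell_meta is not None else _default_meta(tpm.columns)
    return ExpressionMatrix(e, meta, transform="tpm")


def pseudo_tpm_normalize(umi: pd.DataFrame, cell_meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Rescale droplet UMI counts per cell to 10,000 and take log2(x + 1).

    pseudoTPM_ij = UMI_ij / total_j * 10,000;  E_ij = log2(pseudoTPM_ij + 1).
    """
    _check_nonnegative_finite(umi, "UMI counts")
    totals = umi.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValidationError(f"all-zero cell columns: {zero}")
    pseudo = umi.div(totals, axis=1) * 10_000.0
    e = np.log2(pseudo + 1.0)
    meta = cell_meta if cell_meta is not None else _default_meta(umi.columns)
    return ExpressionMatrix(e, meta, transform="pseudotpm")


def filter_cells_genes(
    E: ExpressionMatrix,
    min_genes: int = 1000,
    min_cells: int = 10,
    expr_threshold: float = 1.0,
) -> tuple[ExpressionMatrix, QCReport]:
    """Drop unreliable cells, then unreliable genes, in a single pass.

    A gene is "expressed" in a cell iff E strictly exceeds ``expr_threshold``.
    Cells expressing fewer than ``min_genes`` genes are removed first; genes
    expressed in fewer than ``min_cells`` of the retained cells are removed
    second. The order (cells before genes, one pass) is recorded in the report.
    """
    if min(min_genes, min_cells) < 0 or expr_threshold < 0:
        raise ValidationError("thresholds must be >= 0")
    expressed = E.values.to_numpy() > expr_threshold

    keep_cells = expressed.sum(axis=0) >= min_genes
    keep_genes = expressed[:, keep_cells].sum(axis=1) >= min_cells

    if not keep_cells.any() or not keep_genes.any():
        raise ValidationError(
            f"filtering removed everything ({int(keep_cells.sum())} cells, "
            f"{int(keep_genes.sum())} genes left); relax the thresholds"
        )

    out = E.subset(genes=E.gene_ids[keep_genes], cells=E.cell_ids[keep_cells])
    report = QCReport(
        cells_in=E.n_cells,
        cells_out=out.n_cells,
        genes_in=E.n_genes,
        genes_out=out.n_genes,
        removed_cell_ids=E.cell_ids[~keep_cells].tolist(),
        removed_gene_ids=E.gene_ids[~keep_genes].tolist(),
        thresholds={
            "min_genes": min_genes,
            "min_cells": min_cells,
            "expr_threshold": expr_threshold,
            "order": "cells_then_genes_single_pass",
        },
    )
    return out, report


def filter_droplet_cells(
    counts: pd.DataFrame,
    mito_gene_ids: Sequence[str],
    min_counts: int = 1_000,
    max_counts: int = 150_000,
    min_features: int = 200,
    max_features: int = 10_000,
    max_mito_pct: float = 20.0,
) -> tuple[pd.DataFrame, QCReport]:
    """Keep droplet cells passing all three inclusive QC bounds.

    (1) min_counts <= nCounts <= max_counts, (2) min_features <= nFeatures
    <= max_features (genes with count > 0), (3) mitochondrial percentage
    <= max_mito_pct, where the percentage is 100 x mito counts / total counts.
    """
    _check_nonnegative_finite(counts, "UMI counts")
    mito = [g for g in mito_gene_ids if g in counts.index]
    if not mito:
        import warnings

        warnings.warn("no mitochondrial gene ids found in the matrix; mito filter is a no-op")
    n_counts = counts.sum(axis=0)
    n_features = (counts > 0).sum(axis=0)
    mito_counts = counts.loc[mito].sum(axis=0) if mito else pd.Series(0.0, index=counts.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = 100.0 * mito_counts / n_counts.replace(0, np.nan)
    mito_pct = mito_pct.fillna(0.0)

    keep = (
        (n_counts >= min_counts)
        & (n_counts <= max_counts)
        & (n_features >= min_features)
        & (n_features <= max_features)
        & (mito_pct <= max_mito_pct)
    )
    out = counts.loc[:, keep]
    report = QCReport(
        cells_in=counts.shape[1],
        cells_out=out.shape[1],
        genes_in=counts.shape[0],
        genes_out=counts.shape[0],
        removed_cell_ids=counts.columns[~keep].tolist(),
        removed_gene_ids=[],
        thresholds={
            "min_counts": min_counts,
            "max_counts": max_counts,
            "min_features": min_features,
            "max_features": max_features,
            "max_mito_pct": max_mito_pct,
        },
    )
    return out, report


def call_cell_types_by_markers(E: ExpressionMatrix, rules: Sequence[MarkerRule]) -> pd.DataFrame:
    """Assign a cell-type label per cell from marker-threshold rules.

    A cell receives a rule's label iff all of the rule's clauses hold. Cells
    matching zero rules, or more than one, are labelled ``unassigned``; the
    ``ambiguous`` column flags the >= 2 case.

    Returns a DataFrame indexed by cell id with columns ``label``,
    ``n_rules_matched`` and ``ambiguous``.
    """
    for rule in rules:
        for gene, _, _ in rule.clauses:
            if gene not in E.gene_ids:
                raise ValidationError(f"marker gene {gene!r} (rule {rule.label!r}) not in matrix")

    matched = np.zeros((len(rules), E.n_cells), dtype=bool)
    for i, rule in enumerate(rules):
        ok = np.ones(E.n_cells, dtype=bool)
        for gene, op, thr in rule.clauses:
            x = E.values.loc[gene].to_numpy()
            if op == ">":
                ok &= x > thr
            elif op == "<":
                ok &= x < thr
            else:  # == ; in practice "== 0" for absent markers
                ok &= np.abs(x - thr) < ZERO_TOL
        matched[i] = ok

    n_matched = matched.sum(axis=0)
    labels = np.where(
        n_matched == 1,
        np.array([r.label for r in rules], dtype=object)[matched.argmax(axis=0)],
        "unassigned",
    )
    return pd.DataFrame(
        {"label": labels, "n_rules_matched": n_matched, "ambiguous": n_matched >= 2},
        index=E.cell_ids,
    )


# ---------------------------------------------------------------------------
# Readers / writers. Orientation on disk is genes = rows throughout; MTX
# matrices ship with genes.tsv / cells.tsv label files (one id per line).
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x cells TSV with a header row of cell ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a MatrixMarket triplet matrix with sibling genes.tsv/cells.tsv labels."""
    mtx_path = Path(mtx_path)
    if genes_path is None:
        genes_path = mtx_path.with_name(f"{mtx_path.stem}_genes.tsv")
        if not genes_path.exists():
            genes_path = mtx_path.parent / "genes.tsv"
    genes_path = Path(genes_path)
    if cells_path is None:
        cells_path = mtx_path.with_name(f"{mtx_path.stem}_cells.tsv")
        if not cells_path.exists():
            cells_path = mtx_path.parent / "cells.tsv"
    cells_path = Path(cells_path)
    mat = spio.mmread(mtx_path)
    genes = genes_path.read_text().split()
    cells = cells_path.read_text().split()
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    if dense.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix shape {dense.shape} does not match labels ({len(genes)} genes, {len(cells)} cells)"
        )
    return pd.DataFrame(dense, index=pd.Index(genes, name="gene_id"), columns=cells)


def write_expression_mtx(df: pd.DataFrame, out_dir: str | Path, name: str = "matrix") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / f"{name}.mtx", sparse.csr_matrix(df.to_numpy()))
    (out / f"{name}_genes.tsv").write_text("\n".join(map(str, df.index)) + "\n")
    (out / f"{name}_cells.tsv").write_text("\n".join(map(str, df.columns)) + "\n")
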