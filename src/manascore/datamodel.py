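"""Core in-memory containers for the scoring pipeline.

The central object is :class:`ExpressionBundle`, a genes x cells container
holding the raw UMI count layer and the derived layers the scorer consumes
(log-normalized, imputed, quantile-normalized imputed).  Cell-level metadata
travels as a plain :class:`pandas.DataFrame` with a validated schema
(:func:`validate_annotations`), and clones are summarized by
:class:`CloneRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

TISSUES = ("tumor", "normal", "other")
ANTIGEN_LABELS = ("tumor_reactive", "bystander", "unknown")
RESPONSE_LABELS = ("responder", "non_responder", "not_applicable")

#: The three signature genes, in canonical order.
SIGNATURE_GENES = ("CXCL13", "ENTPD1", "IL7R")

ANNOTATION_COLUMNS = (
    "barcode",
    "patient_id",
    "sample_id",
    "tissue",
    "clonotype_id",
    "antigen_label",
    "response_label",
)


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class FormatError(ValueError):
    """Raised when an on-disk input is structurally malformed."""


def _check_unique(values: Sequence[str], what: str) -> None:
    arr = pd.Index(values)
    if arr.has_duplicates:
        dups = arr[arr.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionBundle:
    """Genes x cells expression container with named layers.

    Parameters
    ----------
    gene_ids : array of unique gene symbols (rows).
    cell_barcodes : array of unique cell barcodes (columns).
    layer_raw : non-negative integer counts, genes x cells, sparse or dense.
    layer_norm, layer_imputed, layer_imputed_qn : derived layers, absent
        (``None``) until produced by the normalization/imputation steps.
    provenance : free-form record of how derived layers were made
        (method names, parameters, seeds).
    """

    gene_ids: np.ndarray
    cell_barcodes: np.ndarray
    layer_raw: sp.spmatrix | np.ndarray
    layer_norm: np.ndarray | None = None
    layer_imputed: np.ndarray | None = None
    layer_imputed_qn: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        _check_unique(self.gene_ids, "gene symbol")
        _check_unique(self.cell_barcodes, "cell barcode")
        shape = (len(self.gene_ids), len(self.cell_barcodes))
        for name in ("layer_raw", "layer_norm", "layer_imputed", "layer_imputed_qn"):
            layer = getattr(self, name)
            if layer is None:
                continue
            if layer.shape != shape:
                raise ValidationError(
                    f"{name} has shape {layer.shape}, expected {shape}"
                )
        raw = self.layer_raw
        data = raw.data if sp.issparse(raw) else np.asarray(raw)
        if data.size:
            if np.any(data < 0):
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("raw counts must be integers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genes, self.n_cells)

    def raw_dense(self) -> np.ndarray:
        raw = self.layer_raw
        return np.asarray(raw.todense()) if sp.issparse(raw) else np.asarray(raw)

    def gene_index(self, symbol: str) -> int:
        idx = np.flatnonzero(self.gene_ids == symbol)
        if idx.size == 0:
            raise KeyError(f"gene {symbol!r} not present in bundle")
        return int(idx[0])

    def get_layer(self, name: str) -> np.ndarray | sp.spmatrix:
        layer = getattr(self, f"layer_{name}", None)
        if layer is None:
            raise ValidationError(f"layer {name!r} has not been produced yet")
        return layer

    def gene_values(self, symbol: str, layer: str = "raw") -> np.ndarray:
        """One gene's values across all cells from the named layer."""
        mat = self.get_layer(layer)
        row = mat[self.gene_index(symbol)]
        if sp.issparse(mat):
            row = row.toarray().ravel()
        return np.asarray(row, dtype=float).ravel()

    def subset_genes(self, mask_or_idx) -> "ExpressionBundle":
        idx = np.asarray(mask_or_idx)
        idx = np.flatnonzero(idx) if idx.dtype == bool else idx.astype(int)
        return ExpressionBundle(
            gene_ids=self.gene_ids[idx],
            cell_barcodes=self.cell_barcodes,
            layer_raw=_take_rows(self.layer_raw, idx),
            layer_norm=_take_rows(self.layer_norm, idx),
            layer_imputed=_take_rows(self.layer_imputed, idx),
            layer_imputed_qn=_take_rows(self.layer_imputed_qn, idx),
            provenance=dict(self.provenance),
        )

    def subset_cells(self, mask_or_idx) -> "ExpressionBundle":
        idx = np.asarray(mask_or_idx)
        idx = np.flatnonzero(idx) if idx.dtype == bool else idx.astype(int)
        return ExpressionBundle(
            gene_ids=self.gene_ids,
            cell_barcodes=self.cell_barcodes[idx],
            layer_raw=_take_cols(self.layer_raw, idx),
            layer_norm=_take_cols(self.layer_norm, idx),
            layer_imputed=_take_cols(self.layer_imputed, idx),
            layer_imputed_qn=_take_cols(self.layer_imputed_qn, idx),
            provenance=dict(self.provenance),
        )


def _take_rows(layer, idx):
    if layer is None:
        return None
    out = layer.tocsr()[idx] if sp.issparse(layer) else layer[idx]
    return out


def _take_cols(layer, idx):
    if layer is None:
        return None
    out = layer.tocsc()[:, idx] if sp.issparse(layer) else layer[:, idx]
    return out


@dataclass
class CloneRecord:
    """One TCR clone: its members and its pTRC-relevant summaries."""

    clone_id: str
    patient_id: str
    cdr3_beta: str
    member_barcodes: list
    size: int
    n_high: int = 0
    is_cross_patient: bool = False
    is_ptrc: bool = False

    def __post_init__(self) -> None:
        if self.size != len(self.member_barcodes) or self.size < 1:
            raise ValidationError(
                f"clone {self.clone_id}: size {self.size} != "
                f"{len(self.member_barcodes)} members"
            )
        if not (0 <= self.n_high <= self.size):
            raise ValidationError(f"clone {self.clone_id}: n_high out of range")


@dataclass
class GeneSet:
    """A named, duplicate-free gene list."""

    name: str
    genes: list

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"gene in set {self.name!r}")


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a per-cell annotation table.

    Requires the columns in :data:`ANNOTATION_COLUMNS` (extras are kept as
    opaque passthrough columns).  Enum columns are checked against their
    allowed tokens; an empty/missing clonotype becomes ``None``.
    """
    df = df.copy()
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns and c != "clonotype_id"]
    if missing:
        raise ValidationError(f"annotation table missing columns: {missing}")
    if "clonotype_id" not in df.columns:
        df["clonotype_id"] = None
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValidationError(f"barcode {dup!r} appears in more than one row")
    clono = df["clonotype_id"]
    df["clonotype_id"] = clono.where(clono.notna() & (clono.astype(str) != ""), None)
    for col, allowed in (
        ("tissue", TISSUES),
        ("antigen_label", ANTIGEN_LABELS),
        ("response_label", RESPONSE_LABELS),
    ):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"invalid {col} value {df.loc[row, col]!r} in row {row} "
                f"(allowed: {allowed})"
            )
    return df


def clones_to_frame(clones: Mapping[str, CloneRecord] | Sequence[CloneRecord]) -> pd.DataFrame:
    """Summarize clone records as a clone-per-row table."""
    records = list(clones.values()) if isinstance(clones, Mapping) else list(clones)
    return pd.DataFrame(
        {
            "clone_id": [c.clone_id for c in records],
            "patient_id": [c.patient_id for c in records],
            "cdr3_beta": [c.cdr3_beta for c in records],
            "size": [c.size for c in records],
            "n_high": [c.n_high for c in records],
            "is_cross_patient": [c.is_cross_patient for c in records],
            "is_ptrc": [c.is_ptrc for c in records],
        }
    )
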