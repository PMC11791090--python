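"""Readers and writers for the standard on-disk formats.

10x-convention triplets (Matrix Market counts + features/barcodes TSV,
gzip allowed), cell metadata TSV, clonotype CSV, one-symbol-per-line gene
sets, and the tab-separated score table.  Matrix Market parsing is
delegated to :mod:`scipy.io`; coordinates are 1-based on disk and 0-based
in memory.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import (
    ExpressionBundle,
    FormatError,
    GeneSet,
    ValidationError,
    validate_annotations,
)

SCORE_COLUMNS = ("barcode", "patient_id", "score_i", "score_ni", "overall", "high_flag")


def _find(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FormatError(f"none of {stems} found in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def dedupe_symbols(symbols) -> np.ndarray:
    """Disambiguate duplicated gene symbols with '.1', '.2' in file order."""
    out = []
    seen: dict[str, int] = {}
    for s in symbols:
        n = seen.get(s, 0)
        out.append(s if n == 0 else f"{s}.{n}")
        seen[s] = n + 1
    return np.asarray(out, dtype=object)


def read_10x_mtx(directory: str | Path) -> ExpressionBundle:
    """Read a 10x triplet directory into an :class:`ExpressionBundle`.

    Expects ``matrix.mtx[.gz]``, ``features.tsv[.gz]`` (or ``genes.tsv``)
    and ``barcodes.tsv[.gz]``.  Gene symbols come from the features file's
    symbol column (second column when present); duplicated symbols are
    suffixed ``.1``, ``.2`` in file order.  Duplicate barcodes are an
    error.
    """
    directory = Path(directory)
    mtx_path = _find(directory, ("matrix.mtx",))
    feat_path = _find(directory, ("features.tsv", "genes.tsv"))
    bc_path = _find(directory, ("barcodes.tsv",))

    with _open_text(mtx_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ValidationError(f"{mtx_path}: non-integer count entries")
    mat = mat.astype(np.int64)

    with _open_text(feat_path) as fh:
        feats = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    symbols = feats.iloc[:, 1] if feats.shape[1] >= 2 else feats.iloc[:, 0]
    gene_ids = dedupe_symbols(symbols.tolist())

    with _open_text(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    if len(set(barcodes)) != len(barcodes):
        raise ValidationError(f"{bc_path}: duplicate barcodes")

    if mat.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match "
            f"{len(gene_ids)} features x {len(barcodes)} barcodes"
        )
    return ExpressionBundle(
        gene_ids=gene_ids,
        cell_barcodes=np.asarray(barcodes, dtype=object),
        layer_raw=mat,
    )


def write_10x_mtx(bundle: ExpressionBundle, directory: str | Path) -> None:
    """Write the raw layer as a 10x triplet (uncompressed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    raw = bundle.layer_raw if sp.issparse(bundle.layer_raw) else sp.coo_matrix(bundle.layer_raw)
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(raw), field="integer")
    (directory / "matrix.mtx").write_bytes(buf.getvalue())
    feats = pd.DataFrame(
        {0: bundle.gene_ids, 1: bundle.gene_ids, 2: "Gene Expression"}
    )
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(bundle.cell_barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell metadata TSV.

    Unknown columns are preserved; enum columns are validated and an empty
    clonotype field becomes ``None``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    for col in ("tissue", "antigen_label", "response_label"):
        if col in df.columns and df[col].isna().any():
            raise ValidationError(f"{path}: empty {col} field")
    return validate_annotations(df)


def write_cell_metadata(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_clonotypes(path: str | Path) -> pd.DataFrame:
    """Read a clonotype CSV with columns barcode, clonotype_id, cdr3_beta."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False).replace({"": None})
    required = {"barcode", "clonotype_id", "cdr3_beta"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: clonotype table requires columns {sorted(required)}")
    return df


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene-set file."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return GeneSet(name=name or path.stem, genes=genes)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score table as TSV with >= 6 significant digits.

    Columns: barcode, patient_id, score_i, score_ni, overall, high_flag.
    A read-back via :func:`read_scores` reproduces the floats within 1e-9.
    """
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValidationError(f"score table missing columns: {missing}")
    out = scores.loc[:, list(SCORE_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.empty and list(df.columns) != list(SCORE_COLUMNS):
        raise FormatError(f"{path}: not a score table")
    return df
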