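"""Quality control and the density-trough CD8+ gate.

Cell filters: detected genes below a floor or more than ``sd_mult``
standard deviations above the median, mitochondrial fraction above a cap,
ribosomal fraction below a floor.  Gene filters: dissociation/stress
lists, mitochondrial (``MT-``), ribosomal-protein (``RPS``/``RPL``), TCR
(``TRA/TRB/TRD/TRG``) genes and genes detected in fewer than five cells.
CD8+ cells are gated at the first trough of the kernel density of
log2-transformed imputed CD8A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import gaussian_kde

from .datamodel import ExpressionBundle, GeneSet, ValidationError

CELL_REASONS = ("low_genes", "high_genes", "high_mito", "low_ribo")
GENE_REASONS = (
    "blacklist_dissociation",
    "blacklist_mito",
    "blacklist_ribo_prefix",
    "blacklist_tcr",
    "min_cells",
)
TCR_PREFIXES = ("TRAV", "TRAJ", "TRAC", "TRBV", "TRBD", "TRBJ", "TRBC",
                "TRDV", "TRDD", "TRDJ", "TRDC", "TRGV", "TRGJ", "TRGC")


@dataclass
class QCReport:
    """Per-cell and per-gene keep flags with machine-readable reasons."""

    cell_table: pd.DataFrame
    gene_table: pd.DataFrame | None
    thresholds: dict = field(default_factory=dict)

    @property
    def cell_mask(self) -> np.ndarray:
        return self.cell_table["keep"].to_numpy()

    def to_tsv(self, cell_path=None, gene_path=None) -> None:
        if cell_path is not None:
            self.cell_table.to_csv(cell_path, sep="\t", index=False)
        if gene_path is not None and self.gene_table is not None:
            self.gene_table.to_csv(gene_path, sep="\t", index=False)


def _is_mito(symbols: np.ndarray) -> np.ndarray:
    return np.char.startswith(symbols.astype(str), "MT-")


def _is_ribo(symbols: np.ndarray) -> np.ndarray:
    s = symbols.astype(str)
    return np.char.startswith(s, "RPS") | np.char.startswith(s, "RPL")


def _is_tcr(symbols: np.ndarray) -> np.ndarray:
    s = symbols.astype(str)
    out = np.zeros(len(s), dtype=bool)
    for p in TCR_PREFIXES:
        out |= np.char.startswith(s, p)
    return out


def qc_cell_mask(
    bundle: ExpressionBundle,
    min_genes: int = 250,
    sd_mult: float = 3.0,
    mito_max: float = 0.10,
    ribo_min: float = 0.10,
    max_genes: float | None = None,
) -> QCReport:
    """Joint cell-level QC on the raw count layer.

    Thresholds are computed once, on the input population (single pass);
    re-running on the surviving cells with the same thresholds removes
    nothing further.  ``max_genes`` overrides the median + ``sd_mult``
    standard deviations upper bound (e.g. to re-apply a previous run's
    threshold).
    """
    raw = bundle.layer_raw
    if bundle.n_cells == 0 or bundle.n_genes == 0:
        raise ValidationError("empty expression matrix")
    dense_counts = raw.tocsc() if sp.issparse(raw) else np.asarray(raw)
    if sp.issparse(raw):
        detected = np.asarray((dense_counts > 0).sum(axis=0)).ravel()
        totals = np.asarray(dense_counts.sum(axis=0)).ravel().astype(float)
        mito_counts = np.asarray(
            dense_counts[_is_mito(bundle.gene_ids)].sum(axis=0)
        ).ravel().astype(float)
        ribo_counts = np.asarray(
            dense_counts[_is_ribo(bundle.gene_ids)].sum(axis=0)
        ).ravel().astype(float)
    else:
        detected = (dense_counts > 0).sum(axis=0)
        totals = dense_counts.sum(axis=0).astype(float)
        mito_counts = dense_counts[_is_mito(bundle.gene_ids)].sum(axis=0).astype(float)
        ribo_counts = dense_counts[_is_ribo(bundle.gene_ids)].sum(axis=0).astype(float)

    upper = (
        float(max_genes)
        if max_genes is not None
        else float(np.median(detected) + sd_mult * np.std(detected))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)
        ribo_frac = np.where(totals > 0, ribo_counts / totals, 0.0)

    low_genes = detected < min_genes
    high_genes = detected > upper
    high_mito = mito_frac > mito_max
    low_ribo = ribo_frac < ribo_min
    keep = ~(low_genes | high_genes | high_mito | low_ribo)

    cell_table = pd.DataFrame(
        {
            "barcode": bundle.cell_barcodes,
            "keep": keep,
            "low_genes": low_genes,
            "high_genes": high_genes,
            "high_mito": high_mito,
            "low_ribo": low_ribo,
            "n_detected_genes": detected,
            "mito_frac": mito_frac,
            "ribo_frac": ribo_frac,
        }
    )
    thresholds = {
        "min_genes": min_genes,
        "max_genes": upper,
        "sd_mult": sd_mult,
        "mito_max": mito_max,
        "ribo_min": ribo_min,
    }
    return QCReport(cell_table=cell_table, gene_table=None, thresholds=thresholds)


def blacklist_genes(
    bundle: ExpressionBundle,
    dissociation_genes: GeneSet | None = None,
    min_cells: int = 5,
    return_report: bool = False,
):
    """Remove blacklisted and rarely detected genes.

    Drops dissociation/stress genes (user-supplied list), ``MT-`` genes,
    ribosomal-protein ``RPS``/``RPL`` genes, TCR V/D/J/C genes (clonotype
    bias), and genes detected (count > 0) in fewer than ``min_cells``
    cells.  A gene detected in exactly ``min_cells`` cells is kept.
    """
    symbols = bundle.gene_ids
    raw = bundle.layer_raw
    n_cells_per_gene = (
        np.asarray((raw > 0).sum(axis=1)).ravel()
        if sp.issparse(raw)
        else (np.asarray(raw) > 0).sum(axis=1)
    )
    diss = np.isin(symbols, dissociation_genes.genes) if dissociation_genes else np.zeros(
        len(symbols), dtype=bool
    )
    mito = _is_mito(symbols)
    ribo = _is_ribo(symbols)
    tcr = _is_tcr(symbols)
    rare = n_cells_per_gene < min_cells
    keep = ~(diss | mito | ribo | tcr | rare)
    if not keep.any():
        warnings.warn("gene blacklist removed every gene", stacklevel=2)
    out = bundle.subset_genes(keep)
    if not return_report:
        return out
    gene_table = pd.DataFrame(
        {
            "gene": symbols,
            "keep": keep,
            "blacklist_dissociation": diss,
            "blacklist_mito": mito,
            "blacklist_ribo_prefix": ribo,
            "blacklist_tcr": tcr,
            "min_cells": rare,
        }
    )
    return out, QCReport(cell_table=pd.DataFrame(), gene_table=gene_table,
                         thresholds={"min_cells": min_cells})


def density_grid(
    values: np.ndarray, bandwidth: str | float = "silverman", grid_size: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE evaluated on an even grid spanning [min, max]."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10:
        raise ValidationError("need at least 10 finite values for density estimation")
    if np.ptp(values) == 0:
        raise ValidationError("values have zero spread; no density trough exists")
    kde = gaussian_kde(values, bw_method=bandwidth)
    grid = np.linspace(values.min(), values.max(), grid_size)
    return grid, kde(grid)


def density_troughs(
    values,
    bandwidth: str | float = "silverman",
    grid_size: int = 512,
    min_prominence_frac: float = 0.05,
) -> list[float]:
    """Interior local minima of the kernel density, ascending.

    A trough is a density minimum lying strictly between two modes.  To
    keep the rule robust to kernel wiggle in sparse regions, only modes
    whose peak prominence exceeds ``min_prominence_frac`` of the density
    maximum count; the trough between two adjacent accepted modes is the
    grid point of minimum density in the open interval between them.
    A unimodal density yields an empty list; callers decide the fallback.
    """
    from scipy.signal import find_peaks

    grid, dens = density_grid(values, bandwidth=bandwidth, grid_size=grid_size)
    prominence = min_prominence_frac * float(dens.max())
    peaks, _ = find_peaks(dens, prominence=prominence)
    # a dominant boundary mode has no interior peak; pad with the edges
    # when the edge value exceeds every interior density before the first
    # (after the last) peak
    if peaks.size and dens[0] > dens[: peaks[0]].min() + prominence:
        peaks = np.concatenate([[0], peaks])
    if peaks.size and dens[-1] > dens[peaks[-1]:].min() + prominence:
        peaks = np.concatenate([peaks, [len(dens) - 1]])
    troughs = []
    for left, right in zip(peaks[:-1], peaks[1:]):
        if right - left < 2:
            continue
        inner = np.arange(left + 1, right)
        i = inner[np.argmin(dens[inner])]
        troughs.append(float(grid[i]))
    return sorted(troughs)


def cd8_gate(
    bundle: ExpressionBundle,
    gene: str = "CD8A",
    bandwidth: str | float = "silverman",
    grid_size: int = 512,
    pseudocount: float = 1.0,
    trough: str = "first",
) -> tuple[float, np.ndarray]:
    """Threshold log2-transformed imputed CD8A at a density trough.

    Returns ``(threshold, keep_mask)``; cells strictly above the threshold
    are called CD8+.  By default the first (lowest-location) trough is
    used; ``trough="last"`` selects the highest.
    """
    if bundle.layer_imputed is None:
        raise ValidationError("imputed layer required for CD8 gating")
    try:
        vals = bundle.gene_values(gene, layer="imputed")
    except KeyError as exc:
        raise ValidationError(str(exc)) from exc
    log_vals = np.log2(vals + pseudocount)
    troughs = density_troughs(log_vals, bandwidth=bandwidth, grid_size=grid_size)
    if not troughs:
        raise ValidationError(
            f"no density trough found for {gene}; supply a manual threshold"
        )
    threshold = troughs[0] if trough == "first" else troughs[-1]
    return threshold, log_vals > threshold
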