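"""Log-normalization, quantile normalization, and pluggable imputation.

The scorer consumes two layers: a log-normalized layer (counts scaled per
cell to ``scale`` total, ln(1+x) transformed) and an imputed layer that is
subsequently quantile-normalized across cells.  Imputation is a contract,
not an algorithm: ``identity`` de-logs the normalized layer, ``knn_smooth``
averages each cell's k nearest neighbors in PCA space.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datamodel import ExpressionBundle, ValidationError


def lognormalize(bundle: ExpressionBundle, scale: float = 10_000.0) -> ExpressionBundle:
    """Populate ``layer_norm`` with ln(1 + count / cell_total * scale).

    Zeros map to zeros; each cell's values depend only on its count
    proportions, so doubling a cell's counts leaves them unchanged.
    """
    raw = bundle.layer_raw
    dense = np.asarray(raw.todense(), dtype=float) if sp.issparse(raw) else np.asarray(
        raw, dtype=float
    )
    totals = dense.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bc = bundle.cell_barcodes[np.flatnonzero(zero)[0]]
        raise ValidationError(f"cell {bc!r} has zero total count; cannot normalize")
    bundle.layer_norm = np.log1p(dense / totals * scale)
    bundle.provenance["lognormalize"] = {"scale": scale}
    return bundle


def quantile_normalize(layer: np.ndarray) -> np.ndarray:
    """Classic quantile normalization across cells (columns).

    Within each cell, values are replaced by the mean across cells of the
    values at the same rank; tied values receive the average of the
    reference values their ranks span.  Afterwards every cell has an
    identical sorted value vector (up to tie-collapsing).
    """
    layer = np.asarray(layer, dtype=float)
    n_genes, n_cells = layer.shape
    if n_cells < 2:
        warnings.warn("quantile normalization of a single cell is the identity",
                      stacklevel=2)
        return layer.copy()
    reference = np.sort(layer, axis=0).mean(axis=1)
    out = np.empty_like(layer)
    for j in range(n_cells):
        col = layer[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # ties span several reference slots; give each tied group their mean
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size != n_genes:
            sums = np.bincount(inv, weights=assigned)
            cnts = np.bincount(inv)
            assigned = (sums / cnts)[inv]
        out[:, j] = assigned
    return out


def impute(
    bundle: ExpressionBundle,
    method: str = "identity",
    k: int = 15,
    n_pcs: int = 20,
    seed: int = 0,
) -> ExpressionBundle:
    """Populate ``layer_imputed`` via the pluggable imputation contract.

    ``identity``
        expm1 of the log-normalized layer (no smoothing).
    ``knn_smooth``
        Each cell's imputed expression is the uniform mean of expm1(norm)
        over its ``k`` nearest neighbors (self included) in the top
        ``n_pcs`` principal components of the log-normalized layer.

    Output is non-negative with unchanged dimensions.
    """
    if bundle.layer_norm is None:
        raise ValidationError("layer_norm required before imputation")
    norm = bundle.layer_norm
    expm1 = np.expm1(norm)
    if method == "identity":
        bundle.layer_imputed = expm1
    elif method == "knn_smooth":
        n_cells = norm.shape[1]
        if k >= n_cells:
            raise ValidationError(f"k={k} must be below the number of cells ({n_cells})")
        n_comp = min(n_pcs, norm.shape[0], n_cells - 1)
        pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(norm.T)
        nn = NearestNeighbors(n_neighbors=k).fit(pcs)
        conn = nn.kneighbors_graph(pcs, mode="connectivity")  # includes self
        weights = conn.multiply(1.0 / conn.sum(axis=1))
        bundle.layer_imputed = np.asarray((weights @ expm1.T).T)
    else:
        raise ValidationError(f"unknown imputation method {method!r}")
    bundle.layer_imputed = np.maximum(bundle.layer_imputed, 0.0)
    bundle.provenance["impute"] = {
        "method": method, "k": k, "n_pcs": n_pcs, "seed": seed,
    }
    return bundle


def quantile_normalize_bundle(bundle: ExpressionBundle) -> ExpressionBundle:
    """Quantile-normalize the imputed layer into ``layer_imputed_qn``."""
    if bundle.layer_imputed is None:
        raise ValidationError("layer_imputed required before quantile normalization")
    bundle.layer_imputed_qn = quantile_normalize(bundle.layer_imputed)
    bundle.provenance["quantile_normalize"] = {"scope": "all cells in bundle"}
    return bundle
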