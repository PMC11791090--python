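"""Clone-level pseudobulk statistics.

Differential expression between clone groups by Wilcoxon rank-sum on
pseudobulk profiles (exact enumeration for small groups, tie-corrected
normal approximation otherwise, Benjamini-Hochberg adjustment),
LOESS-based highly-variable-gene selection, batch adjustment, signature
scoring, DE rank correlation, and the pseudobulk PCA + canonical
correlation permutation test against a sample covariate.
"""

from __future__ import annotations

import itertools
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata, spearmanr
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .datamodel import CloneRecord, ExpressionBundle, GeneSet, ValidationError
from .scorer import module_score


def clone_pseudobulk(
    bundle: ExpressionBundle,
    clones: dict[str, CloneRecord],
    scale: float = 10_000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum raw counts within each clone, then log-normalize clones.

    Returns ``(norm, raw)`` clone x gene DataFrames; clones whose summed
    counts are all zero are dropped with a warning.  Total pseudobulk
    counts equal total member-cell counts (conservation).
    """
    if not clones:
        raise ValidationError("no clones to pseudobulk")
    raw = bundle.layer_raw
    raw = raw.tocsc() if sp.issparse(raw) else np.asarray(raw)
    col_of = {bc: i for i, bc in enumerate(bundle.cell_barcodes)}
    ids, profiles = [], []
    for clone_id in sorted(clones):
        cols = [col_of[bc] for bc in clones[clone_id].member_barcodes if bc in col_of]
        if not cols:
            continue
        block = raw[:, cols]
        summed = np.asarray(block.sum(axis=1)).ravel()
        if summed.sum() == 0:
            warnings.warn(f"clone {clone_id} has all-zero pseudobulk; dropped",
                          stacklevel=2)
            continue
        ids.append(clone_id)
        profiles.append(summed)
    raw_df = pd.DataFrame(profiles, index=ids, columns=bundle.gene_ids)
    totals = raw_df.sum(axis=1).to_numpy()[:, None]
    norm_df = np.log1p(raw_df / totals * scale)
    return norm_df, raw_df


@lru_cache(maxsize=32)
def _exact_ranksum_combos(n: int, m: int) -> np.ndarray:
    """All C(n+m, n) index choices for group A, as a one-hot matrix."""
    combos = list(itertools.combinations(range(n + m), n))
    onehot = np.zeros((len(combos), n + m))
    for i, c in enumerate(combos):
        onehot[i, list(c)] = 1.0
    return onehot


def ranksum_p_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration (ties allowed).

    p = P(|W - mu| >= |w_obs - mu|) over all assignments of the observed
    values to groups, with W the group-A rank sum and mu its null mean.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    ranks = rankdata(np.concatenate([a, b]))
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    onehot = _exact_ranksum_combos(n, m)
    w_all = onehot @ ranks
    return float(np.mean(np.abs(w_all - mu) >= np.abs(w_obs - mu) - 1e-12))


def ranksum_p_normal(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided tie-corrected normal-approximation rank-sum p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n + m) * (n + m - 1))
    var = n * m / 12.0 * ((n + m + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)  # continuity correction
    return float(2 * norm.sf(max(z, 0.0)))


def ranksum_p(a, b, exact_max: int = 10) -> float:
    """Two-sided rank-sum p; exact enumeration when both groups <= exact_max."""
    if len(a) <= exact_max and len(b) <= exact_max:
        return ranksum_p_exact(a, b)
    return ranksum_p_normal(a, b)


def de_wilcoxon(
    pseudobulk: pd.DataFrame,
    group_a: list,
    group_b: list,
    min_frac: float | None = 0.1,
    lfc_min: float | None = 0.25,
    exact_max: int = 10,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between clone groups.

    ``pseudobulk`` is the log-normalized clone x gene matrix.  log2FC is
    log2((mean expm1 A + 1) / (mean expm1 B + 1)).  Genes are pre-filtered
    to those detected in at least ``min_frac`` of either group with
    |log2FC| >= ``lfc_min`` (pass ``None`` to disengage either filter);
    BH adjustment runs over the tested genes.
    """
    a_rows = pseudobulk.loc[group_a]
    b_rows = pseudobulk.loc[group_b]
    if len(a_rows) < 2 or len(b_rows) < 2:
        raise ValidationError("each group needs at least 2 clones")
    a_mat, b_mat = a_rows.to_numpy(), b_rows.to_numpy()
    pct_a = (a_mat > 0).mean(axis=0)
    pct_b = (b_mat > 0).mean(axis=0)
    mean_a = np.expm1(a_mat).mean(axis=0)
    mean_b = np.expm1(b_mat).mean(axis=0)
    log2fc = np.log2((mean_a + 1) / (mean_b + 1))

    keep = np.ones(pseudobulk.shape[1], dtype=bool)
    if min_frac is not None:
        keep &= (pct_a >= min_frac) | (pct_b >= min_frac)
    if lfc_min is not None:
        keep &= np.abs(log2fc) >= lfc_min
    idx = np.flatnonzero(keep)
    pvals = np.array([
        ranksum_p(a_mat[:, j], b_mat[:, j], exact_max=exact_max) for j in idx
    ])
    p_adj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    out = pd.DataFrame(
        {
            "gene": pseudobulk.columns[idx],
            "log2FC": log2fc[idx],
            "p": pvals,
            "p_adj": p_adj,
            "pct_A": pct_a[idx],
            "pct_B": pct_b[idx],
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def rank_correlation(
    de_a: pd.DataFrame, de_b: pd.DataFrame, min_genes: int = 10
) -> tuple[float, float]:
    """Spearman correlation of log2 fold changes over shared genes.

    Tables are joined by gene symbol, so row order is irrelevant.
    """
    merged = de_a[["gene", "log2FC"]].merge(
        de_b[["gene", "log2FC"]], on="gene", suffixes=("_a", "_b")
    )
    if len(merged) < min_genes:
        raise ValidationError(
            f"only {len(merged)} shared genes; need >= {min_genes} for rank correlation"
        )
    rho, p = spearmanr(merged["log2FC_a"], merged["log2FC_b"])
    return float(rho), float(p)


def signature_scores(
    bundle: ExpressionBundle,
    gene_sets: dict[str, GeneSet],
    seed: int = 0,
    n_bins: int = 24,
    n_ctrl: int = 100,
) -> pd.DataFrame:
    """Module scores per cell for each named gene set."""
    if bundle.layer_norm is None:
        raise ValidationError("layer_norm required for signature scoring")
    out = {"barcode": bundle.cell_barcodes}
    for name, gs in gene_sets.items():
        out[name] = module_score(
            bundle.layer_norm, bundle.gene_ids, gs,
            n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
        )
    return pd.DataFrame(out)


def clone_mean_scores(
    scores: pd.DataFrame, clones: dict[str, CloneRecord]
) -> pd.DataFrame:
    """Average per-cell signature scores within each clone."""
    by_bc = scores.set_index("barcode")
    rows = {}
    for clone_id in sorted(clones):
        members = [bc for bc in clones[clone_id].member_barcodes if bc in by_bc.index]
        if members:
            rows[clone_id] = by_bc.loc[members].mean(numeric_only=True)
    return pd.DataFrame(rows).T


def hvg_loess(pseudobulk: pd.DataFrame, span: float = 0.75) -> list[str]:
    """Highly variable genes: positive residual of LOESS(SD ~ mean).

    Fits a locally weighted regression of per-gene standard deviation on
    per-gene mean over the clone/sample profiles and keeps genes whose SD
    exceeds the fitted trend.  A constant matrix yields an empty list.
    """
    if pseudobulk.shape[1] < 20:
        raise ValidationError("need >= 20 genes for LOESS HVG selection")
    means = pseudobulk.mean(axis=0).to_numpy()
    sds = pseudobulk.std(axis=0, ddof=1).to_numpy()
    if np.all(sds == 0):
        return []
    fitted = lowess(sds, means, frac=span, return_sorted=False)
    resid = sds - fitted
    return pseudobulk.columns[resid > 0].tolist()


def batch_adjust(
    profiles: pd.DataFrame,
    batches,
    method: str = "center_scale",
) -> pd.DataFrame:
    """Batch adjustment of sample x gene profiles (pluggable contract).

    ``center_scale`` standardizes each gene within batch and restores the
    pooled mean/SD; ``none`` is the identity.  Singleton batches pass
    through with a warning.
    """
    if method == "none":
        return profiles.copy()
    if method != "center_scale":
        raise ValidationError(f"unknown batch adjustment {method!r}")
    batches = np.asarray(batches)
    if len(batches) != len(profiles):
        raise ValidationError("batch labels must match sample count")
    mat = profiles.to_numpy(dtype=float).copy()
    pooled_mean = mat.mean(axis=0)
    pooled_sd = mat.std(axis=0, ddof=1)
    for b in np.unique(batches):
        rows = np.flatnonzero(batches == b)
        if len(rows) < 2:
            warnings.warn(f"singleton batch {b!r}: passthrough", stacklevel=2)
            continue
        bm = mat[rows].mean(axis=0)
        bs = mat[rows].std(axis=0, ddof=1)
        safe = bs > 0
        mat[np.ix_(rows, np.flatnonzero(safe))] = (
            (mat[rows][:, safe] - bm[safe]) / bs[safe] * pooled_sd[safe]
            + pooled_mean[safe]
        )
        const = np.flatnonzero(~safe)
        if const.size:
            mat[np.ix_(rows, const)] = mat[rows][:, const] - bm[const] + pooled_mean[const]
    return pd.DataFrame(mat, index=profiles.index, columns=profiles.columns)


def concatenate_hvg_profiles(
    cluster_profiles: dict[str, pd.DataFrame],
    span: float = 0.75,
) -> pd.DataFrame:
    """Per-sample concatenated HVG vectors across cell clusters.

    Each cluster's sample x gene pseudobulk is reduced to its LOESS HVGs
    and the retained columns are concatenated into one feature vector per
    sample (columns named ``cluster:gene``).
    """
    blocks = []
    for cluster, prof in sorted(cluster_profiles.items()):
        hvgs = hvg_loess(prof, span=span)
        if not hvgs:
            continue
        block = prof[hvgs].copy()
        block.columns = [f"{cluster}:{g}" for g in hvgs]
        blocks.append(block)
    if not blocks:
        raise ValidationError("no highly variable genes in any cluster")
    return pd.concat(blocks, axis=1)


def pseudobulk_cca(
    profiles: pd.DataFrame,
    covariate,
    n_perm: int = 10_000,
    seed: int = 0,
    n_components: int = 2,
) -> tuple[float, float]:
    """Canonical correlation of the top PCs with a sample covariate.

    Features are standardized to zero mean and unit variance, samples are
    embedded by PCA, and the canonical correlation of (PC1, PC2) with the
    covariate is the multiple correlation sqrt(R^2) of the covariate
    regressed on the two PCs.  Significance is a one-sided permutation
    test of the sample labels with the add-one estimator
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    y = np.asarray(covariate, dtype=float)
    if len(profiles) < 5:
        raise ValidationError("need >= 5 samples")
    if np.ptp(y) == 0:
        raise ValidationError("covariate is constant")
    X = profiles.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    n_comp = min(n_components, Xs.shape[0] - 1, Xs.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(Xs)

    def canon_r(yy: np.ndarray) -> float:
        yc = yy - yy.mean()
        P = pcs - pcs.mean(axis=0)
        beta, *_ = np.linalg.lstsq(P, yc, rcond=None)
        fitted = P @ beta
        denom = (yc**2).sum()
        return float(np.sqrt(max((fitted**2).sum() / denom, 0.0))) if denom > 0 else 0.0

    r_obs = canon_r(y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if canon_r(rng.permutation(y)) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, float(p)
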