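"""Synthetic multi-patient CD8+ TIL cohorts with ground truth.

Counts are negative-binomial per gene and cell.  Tumor-reactive cells
up-regulate CXCL13 (+2.5 log2FC) and ENTPD1 (+1.5) and down-regulate
IL7R (-1.5) relative to bystanders, with patient-level multiplicative
shifts on every gene.  Reactive clones are expanded (geometric clone
sizes, mean 8) while bystander clones are mostly singletons (mean 1.5).
A fraction of each patient's cells sit in adjacent normal tissue, where
reactive effects are attenuated to half on the log2 scale, emulating the
lower scores seen outside tumors.  The gene panel also carries ribosomal,
mitochondrial and CD8A genes so the QC and gating steps are exercisable,
plus a small "checkpoint-like" accessory block (+1 log2FC in reactive
cells) that gives the signature-score and DE modules detectable
structure; the accessory block is a generator device, not a biological
claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import ExpressionBundle, ValidationError, validate_annotations
from .clones import assemble_clones

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: log2 fold-changes of the signature genes in tumor-reactive cells.
DEFAULT_EFFECTS = {"CXCL13": 2.5, "ENTPD1": 1.5, "IL7R": -1.5}

#: baseline negative-binomial means of the named genes (bystander cells).
#: IL7R is abundant in memory-phenotype T cells; CXCL13 and ENTPD1 are
#: expressed at moderate baseline so that the stated log2 effects render
#: the score distributions bimodal, as in the real cohorts.
DEFAULT_BASELINES = {"CXCL13": 3.0, "ENTPD1": 4.0, "IL7R": 15.0, "CD8A": 15.0}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort."""

    n_patients: int = 6
    cells_per_patient: int = 2000
    frac_tumor_reactive: float = 0.05
    frac_bystander: float = 0.10  # ground-truth-labeled virus-specific cells
    n_background_genes: int = 500
    nb_size: float = 2.0  # NB dispersion: var = m + m^2/size
    background_mean_log_mu: float = np.log(1.5)
    background_mean_log_sd: float = 0.8
    effects_log2fc: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    patient_shift_sd: float = 0.3  # natural-log scale
    reactive_clone_mean: float = 8.0
    bystander_clone_mean: float = 1.5
    frac_normal_tissue: float = 0.3
    normal_effect_attenuation: float = 0.5
    n_accessory_genes: int = 10
    accessory_log2fc: float = 1.0
    n_ribo_genes: int = 20
    ribo_mean: float = 10.0
    n_mito_genes: int = 3
    mito_mean: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_tumor_reactive", "frac_bystander", "frac_normal_tissue",
                     "normal_effect_attenuation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} must lie in [0, 1]")
        for name in ("n_patients", "cells_per_patient", "n_background_genes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.nb_size <= 0:
            raise ValidationError("nb_size must be positive")
        for g, m in self.baselines.items():
            if m <= 0:
                raise ValidationError(f"baseline mean for {g} must be > 0")
        if self.reactive_clone_mean < 1 or self.bystander_clone_mean < 1:
            raise ValidationError("clone mean sizes must be >= 1")


def _gene_panel(config: SimulationConfig, rng: np.random.Generator):
    names, means = [], []
    for g in ("CXCL13", "ENTPD1", "IL7R", "CD8A"):
        names.append(g)
        means.append(config.baselines[g])
    for i in range(config.n_accessory_genes):
        names.append(f"CHKP{i + 1:02d}")
        means.append(1.0)
    for i in range(config.n_ribo_genes):
        fam = "RPS" if i % 2 == 0 else "RPL"
        names.append(f"{fam}{i // 2 + 1}")
        means.append(config.ribo_mean)
    for i in range(config.n_mito_genes):
        names.append(f"MT-G{i + 1}")
        means.append(config.mito_mean)
    bg_means = rng.lognormal(
        config.background_mean_log_mu,
        config.background_mean_log_sd,
        config.n_background_genes,
    )
    for i, m in enumerate(bg_means):
        names.append(f"BG{i + 1:04d}")
        means.append(m)
    return np.asarray(names, dtype=object), np.asarray(means, dtype=float)


def _clone_sizes(n_cells: int, mean_size: float, rng: np.random.Generator) -> list[int]:
    """Geometric clone sizes (support >= 1) covering exactly n_cells."""
    p = 1.0 / mean_size
    sizes: list[int] = []
    left = n_cells
    while left > 0:
        s = min(int(rng.geometric(p)), left)
        sizes.append(s)
        left -= s
    return sizes


def _cdr3(rng: np.random.Generator) -> str:
    return "CASS" + "".join(rng.choice(AA, size=8)) + "F"


def simulate_cohort(config: SimulationConfig | None = None):
    """Draw one cohort; returns (bundle, annotations, clones, truth).

    Deterministic given the config (including its seed): the same config
    yields byte-identical matrices and tables.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids, base_means = _gene_panel(config, rng)
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)
    accessory = [g for g in gene_ids if g.startswith("CHKP")]

    barcodes, patients, tissues, classes, clone_ids, cdr3s = [], [], [], [], [], []
    responses = {}
    clone_counter = 0
    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        responses[patient] = "responder" if p % 2 == 0 else "non_responder"
        n_cells = config.cells_per_patient
        n_reactive = int(round(config.frac_tumor_reactive * n_cells))
        n_bystander = int(round(config.frac_bystander * n_cells))
        if n_reactive + n_bystander > n_cells:
            raise ValidationError("frac_tumor_reactive + frac_bystander exceeds 1")
        # 1 = tumor-reactive, 0 = labeled bystander (virus-specific),
        # -1 = unlabeled background TIL (transcriptionally like bystanders)
        labels = np.array(
            [1] * n_reactive + [0] * n_bystander
            + [-1] * (n_cells - n_reactive - n_bystander)
        )
        rng.shuffle(labels)
        # two compartments per patient: a tumor sample and an adjacent
        # normal sample; the clone-size law describes clonal expansion
        # within the tumor, and normal-tissue cells share TCRs with the
        # tumor clones of their class (cross-tissue tracking structure)
        n_normal = int(round(config.frac_normal_tissue * n_cells))
        tissue = np.array(["tumor"] * (n_cells - n_normal) + ["normal"] * n_normal)
        rng.shuffle(tissue)
        cell_clone = np.empty(n_cells, dtype=object)
        cell_cdr3 = np.empty(n_cells, dtype=object)
        for cls, mean_size in ((1, config.reactive_clone_mean),
                               (0, config.bystander_clone_mean),
                               (-1, config.bystander_clone_mean)):
            tumor_rows = np.flatnonzero((labels == cls) & (tissue == "tumor"))
            normal_rows = np.flatnonzero((labels == cls) & (tissue == "normal"))
            clone_of_row: list[str] = []
            sizes = _clone_sizes(len(tumor_rows), mean_size, rng) if len(tumor_rows) else []
            class_clones: list[tuple[str, str, int]] = []  # (id, cdr3, tumor size)
            start = 0
            for size in sizes:
                clone_counter += 1
                cid = f"clone{clone_counter:05d}"
                cdr3 = _cdr3(rng)
                class_clones.append((cid, cdr3, size))
                cell_clone[tumor_rows[start:start + size]] = cid
                cell_cdr3[tumor_rows[start:start + size]] = cdr3
                start += size
            if len(normal_rows):
                if not class_clones:
                    clone_counter += 1
                    class_clones = [(f"clone{clone_counter:05d}", _cdr3(rng), 1)]
                # a normal-tissue cell is drawn from a clone with
                # probability proportional to its tumor expansion
                weights = np.array([s for _, _, s in class_clones], dtype=float)
                weights /= weights.sum()
                picks = rng.choice(len(class_clones), size=len(normal_rows), p=weights)
                for row, k in zip(normal_rows, picks):
                    cell_clone[row] = class_clones[k][0]
                    cell_cdr3[row] = class_clones[k][1]
        for i in range(n_cells):
            barcodes.append(f"{patient}_BC{i + 1:05d}")
        patients.extend([patient] * n_cells)
        tissues.extend(tissue.tolist())
        classes.extend(labels.tolist())
        clone_ids.extend(cell_clone.tolist())
        cdr3s.extend(cell_cdr3.tolist())

    n_total = len(barcodes)
    patients = np.asarray(patients, dtype=object)
    tissues = np.asarray(tissues, dtype=object)
    classes = np.asarray(classes)

    # per-patient multiplicative shifts, shared by all of a patient's cells
    shift = {}
    for p in sorted(set(patients)):
        shift[p] = np.exp(rng.normal(0.0, config.patient_shift_sd, n_genes))

    means = np.empty((n_genes, n_total))
    for j in range(n_total):
        means[:, j] = base_means * shift[patients[j]]
    # reactive effects (attenuated in normal tissue)
    effect = np.zeros(n_genes)
    for g, lfc in config.effects_log2fc.items():
        effect[gene_idx[g]] = lfc
    for g in accessory:
        effect[gene_idx[g]] = config.accessory_log2fc
    reactive = classes == 1
    atten = np.where(tissues == "normal", config.normal_effect_attenuation, 1.0)
    factor = 2.0 ** (np.outer(effect, reactive * atten))
    means *= factor

    size = config.nb_size
    counts = rng.negative_binomial(size, size / (size + means))
    bundle = ExpressionBundle(
        gene_ids=gene_ids,
        cell_barcodes=np.asarray(barcodes, dtype=object),
        layer_raw=sp.csr_matrix(counts),
        provenance={"simulate_cohort": {"seed": config.seed}},
    )

    antigen_label = np.select(
        [classes == 1, classes == 0], ["tumor_reactive", "bystander"], "unknown"
    )
    annotations = validate_annotations(pd.DataFrame(
        {
            "barcode": barcodes,
            "patient_id": patients,
            "sample_id": [f"{p}_{t}" for p, t in zip(patients, tissues)],
            "tissue": tissues,
            "clonotype_id": clone_ids,
            "cdr3_beta": cdr3s,
            "antigen_label": antigen_label,
            "response_label": [responses[p] for p in patients],
        }
    ))
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "patient_id": patients,
            "true_class": np.select(
                [classes == 1, classes == 0],
                ["tumor_reactive", "bystander"], "background",
            ),
            "clone_id": clone_ids,
            "tissue": tissues,
            "attenuated": (reactive & (tissues == "normal")),
        }
    )
    clones = assemble_clones(annotations, key="clonotype_id")
    return bundle, annotations, clones, truth


def simulate_bimodal_scores(
    n: int,
    modes,
    weights,
    sds,
    seed: int = 0,
    lo: float = 0.0,
    hi: float = 1.0,
):
    """Truncated-Gaussian mixture samples on [lo, hi] plus their density.

    Returns ``(values, density)`` where ``density`` is the analytic
    mixture density (vectorized callable) for oracle comparisons.
    """
    modes = np.asarray(modes, dtype=float)
    weights = np.asarray(weights, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (len(modes) == len(weights) == len(sds)):
        raise ValidationError("modes, weights and sds must have equal length")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValidationError("weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(modes), size=n, p=weights)
    values = rng.normal(modes[comp], sds[comp])
    # resample out-of-range draws (proper truncation)
    bad = (values < lo) | (values > hi)
    while bad.any():
        values[bad] = rng.normal(modes[comp[bad]], sds[comp[bad]])
        bad = (values < lo) | (values > hi)

    from scipy.stats import norm as _norm

    z = _norm.cdf((hi - modes) / sds) - _norm.cdf((lo - modes) / sds)

    def density(x):
        x = np.asarray(x, dtype=float)
        parts = [
            w * _norm.pdf(x, m, s) / zk
            for w, m, s, zk in zip(weights, modes, sds, z)
        ]
        out = np.sum(parts, axis=0)
        return np.where((x >= lo) & (x <= hi), out, 0.0)

    return values, density
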