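"""Clone assembly, putative tumor-reactive cell (pTRC) calling, and
cross-tissue TCR tracking.

A clone is the set of cells sharing a TCR (clonotype id, or patient +
CDR3beta).  A clone is pTRC when at least ``min_high`` of its tumor
cells are score-high and the clone is not shared across patients; every
member cell of a pTRC clone — including score-low and normal-tissue
members — is a pTRC cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import CloneRecord, ValidationError, clones_to_frame


def assemble_clones(
    annotations: pd.DataFrame,
    key: str = "clonotype_id",
) -> dict[str, CloneRecord]:
    """Group clonotype-bearing cells into clones within each patient.

    ``key="clonotype_id"`` uses the provided clonotype column;
    ``key="patient_cdr3b"`` keys clones by (patient_id, cdr3_beta).
    Clones whose CDR3beta (or clonotype id) occurs in more than one
    patient are flagged cross-patient.  Cells without clonotype
    information belong to no clone.
    """
    if key not in ("clonotype_id", "patient_cdr3b"):
        raise ValidationError(f"unknown clone key {key!r}")
    df = annotations.copy()
    has_cdr3 = "cdr3_beta" in df.columns
    if key == "patient_cdr3b" and not has_cdr3:
        raise ValidationError("cdr3_beta column required for patient_cdr3b keying")
    ident = df["clonotype_id"] if key == "clonotype_id" else df["cdr3_beta"]
    df["_ident"] = ident
    df = df[df["_ident"].notna()]
    if df.empty:
        raise ValidationError("no clonotype information present")

    # cross-patient sharing is judged on the TCR sequence identity when
    # available, otherwise on the clonotype id itself
    share_key = df["cdr3_beta"] if has_cdr3 else df["_ident"]
    share = pd.DataFrame({"k": share_key, "patient_id": df["patient_id"]})
    shared = (
        share.dropna(subset=["k"])
        .groupby("k")["patient_id"].nunique()
    )
    cross = set(shared[shared > 1].index)

    clones: dict[str, CloneRecord] = {}
    for (patient, ident_val), grp in df.groupby(["patient_id", "_ident"], sort=True):
        clone_id = (
            str(ident_val) if key == "clonotype_id" else f"{patient}:{ident_val}"
        )
        if key == "clonotype_id" and clone_id in clones:
            clone_id = f"{patient}:{ident_val}"
        cdr3 = ""
        if has_cdr3:
            vals = grp["cdr3_beta"].dropna().unique()
            cdr3 = str(vals[0]) if len(vals) else ""
        is_cross = (cdr3 in cross) if has_cdr3 else (ident_val in cross)
        clones[clone_id] = CloneRecord(
            clone_id=clone_id,
            patient_id=str(patient),
            cdr3_beta=cdr3,
            member_barcodes=grp["barcode"].tolist(),
            size=len(grp),
            is_cross_patient=bool(is_cross),
        )
    return clones


def call_ptrc(
    clones: dict[str, CloneRecord],
    score_table: pd.DataFrame,
    annotations: pd.DataFrame,
    min_high: int = 5,
    min_high_frac: float | None = None,
    count_tissue: str = "tumor",
) -> tuple[dict[str, CloneRecord], pd.DataFrame]:
    """Flag pTRC clones and propagate pTRC status to member cells.

    ``n_high`` counts score-high member cells in ``count_tissue`` (tumor
    by default; normal-tissue members inherit status but do not count).
    With ``min_high_frac`` set, the threshold becomes
    ``max(min_high, ceil(frac * clone size))`` — a sequencing-depth-robust
    alternative.  Cross-patient clones are never pTRC.
    """
    high = score_table.set_index("barcode")["high_flag"]
    tissue = annotations.set_index("barcode")["tissue"]
    cell_flags = pd.Series(False, index=score_table["barcode"], name="is_ptrc")
    for clone in clones.values():
        members = clone.member_barcodes
        n_high = 0
        for bc in members:
            if tissue.get(bc) != count_tissue:
                continue
            flag = high.get(bc)
            if flag is not pd.NA and flag is not None and bool(flag) is True:
                n_high += 1
        clone.n_high = n_high
        threshold = min_high
        if min_high_frac is not None:
            threshold = max(min_high, int(np.ceil(min_high_frac * clone.size)))
        clone.is_ptrc = (n_high >= threshold) and not clone.is_cross_patient
        if clone.is_ptrc:
            present = [bc for bc in members if bc in cell_flags.index]
            cell_flags.loc[present] = True
    table = score_table.copy()
    table["is_ptrc"] = cell_flags.to_numpy()
    return clones, table


def clonal_sizes(
    annotations: pd.DataFrame,
    clones: dict[str, CloneRecord],
    display_cap: int | None = None,
) -> pd.Series:
    """Per-cell clone size; cells without a clonotype count as singletons.

    ``display_cap`` (e.g. 1000) applies only when exporting for
    visualization; the returned sizes are capped when it is given.
    """
    size_of = {}
    for clone in clones.values():
        for bc in clone.member_barcodes:
            size_of[bc] = clone.size
    sizes = annotations["barcode"].map(lambda b: size_of.get(b, 1)).astype(int)
    if display_cap is not None:
        sizes = sizes.clip(upper=display_cap)
    sizes.index = annotations["barcode"]
    return sizes


def track_clones(
    annotations: pd.DataFrame,
    clones: dict[str, CloneRecord],
    tissue_a: str = "tumor",
    tissue_b: str = "normal",
) -> pd.DataFrame:
    """Cross-tissue clone frequencies and tumor:normal ratios per patient.

    A clone's frequency in a tissue is its cell count there divided by
    the total clonotype-bearing cells of that patient+tissue.  Ratios are
    reported only for clones present in both tissues.
    """
    tissue = annotations.set_index("barcode")["tissue"]
    patient = annotations.set_index("barcode")["patient_id"]
    bearing = annotations[annotations["clonotype_id"].notna()] if "clonotype_id" in annotations else annotations
    denom = bearing.groupby(["patient_id", "tissue"]).size()

    rows = []
    for clone in clones.values():
        counts = {tissue_a: 0, tissue_b: 0}
        for bc in clone.member_barcodes:
            t = tissue.get(bc)
            if t in counts:
                counts[t] += 1
        freqs = {}
        skip_reason = None
        for t, c in counts.items():
            total = denom.get((clone.patient_id, t), 0)
            if total == 0:
                skip_reason = f"no clonotype-bearing cells in {t}"
                freqs[t] = np.nan
            else:
                freqs[t] = c / total
        shared = counts[tissue_a] > 0 and counts[tissue_b] > 0
        ratio = (
            freqs[tissue_a] / freqs[tissue_b]
            if shared and not skip_reason and freqs[tissue_b] > 0
            else np.nan
        )
        rows.append(
            {
                "clone_id": clone.clone_id,
                "patient_id": clone.patient_id,
                f"n_{tissue_a}": counts[tissue_a],
                f"n_{tissue_b}": counts[tissue_b],
                f"freq_{tissue_a}": freqs[tissue_a],
                f"freq_{tissue_b}": freqs[tissue_b],
                "shared": shared,
                "ratio": ratio,
                "skip_reason": skip_reason,
                "is_ptrc": clone.is_ptrc,
            }
        )
    return pd.DataFrame(rows)


def clone_table(clones: dict[str, CloneRecord]) -> pd.DataFrame:
    """TSV-ready clone summary table."""
    return clones_to_frame(clones)
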