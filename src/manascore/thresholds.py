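"""Patient-specific score-high calling via the last-trough rule.

Each patient's tumor-cell score distributions (imputed and non-imputed)
are kernel-density estimated; the cutoff is the last (highest-location)
interior trough of each density.  A cell is score-high only when it
exceeds BOTH cutoffs.  Patients with unimodal score distributions fall
back to an upper-quantile cutoff, flagged in provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import density_troughs


@dataclass
class PatientCutoffs:
    """Per-patient cutoffs on score_i and score_ni plus provenance."""

    patient_id: str
    cutoff_i: float | None
    cutoff_ni: float | None
    provenance: dict = field(default_factory=dict)


def last_trough_cutoff(
    scores,
    bandwidth: str | float = "silverman",
    grid_size: int = 512,
    min_scores: int = 50,
) -> float | None:
    """Largest-location density trough of a score distribution, or None."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < min_scores:
        return None
    if np.ptp(scores) == 0:
        return None
    troughs = density_troughs(scores, bandwidth=bandwidth, grid_size=grid_size)
    return troughs[-1] if troughs else None


def per_patient_cutoffs(
    score_table: pd.DataFrame,
    annotations: pd.DataFrame,
    bandwidth: str | float = "silverman",
    grid_size: int = 512,
    min_cells: int = 50,
    fallback_quantile: float = 0.90,
    tissue: str = "tumor",
) -> dict[str, PatientCutoffs]:
    """Estimate last-trough cutoffs per patient on tumor-tissue cells.

    When a score distribution shows no trough, the cutoff falls back to
    the ``fallback_quantile`` of that patient's scores (flagged).  A
    patient with fewer than ``min_cells`` tumor cells gets null cutoffs.
    """
    merged = score_table.merge(
        annotations[["barcode", "tissue"]], on="barcode", how="left", validate="1:1"
    )
    in_tissue = merged["tissue"] == tissue
    out: dict[str, PatientCutoffs] = {}
    for patient, grp in merged[in_tissue].groupby("patient_id", sort=True):
        prov: dict = {"bandwidth": bandwidth, "grid_size": grid_size,
                      "n_cells": len(grp), "fallback": {}}
        if len(grp) < min_cells:
            out[patient] = PatientCutoffs(patient, None, None,
                                          {**prov, "too_few_cells": True})
            continue
        cuts = {}
        for col in ("score_i", "score_ni"):
            vals = grp[col].to_numpy()
            cut = last_trough_cutoff(vals, bandwidth, grid_size, min_scores=min_cells)
            if cut is None:
                cut = float(np.quantile(vals, fallback_quantile))
                prov["fallback"][col] = fallback_quantile
            cuts[col] = float(np.clip(cut, vals.min(), vals.max()))
        out[patient] = PatientCutoffs(patient, cuts["score_i"], cuts["score_ni"], prov)
    return out


def call_high(
    score_table: pd.DataFrame, cutoffs: dict[str, PatientCutoffs]
) -> pd.DataFrame:
    """Fill ``high_flag``: strictly above BOTH patient cutoffs.

    Cells of patients without cutoffs stay undetermined (NA).
    """
    out = score_table.copy()
    flags = pd.array([pd.NA] * len(out), dtype="boolean")
    for i, (patient, si, sni) in enumerate(
        zip(out["patient_id"], out["score_i"], out["score_ni"])
    ):
        co = cutoffs.get(patient)
        if co is None or co.cutoff_i is None or co.cutoff_ni is None:
            continue
        flags[i] = bool(si > co.cutoff_i and sni > co.cutoff_ni)
    out["high_flag"] = flags
    return out


def cutoffs_to_frame(cutoffs: dict[str, PatientCutoffs]) -> pd.DataFrame:
    rows = []
    for p, c in sorted(cutoffs.items()):
        rows.append(
            {
                "patient_id": p,
                "cutoff_i": c.cutoff_i,
                "cutoff_ni": c.cutoff_ni,
                "fallback_i": "score_i" in c.provenance.get("fallback", {}),
                "fallback_ni": "score_ni" in c.provenance.get("fallback", {}),
            }
        )
    return pd.DataFrame(rows)
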