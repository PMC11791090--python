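import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from manascore.datamodel import ExpressionBundle
from manascore.pipeline import (
    evaluate_heldout,
    run_scoring_pipeline,
)
from manascore.simulate import SimulationConfig, simulate_cohort

STUDY_SEED = 0


def make_bundle(counts, genes=None, barcodes=None, sparse=False):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"BC{j}" for j in range(n_cells)]
    raw = sp.csr_matrix(counts) if sparse else counts
    return ExpressionBundle(
        gene_ids=np.asarray(genes, dtype=object),
        cell_barcodes=np.asarray(barcodes, dtype=object),
        layer_raw=raw,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap 3-patient cohort for unit tests."""
    config = SimulationConfig(n_patients=3, cells_per_patient=400, seed=7)
    bundle, annotations, clones, truth = simulate_cohort(config)
    return {
        "config": config,
        "bundle": bundle,
        "annotations": annotations,
        "clones": clones,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_study():
    """The default study conditions, run once per session.

    6 patients x 2000 cells, 5% tumor-reactive with +2.5/+1.5/-1.5 log2
    effects on CXCL13/ENTPD1/IL7R; trained on the first 4 patients and
    scored on the 2 held-out ones.
    """
    config = SimulationConfig(seed=STUDY_SEED)
    bundle, annotations, clones, truth = simulate_cohort(config)
    patients = sorted(annotations["patient_id"].unique())
    result = run_scoring_pipeline(
        bundle, annotations, clones, patients[:4], seed=STUDY_SEED
    )
    result.truth = truth
    metrics = evaluate_heldout(result, truth, patients[4:])
    return {
        "config": config,
        "bundle": bundle,
        "annotations": annotations,
        "clones": result.clones,
        "truth": truth,
        "result": result,
        "metrics": metrics,
        "train_patients": patients[:4],
        "heldout_patients": patients[4:],
    }
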