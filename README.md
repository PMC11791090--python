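# manascore

Identifying which CD8+ tumor-infiltrating lymphocytes (TIL) actually
recognize tumor antigens is a central problem in cancer immunology:
functional validation (tetramer staining, TCR transfer) is slow and
expensive, and most intratumoral T cells are bystanders specific for
viral antigens such as influenza or EBV. `manascore` implements a
three-gene scoring system for coupled scRNA-seq/scTCR-seq data that
calls putative tumor-reactive cells from expression of just **CXCL13**
(up in tumor-reactive TIL), **ENTPD1** (CD39, exhaustion-associated, up)
and **IL7R** (memory-maintenance receptor, down), together with the full
pipeline around it: quality control, CD8 gating, normalization and
imputation layers, patient-specific thresholding, clone-level calling,
and downstream clone statistics.

## The score

For each cell two soft-voting ensemble probabilities are computed over
the three signature genes:

- **score_i** — from the quantile-normalized imputed expression layer,
- **score_ni** — from the log-normalized layer without imputation.

Each ensemble averages the class-1 probabilities of one random-forest
(100 trees, all 3 features per split) and one logistic model per
training patient, fitted on that patient's validated tumor-reactive
(class 1) versus virus-specific bystander (class 0) cells, with an
80/20 stratified train/test split. The two scores combine into an
overall score √(score_i² + score_ni²).

Calling proceeds in two patient-aware steps:

1. **Score-high cells.** Within each patient's tumor cells, a Gaussian
   kernel density is fitted to each score distribution and the cutoff is
   placed at the *last trough* (the interior density minimum before the
   high mode). A cell is score-high only if it exceeds **both** cutoffs.
2. **pTRC clones.** Cells sharing a TCR always share antigen
   specificity, so calling is lifted to clonotypes: a clone is a
   *putative tumor-reactive clone* (pTRC) when at least 5 of its tumor
   cells are score-high and the clone is not shared across patients.
   Every member cell of a pTRC clone — including score-low cells and
   cells tracked into adjacent normal tissue — is a pTRC cell.

Real cohorts of this kind are controlled-access, so the package ships a
first-class synthetic-cohort generator (negative-binomial counts,
patient-level shifts, expanded reactive clones, tumor/normal
compartments with TCR sharing) that makes every stage testable without
any download.

## Worked example

```python
from manascore.simulate import SimulationConfig, simulate_cohort
from manascore.pipeline import run_scoring_pipeline, evaluate_heldout

config = SimulationConfig(seed=1)          # 6 patients x 2000 CD8+ cells
bundle, annotations, clones, truth = simulate_cohort(config)
patients = sorted(annotations["patient_id"].unique())

# train on 4 patients' ground truth, score everyone, threshold, call pTRC
result = run_scoring_pipeline(bundle, annotations, clones,
                              train_patients=patients[:4], seed=1)
metrics = evaluate_heldout(result, truth, patients[4:])
print(f"held-out AUC (imputed):     {metrics['auc_i']:.3f}")
print(f"held-out AUC (non-imputed): {metrics['auc_ni']:.3f}")
print(f"pTRC sensitivity:           {metrics['ptrc_sensitivity']:.3f}")
print(f"pTRC rate in bystanders:    {metrics['ptrc_bystander_rate']:.3f}")
```

prints

```
held-out AUC (imputed):     0.968
held-out AUC (non-imputed): 0.962
pTRC sensitivity:           0.795
pTRC rate in bystanders:    0.000
```

i.e. on two patients whose labels were never seen during training, the
3-gene score separates validated tumor-reactive from bystander cells
with AUC ≈ 0.97, and the clone-level pTRC rule recovers ~80% of
ground-truth reactive cells while flagging no bystanders.

The same workflow is available from the shell:

```bash
manascore simulate --seed 1 --out data
manascore normalize --data data
manascore impute    --data data --seed 1
manascore train     --data data --meta data/metadata.tsv \
                    --train-patients P01,P02,P03,P04 --seed 1 --out model.pkl
manascore score     --data data --meta data/metadata.tsv \
                    --model model.pkl --out scores.tsv
manascore threshold --scores scores.tsv --meta data/metadata.tsv --out run
manascore ptrc      --scores run_scored.tsv --meta data/metadata.tsv --out run
manascore report    --dir . --out report.md
```

Further subcommands cover QC (`qc`), clone-pseudobulk differential
expression (`de`) and the pseudobulk PCA + canonical-correlation
permutation test (`cca`).

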