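# Methods

This note documents the models and numerical procedures implemented in
`manascore`, the parameters that matter, the design choices made where
the design was genuinely open, and the limits of what the synthetic
cohorts can show.

## Scoring model

The scorer is a pair of soft-voting ensembles over three signature
genes (CXCL13, ENTPD1, IL7R). For each training patient with ground
truth (validated tumor-reactive cells labeled 1, validated
virus-specific bystanders labeled 0), two members are fitted on that
patient's labeled tumor cells:

- a random forest with `n_estimators=100` and `max_features=3` (all
  features considered at every split). These are the selected values of
  a grid over trees ∈ {100, 500, 1000, 2000, 2500} × features ∈
  {1, 2, 3}; the grid remains available (`RF_SEARCH_GRID`) but is not
  re-run by default;
- a logistic regression fitted by unpenalized maximum likelihood. A
  linear model is combined by *soft* voting, which requires probability
  outputs; the logistic link is the probabilistic reading of a linear
  member. A literal least-squares variant with predictions clipped to
  [0, 1] is available as `algorithm="linear_clipped"` for sensitivity
  analysis.

The ensemble class-1 probability is the unweighted arithmetic mean of
its members' probabilities (no weights are justified by anything in the
design). The canonical composition is 3 patients × 2 algorithms = 6
members per layer; the implementation accepts any k ≥ 2 distinct
patients with the same algorithm pair per patient (2k members), which
the validation enforces. One ensemble is fitted per input layer:
`score_i` on the quantile-normalized imputed layer and `score_ni` on
the log-normalized layer; the overall score is √(score_i² + score_ni²).

Ground-truth cells are split 80/20, stratified by (patient, class),
before member fitting; members are fitted once on the 80% portion.
Strata with fewer than two cells go wholly to training (warned).

## Layers

- **Log-normalization**: per cell, value = ln(1 + count/total × 10 000).
  Natural log, +1 pseudocount, scale 10 000 — the single-cell ecosystem
  convention; all three are parameters.
- **Imputation** is a pluggable contract, not an algorithm: `identity`
  de-logs the normalized layer; `knn_smooth` replaces each cell by the
  uniform mean of its k = 15 nearest neighbors (self included,
  Euclidean distance in the top 20 PCs of the normalized layer).
  Published imputation methods are deliberately out of scope.
- **Quantile normalization** across cells: within each cell values are
  replaced by the mean across cells of the order statistics at the same
  rank; tied values receive the average of the reference values their
  ranks span. It is computed over whatever cell population is passed —
  cohort-wide by default — and the scope is recorded in provenance.

The default pipeline uses the `identity` imputer. This is a deliberate
choice for the synthetic setting: the generator draws genes
independently given the cell's class and patient (transcriptome-wide
co-expression is a non-goal), so a neighbor-based smoother has no
structure to borrow from — the class signal occupies a low-variance
direction that pooled PCA cannot isolate at a 5% positive fraction, and
smoothing across mixed-class neighbors measurably blurs the three
markers. On real data, where cell states span hundreds of co-regulated
genes, a model-based imputer is expected to sharpen the imputed score
instead; `knn_smooth` is tested on fixtures with explicit cluster
structure, where it provably reduces within-cluster marker variance.

## Quality control and gating

Cell filters (joint, single pass): detected genes < 250; detected genes
more than 3 SD above the median (raw SD of the detected-gene counts,
computed once on the input population); mitochondrial count fraction
(`MT-` prefix) > 10%; ribosomal fraction (`RPS`/`RPL` prefixes) < 10%.
Gene filters: user-supplied dissociation/stress list, `MT-` genes,
ribosomal-protein genes, TCR V/D/J/C genes (`TRA/TRB/TRD/TRG` segment
prefixes — removed to avoid clonotype bias), and genes detected in
fewer than 5 cells (a gene in exactly 5 cells is kept). Every removed
cell or gene carries machine-readable reasons.

The ribosomal family is recognized by the conventional `RPS`/`RPL`
symbol prefixes; a literal `RP-` prefix matches almost no human
symbols.

**CD8 gate.** A Gaussian KDE is fitted to log2(imputed CD8A + 1) and
the threshold is the *first* density trough; cells strictly above it
are CD8+. The +1 pseudocount is needed because imputed values can fall
below 1; it is configurable.

## Density troughs and patient-specific cutoffs

`density_troughs` fits a Gaussian KDE (Silverman bandwidth by default;
the bandwidth is exposed because trough locations depend on it) on a
512-point grid spanning the data range. Raw "every strict local
minimum" detection is fragile: in sparse valleys the kernel estimate
wiggles and produces spurious shallow minima, and a "last trough" rule
then lands on the shoulder of the high mode rather than in the valley.
The implementation therefore requires modes to have prominence of at
least 5% of the density maximum and returns, for each pair of adjacent
accepted modes, the grid point of minimum density strictly between
them. A dominant boundary mode (common when most scores pile up near
0) counts as a mode. Unimodal densities yield no troughs; callers
decide the fallback.

Per patient, cutoffs are estimated independently on the tumor-tissue
score_i and score_ni distributions; the cutoff is the last (largest
location) trough. A patient with no trough falls back to the 0.90
quantile of their scores, flagged in provenance; patients with fewer
than 50 tumor cells get null cutoffs. A cell is score-high iff it is
strictly above **both** of its patient's cutoffs (the conjunction is
the point: two independent layers must agree).

## Clones and pTRC

Clones are keyed by the supplied clonotype id, or by (patient, CDR3β)
when ids are absent — both keys are supported because chain-level
identity is what cross-tissue tracking uses. A clone found in more
than one patient (by CDR3β identity) is cross-patient and never pTRC:
public TCRs are overwhelmingly viral-specific.

A clone is pTRC when ≥ `min_high` (default 5) of its **tumor** cells
are score-high. Normal-tissue members inherit pTRC status through TCR
tracking but do not count toward the threshold — scores in adjacent
normal tissue are systematically lower, and counting them would make
the rule depend on how much normal tissue was sampled. The absolute
count is sequencing-depth dependent, so a fraction-of-clone alternative
(`min_high_frac`) is provided. Cross-tissue tracking reports, for each
clone present in both tissues, frequency per tissue (clone cells over
clonotype-bearing cells of that patient+tissue) and the tumor:normal
ratio.

## Downstream statistics

- **Clone pseudobulk**: raw counts summed within clone, then
  log-normalized treating clones as cells. Total counts are conserved.
- **Differential expression**: two-sided Wilcoxon rank-sum on
  pseudobulk values per gene. The null is enumerated exactly (all
  C(n+m, n) assignments, tie-aware, two-sided via |W − μ|) when both
  groups have ≤ 10 clones, and approximated by the tie-corrected normal
  with continuity correction otherwise. Genes are pre-filtered to those
  detected in ≥ 10% of either group with |log2FC| ≥ 0.25 (both filters
  disengageable); log2FC = log2((mean expm1 A + 1)/(mean expm1 B + 1))
  with the +1 pseudocount making the ratio well-defined at zero.
  BH adjustment runs over tested genes.
- **HVG selection**: LOESS of per-gene SD on per-gene mean (span 0.75);
  HVGs are genes with positive residuals.
- **Batch adjustment** is a contract with `none` and `center_scale`
  (standardize within batch, restore pooled moments); empirical-Bayes
  batch correction is out of scope, and a plug-in point is left for it.
- **Canonical correlation**: features standardized to zero mean/unit
  variance, samples embedded by PCA of concatenated per-cluster HVG
  vectors; the canonical correlation of (PC1, PC2) with a covariate is
  the multiple correlation √R² of the covariate regressed on the two
  PCs. Significance is a one-sided (large r) permutation test of the
  sample labels with the add-one estimator p = (1 + #{r* ≥ r})/(1 + B),
  which cannot return zero; B = 10 000 by default.
- **Signature scores**: binned-control module scores — genes are split
  into 24 equal-size bins by mean expression; each set gene draws 100
  controls from its bin (with replacement when the bin is small,
  seeded); score = mean(set) − mean(pooled controls) per cell. An
  ssGSEA-style rank-weighted running-sum score (weight rank^0.25,
  normalized by the score range across cells) is included purely as a
  comparison baseline; signature gene lists must be supplied by the
  user for real analyses.

## Synthetic cohorts

The generator emulates the statistical structure the scorer assumes,
with defaults defining the study conditions: 6 patients × 2000 CD8+
cells; 5% tumor-reactive cells; 10% labeled virus-specific bystanders
(transcriptionally identical to the unlabeled background — bystander
status is an antigen label, not an expression phenotype); 500
background genes with log-normal baseline means; negative-binomial
counts with size 2 (var = m + m²/2); patient-level multiplicative
shifts exp(N(0, 0.3)) per gene; reactive effects +2.5 (CXCL13), +1.5
(ENTPD1), −1.5 (IL7R) log2-fold; a 10-gene accessory "checkpoint-like"
block at +1 log2FC so signature-score and DE modules have detectable
structure (a generator device, not a biological claim).

Signature baselines default to CXCL13 = 3, ENTPD1 = 4, IL7R = 15,
CD8A = 15 mean counts: IL7R is abundant in memory-phenotype T cells,
and the markers must be quantifiable at typical T-cell library depth
(~1300 UMIs here) for the stated fold-changes to produce the bimodal
score distributions on which trough thresholding operates — the regime
the method is designed for.

Each patient has a tumor and an adjacent-normal compartment (30% of
cells normal). The clone-size law describes clonal expansion within the
tumor sample: geometric sizes with mean 8 for reactive clones and 1.5
for bystander/background clones. Normal-tissue cells join an existing
tumor clone of their class with probability proportional to its tumor
expansion, giving every clone a tumor anchor — the cross-tissue
tracking structure. Reactive cells in normal tissue receive effects
attenuated to 50% on the log2 scale, emulating the lower scores
observed outside tumors. The panel includes ribosomal (`RPS*/RPL*`,
high mean) and mitochondrial (`MT-*`, low mean) genes so the QC
fractions are meaningful, and CD8A so the gate is exercisable.

What the generator does **not** emulate: transcriptome-wide
co-expression and cell-state manifolds (hence the identity imputer
default, above), UMI saturation, doublets, ambient RNA, and any real
relationship between response labels and expression. Passing tests on
these cohorts demonstrate that the pipeline's logic and statistics are
correct under the stated generative model — not that the three genes
suffice on any particular real dataset.

## Problem sizes and numerical choices

The default study (simulate, two layers, 8 + 8 ensemble members, 12 000
cells scored, cutoffs, pTRC) runs in well under a minute on one core;
the null-behavior analysis uses 20 replicate cohorts of 3 patients ×
400 cells, and calibration studies use 500 null genes (8 vs 8 exact
Wilcoxon) and 200 replicates × 500 permutations (canonical
correlation). Determinism: every stochastic step takes a seed, and a
config plus seed reproduces byte-identical cohorts; random-forest
members are seeded so refits reproduce identical predictions.

Tie-breaking and degenerate inputs: rank ties are averaged everywhere
(AUC, rank-sum, quantile normalization); cells exactly at a cutoff are
not high (strict inequality); a gene detected in exactly the minimum
number of cells is kept; a single-cell quantile normalization is the
identity (warned); zero-total cells are a hard error naming the
barcode; constant score distributions yield no trough and fall back.

## Known limitations

- The `min_high = 5` pTRC rule is an absolute count and therefore
  depends on sequencing depth; the fractional alternative is provided
  but not the default.
- The last-trough cutoff assumes a (near-)bimodal score distribution.
  Patients with weak separation silently fall back to a quantile
  cutoff; the fallback is flagged, and downstream users should consider
  excluding such patients.
- Model serialization uses pickle; files are only loadable with a
  compatible scikit-learn version.
- The ssGSEA-style baseline follows the usual running-sum convention
  but is a documented stand-in; it is used only as a comparison axis,
  never in pTRC calling.
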