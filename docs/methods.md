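# Methods

`evsig` re-implements, as a tested library, a biomarker-discovery analysis
for plasma extracellular-vesicle (EV) cargo: label-free-quantified (LFQ)
proteins and a targeted metabolite panel measured in technical duplicate on
a three-group cohort (primary melanoma, metastatic melanoma, healthy
control). The pipeline runs preprocessing → differential abundance →
triple-algorithm feature selection with consensus → grid-searched signature
evaluation by clustering-as-classifier against an exact binomial null →
multi-omic integration. Because no raw data from the original cohort are
public, the package ships a synthetic-cohort generator with known ground
truth; every statistical claim the test suite makes is computed on those
synthetic cohorts or on printed summary inputs.

## Preprocessing

Fixed stage order, each stage logging feature counts:

1. **Identification filtering** (at read time): MaxQuant protein groups
   flagged `Reverse`, `Potential contaminant` or `Only identified by site`
   are dropped; LFQ intensities of 0 are re-coded missing, per that
   format's convention.
2. **Missingness filter**: features missing in strictly more than 40% of
   observations are removed. The boundary (exactly 40%) is retained — the
   rule is a strict inequality.
3. **Immunoglobulin removal** (proteins only): gene symbols starting with
   `IGH`, `IGK`, `IGL`, `IGJ` or `JCHAIN` (case-insensitive) are removed.
   These abundant plasma proteins mask low-abundance EV cargo. No
   canonical list exists; the prefix set is configurable.
4. **Imputation**: iterative random-forest (missForest-style). Missing
   entries start at feature means; features are revisited in order of
   increasing missingness, each regressed on all others and re-predicted;
   the loop stops when the sum of squared changes of imputed values
   increases (the diverging sweep is reverted) or after `max_iter = 10`
   sweeps. Defaults: 100 trees, mean initialisation. Forest predictions
   are averages of observed targets, so imputed values always lie inside
   the feature's observed range.
5. **Normalisation**: log2 transform, then per-observation median
   centring. A uniform scaling of one sample becomes an additive log
   shift, which the median removes. Only "normalised and log-transformed"
   is externally specified; median centring is this package's explicit
   choice and is recorded in every run report.
6. **Replicate averaging** (where an analysis runs at subject level):
   arithmetic per-feature mean of a subject's technical replicates.

Proteins and metabolites are preprocessed separately; imputation never
mixes the two blocks.

## Differential abundance

The moderated two-sample t-test shrinks each feature's pooled variance
s²_g (d_g residual df) toward a prior estimated from all features by
moment matching on e_g = log s²_g − ψ(d_g/2) + log(d_g/2):

- prior df d₀ solves ψ′(d₀/2) = mean[(e_g − ē)²·G/(G−1) − ψ′(d_g/2)],
  found by Newton iteration on the trigamma inverse (≤ 50 iterations,
  tolerance 1e-8) and clamped to ∞ when the right-hand side is ≤ 0;
- prior variance from log s₀² = ē + ψ(d₀/2) − log(d₀/2);
- posterior s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g);
- t = Δmean / (s̃_g·√(1/n₁ + 1/n₂)) on d₀ + d_g df.

Setting the prior df to 0 recovers the ordinary pooled t exactly; to ∞,
a common variance for all features. The test suite cross-checks the
statistics against the limma reference implementation. Significance is the
unadjusted p < 0.05 convention of the source analysis; a
Benjamini–Hochberg option exists but is off by default.

**Evaluation level.** Technical replicates of one subject are correlated,
so differential testing always runs at subject level (replicates averaged
first); a replicate-level t-test would be anticonservative. The
replicate-as-independent convention survives only where the original
analysis used it: classification evaluation of proteomic signatures
(n = 94 predictions rather than 47). Both levels are always recorded.

Classical tests (Mann–Whitney U with the exact two-sided p for n₁·n₂ ≤ 400
without ties, Spearman, rank-based ROC-AUC, Pearson χ² without continuity
correction, one-way ANOVA recomputed from group sizes/means/SDs) audit
cohort demographics and marker-level comparisons.

## Feature selection and consensus

Three selectors produce candidate sets:

- **Serial kNN**: features ranked by moderated-t p-value; for each grid
  point (k odd, N) a k-nearest-neighbour classifier on the top-N features
  (Euclidean distance) is cross-validated. Default
  leave-one-subject-out, so replicates never straddle train/test; a
  leave-one-observation-out mode reproduces the replicate-as-independent
  convention. Distance ties break toward the lowest observation index;
  grid ties toward smaller N, then smaller k.
- **L1-penalised logistic regression**: internally standardised features,
  a 30-point geometric lambda path from the analytic full-shrinkage point,
  lambda chosen by 5-fold cross-validated binomial deviance (`min` rule by
  default; `1se` available). Non-zero coefficients form the signature.
- **Random-forest importance**: 500 trees; the top ⌈0.10·G⌉ features by
  mean impurity decrease.

The **consensus** is the three-way intersection ordered by mean rank; when
empty, a **lenient** set (union of pairwise intersections — features any
two selectors agree on) is the fallback. The grid-search candidate pool is
capped at 6 features, the largest grid the source analysis ever ran; for
the combined search, half the slots go to each omic.

## Signature evaluation

A candidate subset is evaluated by agglomerative clustering (Euclidean
distance, complete linkage by default) of the feature-restricted matrix,
cut at two clusters; the cluster→label assignment maximising accuracy is
taken (the assignment rule is not externally specified). Reported per
signature: confusion counts, accuracy with exact 95% Clopper–Pearson
interval, the No-Information Rate (majority-class proportion), the
one-sided exact binomial P(X ≥ correct), X ~ Bin(n, NIR), sensitivity
(positive = disease class), specificity, and the evaluation level. The
grid search enumerates every non-empty subset of ≤ 12 candidates with ties
broken toward smaller subsets then lexicographic order, making the winner
invariant to candidate input order.

**Caveat.** The binomial p-value is computed for the grid winner on the
same data that chose it, exactly as in the source analysis; it is a
descriptive index, not a valid selection-adjusted test. The null
calibration below measures how anticonservative it is in practice: at
subject level with ≤ 6 candidates, the winner's p exceeds 0.05 in ≈ 90%
of zero-effect cohorts, but at replicate level (pseudo-replicated n) or
with larger candidate pools it degrades sharply. This is a property of
the clustering-as-classifier + grid-search method itself.

## Multi-omic integration

Concatenation only: protein replicates are averaged to subject level and
joined feature-wise with the metabolite table. Cross-omic structure is
summarised by hierarchical clustering of features on distance 1 − ρ
(Spearman), cut into k partitions (default 6). Anticorrelated features
are far apart by design (1 − ρ, not 1 − |ρ|); a constant feature gets
ρ = 0 with a warning. Being rank-based, the partition is invariant to
strictly monotone transforms of any feature.

## Synthetic cohorts

The generator emulates the study design: 24/12/13 subjects in technical
duplicate; 257 proteins; 88 metabolites labelled 72 glycerophospholipids,
14 sphingolipids, one biogenic amine, one amino acid. Nothing about the
real data's distribution is public, so all distributional choices are
stand-ins chosen once:

- **Baselines** log-normal (the LFQ/concentration convention): per-feature
  log2 means Normal(25, 2) for proteins (LFQ scale) and Normal(0, 1.5)
  for metabolites (µM scale); per-feature log2 SDs Gamma(2, 0.25),
  floored at 0.05.
- **Group effects** multiplicative on designated markers
  (2^log2FC in the contrast's positive group). Defaults spike PRG4,
  APOC4 (log2FC 1.5) and HPR (1.0) plus two metabolites for melanoma vs
  control, and VWF, SERPIND1 plus two metabolites for metastatic vs
  primary.
- **Ages** Normal per group with the cohort's printed means/SDs (both
  melanoma groups ≈ 62 y, controls ≈ 35 y), clipped to [18, 95].
- **Age coupling**: one marker (PRG4) is re-ordered within study groups
  along a latent blend w·z(age) + √(1−w²)·noise, w found by bisection so
  the realised Spearman ρ approximates the 0.34 target (±0.05 tolerance;
  within-group re-ordering leaves group means, hence spiked effects,
  exactly intact).
- **Replicates**: multiplicative log-normal jitter, CV 0.15.
- **Missingness**: each entry masked with probability mcar_rate plus, for
  slope > 0, (1 − mcar)·expit(−slope·(z − c)) where z is the entry's
  standardised global log2 intensity and c = −0.5 SD — low-abundance
  dropout. Defaults mcar 0.02, slope 3. Spiked markers are protected from
  masking so the missingness filter cannot silently delete the ground
  truth.
- **Immunoglobulin decoys**: 15 features named IGHG1-style so the removal
  filter is testable by name.

What passing tests on these cohorts do *not* show: robustness to
non-log-normal intensity distributions, batch effects, correlated feature
blocks beyond the spiked markers, peptide-level artefacts, or assay
limits of quantification — none of which the generator models.

## Calibration and recovery benchmarks (problem sizes used)

- **Type-I error**: zero-effect study-shaped cohorts, 20 seeds; the
  subject-level moderated-t p < 0.05 rate pooled over both omics
  (≈ 6,600 null features) sits within 0.05 ± 0.01.
- **Endpoint null**: on the same 20 cohorts, the combined subject-level
  grid winner has Acc>NIR p > 0.05 in ≥ 90% of seeds (18/20 at the fixed
  seed base — this bound is marginal; see the caveat above).
- **Recovery**: two markers spiked at log2FC 1.5, 50 seeds; both
  significant and selected by ≥ 2 of 3 algorithms in 50/50 seeds; the
  spiked effect falls inside the moderated 95% CI in ≥ 90% of seeds.

These benchmarks generate cohorts without missingness: the properties
under test concern the t-statistic and the selectors, and the imputation
path is exercised separately (unit tests and the end-to-end run, both of
which include intensity-dependent dropout).

## Numerical notes

- Trigamma inverse: Newton with limma-style initialisation; asymptotic
  branches for arguments above 1e7 or below 1e-6.
- Zero-variance features are excluded from prior estimation; their
  posterior variance is the shrunken prior alone, and a zero mean
  difference yields t = 0, p = 1.
- The LASSO path uses liblinear with intercept_scaling = 1000 so the
  (nominally penalised) intercept is effectively free, keeping the
  analytic full-shrinkage lambda exact; the solver seed is derived from
  the run seed — results are bit-reproducible across processes.
- PCA scores fix signs by making each loading's largest-magnitude entry
  positive.
- One integer seed per run feeds every stochastic stage (generator,
  imputation forests, LASSO fold shuffling and solver, selection
  forests); reports are byte-identical across repeated runs.
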