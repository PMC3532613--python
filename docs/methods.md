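# Methods

This note documents the models, conventions and numerical choices
behind `oncorule`, in the order data flows through the pipeline.

## Ct screening and normalization

A sample's raw data are duplicate Ct values per gene plus RNA metadata
(concentration, 260/280 ratio). Five acceptance criteria are applied,
all inclusive at the boundary: RNA concentration ≥ 10 ng/µL, 260/280 ≥
1.8, mean housekeeping (HK) Ct ≤ 32.0, every individual Ct ≤ 35, and
per-sample replicate concordance r² ≥ 0.90. Failure reasons are
reported in a fixed order (`LOW_RNA_CONC`, `LOW_PURITY_RATIO`,
`HK_MEAN_EXCEEDED`, `CT_EXCEEDED`, `LOW_REPLICATE_R2`,
`NO_AMPLIFICATION`); a sample passes iff it violates none.

Conventions chosen where practice varies:

- **Replicate r² is computed per sample across genes** (rep-1 Ct vector
  vs rep-2 Ct vector), matching per-assay-card inspection; it is
  undefined (and fails QC) with fewer than three complete pairs.
- **No amplification is a missing Ct**, never a sentinel cycle number
  such as 40; `NO_AMPLIFICATION` fires when a *requisite* gene has both
  replicates missing.
- **Replicates are averaged on the Ct (log₂) scale** before
  normalization; with one replicate missing the other is used alone.
- The HK mean uses all five HK genes with no outlier trimming; a sample
  whose HK gene is entirely missing cannot be normalized and is an
  error rather than a silent drop.

Normalized expression is `100 · 2^(Ave5HK_Ct − Ct)`: dimensionless,
strictly positive, doubling per cycle saved. The factor 100 puts a gene
expressed at the HK level at exactly 100.

## Rule model

A rule is an expression tree over gene terminals and numeric constants
with operator set `add, sub, mul, div (protected), min, max, neg, iflt
(4-ary comparison), and, or, not`. Conventions:

- **Protected division** returns 1.0 on a zero denominator (standard
  genetic-programming practice), keeping evaluation total and scores
  finite on all positive inputs.
- **Booleans are numeric**: true = 1.0, false = 0.0, and any value > 0
  is truthy on coercion, so every tree yields a real score comparable
  to the slice point.
- **The slice point boundary is inclusive above**: scores < slice point
  form the `below` group; scores ≥ it the `at_or_above` group. Which
  group is *high risk* is data, not convention — it is fixed during
  finalization as the side with the higher observed recurrence
  proportion, and no gradation within a group is exposed.
- Gene-count (default ≤ 7 distinct genes) and depth caps are enforced
  at construction and at parse time. Rules serialize to a
  schema-versioned JSON document.

The published 5-gene signature's constants (gene set {BMI1, ETV6,
H3F3B, RPS10, VEGFA}, slice point −4.4777, observed score range
[−92.8245, 69.7508]) are shipped as data for reference; its algebraic
form was never released and is not reconstructed.

## Evolutionary search

The original signature was produced with a proprietary evolutionary
engine whose hyperparameters are unpublished, so this engine uses
standard tree-GP machinery, all exposed in `EvolutionConfig`: ramped half-and-half initialization, tournament
selection (size 3), subtree crossover (p = 0.8), subtree/constant
mutation (p = 0.15, constants drawn uniformly from [−10, 10] with
Gaussian point-mutation of sd 10% of the range), one elite per
generation. Offspring violating the gene-count or depth cap are retried
up to ten times, then replaced by a copy of a parent, so the caps are
hard invariants of every generation.

**Fitness** is the mean AUC over the held-out folds of a stratified
k-fold partition (default k = 4): a rule's scores are computed once and
the AUC is evaluated within each fold separately, never pooled, so
fitness is an average of independent held-out estimates. AUC is the
rank-based (Mann–Whitney) statistic with ties counted one half; the
slice point plays no role during evolution. A fold containing a single
class is skipped; if all folds are degenerate the fitness is 0.5.

The boolean operators, though in the grammar, are excluded from the
default *search* operator set: expression values are strictly positive,
making every subexpression truthy and the trio degenerate as search
material. They remain available via configuration.

**Campaign structure.** A campaign is `len(sets)` sets of
`n_runs_per_set` independent runs, each set capping the number of
distinct genes (default caps 4, 5, 6, 7; defaults of 300 runs per set
give 1,200 best-of-run rules from 4 folds × 300 runs × 4 sets
fold-level evaluations). The alternative reading — folds as additional
independent runs — is selectable with `folds_as_runs`. Per-run seeds
are spawned from the campaign seed, so results are reproducible and
independent of execution order.

## Selection and finalization

Gene-use frequency counts distinct presence per rule (a gene used twice
in one rule counts once) as a percent of all candidate rules; key genes
are taken by rank with ties at the cutoff broken alphabetically and
reported. The best rule is the candidate with maximal AUC on the
reserved test set, ties broken by fewer genes, then shallower tree,
then earliest (set, run).

Slice-point refinement freezes the winning structure and chooses the
threshold maximizing **Youden's J** over all midpoints between adjacent
distinct scores on the combined training + test samples, considering
both orientations; J-ties go to the cut nearest the score median. The
refinement objective is a deliberate design choice (no canonical
objective exists for this step); J is the standard dichotomization
criterion, and the high-risk side is fixed simultaneously
as the orientation that maximizes J (equivalently, the side with the
higher recurrence rate at the chosen cut).

## Validation statistics

- Sensitivity/specificity/PPV/NPV carry exact **Clopper–Pearson**
  intervals from beta quantiles (lower bound exactly 0 at k = 0, upper
  exactly 1 at k = n); PPV/NPV with empty denominators are reported as
  undefined without failing the rest.
- The **exact McNemar** test doubles the smaller binomial(b + c, ½)
  tail, capped at 1; mid-p and continuity-corrected variants are out of
  scope. Paired classifiers are compared among recurrent patients
  (proportions called high risk) and nonrecurrent patients (proportions
  called low risk) separately.
- The **two-proportion sample size** uses the unpooled normal
  approximation `n = ⌈(z₁₋α/2 + z_power)² (p₁q₁ + p₂q₂) / (p₁ − p₂)²⌉.`
  Power-analysis packages differ in pooling and continuity conventions;
  this form is stated explicitly and oracle-checked rather than claimed
  identical to any of them.
- Survival analysis is backed by lifelines: product-limit curves,
  the two-group log-rank test, and Cox proportional-hazards fits with
  **Efron tie handling** (monthly times make ties common; lifelines
  does not offer Breslow, so no Breslow flag is exposed). Missing
  covariates are handled complete-case per model with the n used and
  excluded reported, mirroring per-variable patient counts in published
  regression tables. The univariate screen fits one two-covariate model
  per baseline variable (variable + rule call); backward elimination
  repeatedly drops the highest-p non-forced variable until all
  remaining are below α, never dropping the forced rule call; two
  classifiers are compared by a Wald test on the difference of their
  coefficients in a joint model, using the joint covariance.
- Recurrence-free-survival convention: recurrent patients contribute
  time to first recurrence as an event; nonrecurrent patients are
  censored at the 36-month horizon. Continuous covariates (T class,
  grade, node count, age) enter uncategorized.

## Guideline baseline

Stage I → low risk (surveillance). Stage II → high if any high-risk
factor is confirmed present (T4, grade 3–4, LVI, PNI, obstruction or
perforation, < 12 nodes examined, compromised margins), low if all are
confirmed absent, and not evaluable if none is present but any is
unknown — a present factor wins over missing ones, which keeps the
classifier monotone in the factors. Close, indeterminate and positive
margins collapse to one `margins_compromised` boolean (eligible cohorts
have clear margins, but the factor is retained for generality).
Not-evaluable patients are excluded from comparisons.

## Synthetic cohorts

The generator emulates the data layout and statistical structure the
pipeline assumes; defaults are the study conditions.

- **Assay panel.** Per-gene baseline Cts are derived deterministically
  from the gene name plus an `assay_seed` (target genes N(27, 1.5²),
  HK genes N(26, 0.5²)), so every cohort generated against the same
  panel shares gene baselines and rules transfer across cohorts, as for
  a real fixed assay. Per-sample biological variation is N(0, 1.25²)
  per target gene (N(0, 0.2²) for HK genes); true Cts are truncated to
  [15, 34] — the panel's genes were preselected to amplify reliably, so
  a clean cohort passes all QC criteria. Measured duplicates add
  independent N(0, 0.15²) technical noise per replicate.
- **Planted rule and outcome links.** With a planted rule, each
  patient's score is the rule evaluated on noiseless expression. Three
  links map scores to outcomes. *Logistic* (default): recurrence
  probability is logistic in the rank-based normal scores of the
  planted score (Blom transform) with slope 5 — raw rule scores on the
  log-normal expression scale are heavily skewed, and normal scores
  give the slope a distribution-free meaning; the intercept is solved
  so the cohort hits the target prevalence (default 0.35, as in a
  ~92/264 validation cohort), and slope 5 puts the planted signal's
  intrinsic discrimination near 0.96 AUC. *Threshold*: labels are the
  rule's own high/low calls (slice point realized at the prevalence
  quantile if unset) — with zero technical noise the downstream
  pipeline reproduces the labels exactly. *Hazard*: outcomes are driven
  purely by a group-wise exponential survival model — the rule's
  high/low groups (median-score slice if unset) get hazards in the
  configured ratio (default 1.8), the baseline hazard is solved so the
  overall 36-month event probability equals the prevalence, and a
  patient recurs iff the event precedes the horizon. The hazard link is
  the one for hazard-ratio recovery and null-calibration experiments;
  under the logistic and threshold links, recurrent patients' event
  times are truncated-exponential on (0, 36] with base rate 1/18 per
  month scaled by the hazard ratio in the high-score group. The true
  group assignment is recorded as `planted_high`.
- **Covariates** follow marginals typical of a node-negative external
  validation cohort (site 52/43/5% right colon/left colon/rectum; T1–T4
  3/14/55/28% for colon, rectal cases stage I; grade 16/71/12/1%;
  median 9 nodes; LVI 31%, PNI 17%, obstruction/perforation 6%; age
  N(65, 13) clipped to 22–90; 56% women; 86% Caucasian) and are
  independent of outcome by default; PNI is missing in 53% of patients
  (LVI 4%, obstruction 12%) to exercise complete-case handling, and an
  optional odds-ratio hook links LVI to recurrence for confounding
  experiments.
- **QC injection** corrupts a requested fraction of samples, each with
  exactly one named failure (HK mean pushed above 32, one target gene's
  replicates removed, or RNA concentration dropped below 10), recorded
  in the metadata.
- **Stratified splitting** partitions ids within strata (any column
  set; a helper bins recurrence times at a configurable width, since
  the original binning is unstated), assigning `round(ratio·n)` per
  stratum to the first side, so a half split differs by at most one per
  stratum.

What the generator does *not* emulate: FFPE degradation chemistry,
plate geometry, amplification-curve shapes, covariate–covariate
correlation structure, and any real biological co-expression between
panel genes (target genes are independent given the planted rule).
Passing tests therefore demonstrate correctness of the computational
pipeline under the assumed generative model, not clinical performance
on real cohorts.

## Reference experiments and problem sizes

The experiment drivers (`oncorule.experiments`) run at sizes chosen so
the whole battery completes in minutes on one CPU: planted-rule
recovery uses 300-patient cohorts over a 20-gene panel with a
scaled-down campaign (sets capped at 2 and 3 genes, 6 runs each,
population 120, 20 generations, 4 folds) repeated over 10 seeds;
hazard-ratio recovery uses n = 2,000; log-rank calibration uses 500
null replicates of n = 1,000. Recovery is declared when the finalized
rule keeps ≥ 0.9 AUC on a fresh cohort and contains both planted genes.

## Known limitations

- Quantities that require the original patient-level cohorts (the
  reported hazard ratios 1.80/1.63/1.76, log-rank p values, regression
  tables, gene-use frequencies, and the −4.4777 slice point) cannot be
  reproduced; the package instead verifies the machinery by parameter
  recovery on synthetic cohorts and reproduces exactly the arithmetic
  derivable from printed counts.
- The GP engine is a faithful standard implementation of this kind of
  search, not a reconstruction of the proprietary engine's internals;
  gene-use frequency influences selection only post hoc (the original
  engine reportedly also weighed it in fitness; the mechanism is
  unpublished).
- Cox fits offer Efron tie handling only.
- The guideline baseline encodes the printed factor list for one
  guideline edition; rectal-specific adjuvant rules beyond it are out
  of scope.
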