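# Methods

## Model

`pathoforest` classifies single amino acid substitutions into pathogenic,
neutral or unknown. The underlying classifier is an ensemble of random
forests: each of `n_bootstrap` members is trained on a stratified
bootstrap resample of the training variants — sampling with replacement
*within* each class so every resample reproduces the original class
counts exactly — and predicts a pathogenicity probability for a query as
the fraction of its trees voting pathogenic. The spread of the member
probabilities measures how stable the prediction is under resampling of
the training data.

The reject option is distribution-free. Writing μ and σ for the mean and
sample standard deviation (n−1 denominator) of the member probabilities,
Chebyshev's inequality guarantees that at least 1 − 1/k² of the
probability mass lies in μ ± kσ for any distribution. At confidence c we
set k = 1/√(1−c) (c = 0.95 ⇒ k = √20 ≈ 4.4721) and classify only when the
interval excludes 0.5 — strictly: an endpoint exactly at 0.5 rejects.
Because Chebyshev is conservative for any real distribution, the gate
errs toward rejecting, which is the safe direction for this application.
When the reject option is disabled the binary fallback thresholds μ at
0.5; an exact tie is called neutral to keep false positives low.

### Assumptions

* Training labels are a two-class gold standard; the model is calibrated
  for roughly balanced classes (imbalanced data changes the meaning of
  the 0.5 threshold).
* Member probabilities are exchangeable draws from "the classifier's"
  probability for the variant; the Chebyshev interval quantifies
  resampling instability, not biological uncertainty.
* Features are informative marginally or jointly; trees handle monotone
  transformations, so feature scaling (including the logarithm base of
  the GO feature) is immaterial.

## Features

**GO log-ratio.** Each protein's GO terms are expanded to their
ancestors (following both `is_a` and `part_of` edges by default;
`is_a`-only is available) and deduplicated so each protein carries each
term at most once. Class-wise term frequencies f(P), f(N) are counted
over *training variants*: each variant contributes its protein's term set
to its class, so the context reflects the class composition of the
variant data (per-protein counting is available via `counting="protein"`;
the choice matters only when variant counts per protein are very
skewed). The feature is LR = Σ log[(f(Pᵢ)+1)/(f(Nᵢ)+1)] with natural
logarithm; the +1 smoothing keeps every ratio finite. A protein with no
GO annotation yields a missing value, never zero.

**Selective pressure ω.** Model-based codon-level Ka/Ks values are taken
as an input column — they come from a selection-analysis tool run on a
codon alignment, which this package deliberately does not re-implement.
The built-in `surrogate_omega` is a pathway-averaged counting estimate
(per-codon synonymous/non-synonymous difference counts against the
reference, each normalised by the codon's expected site counts). It is
default-off, returns missing when the synonymous rate is zero, and is
logged as non-equivalent to model-based estimates; use it only to run the
pipeline end to end without external tools.

**Sequence profile.** f_ref and f_var are the proportions of the
reference and variant residues in the variant's alignment column; n_seq
is the alignment depth. The denominator counts all rows including gapped
ones (configurable), and the human reference row is included in both the
counts and n_seq.

**Amino acid properties.** AAindex1 entries give index(ref)−index(var)
(any consistent direction is equivalent for tree learners); AAindex2/3
matrices are looked up directly with row = reference, column = variant,
symmetrizing lower-triangular storage on load. Entries containing any NA
are dropped by `filter_complete_indices` before use.

## Functional-site priors

Annotation types whose overlapping training variants are more than 85 %
one class are retained, storing the pathogenic proportion Pₐ. At
prediction time a variant inside a retained site combines Pₐ with each
member's probability by noisy-OR, P꜀ = Pₐ + P_rf − Pₐ·P_rf, *before* μ
and σ are computed. Applying the combination per member (rather than to
the mean only) shrinks σ and therefore reduces rejections for annotated
variants, which is the observed purpose of the priors; mean-only
combination is available. The noisy-OR form can only raise the
pathogenicity probability; it is applied as stated even for
neutral-biased types (Pₐ < 0.5), with a mirrored variant available via
`combine_probability(..., mode="symmetric")` (and the matching
`combine_mode` argument of `predict`) for users who want neutral-biased
priors to push downward. When several retained types overlap a position,
the type with Pₐ farthest from 0.5 wins (first-match available).

## Feature selection

Step one: for each of 10 family-aware CV folds, backward elimination
starts from all candidates, repeatedly retrains a forest, records
held-out accuracy, ranks features by mean decrease in gini index
(retraining at every iteration), and drops the lowest-ranked until one
feature remains; the subset with the highest held-out accuracy wins,
ties favouring the smaller set. Step two: the union of the 10 subsets is
the non-redundant set; forward selection seeds with its top gini-ranked
feature and accepts, per round, the addition with the largest *relative*
accuracy gain under 10-fold family-aware CV, requiring strict
improvement (absolute-gain mode gives the same argmax when baselines are
equal). Selection accuracy is measured over all predictions with the
binary 0.5 cutoff — the reject gate sits downstream of selection. Gini
ties break by feature name; every fold split keeps whole protein
families together, and leakage is asserted, not assumed.

Selection forests default to 100 trees (the final model always uses the
full ensemble settings); the recovery experiments in the test suite use
25-tree forests on ~240-variant benchmarks, which this package treats as
its standard desk-scale configuration.

## Evaluation

The six measures follow their standard contingency definitions;
nMCC = (1+MCC)/2 rescales MCC to [0,1] and
OPM = (PPV+NPV)(Sens+Spec)(Acc+nMCC)/8 is the normalised volume of the
performance cuboid with face distances +x PPV, −x NPV, +y sensitivity,
−y specificity, +z accuracy, −z nMCC. The geometric volume is re-derived
from the cuboid and asserted to equal the analytic OPM to 1e-12. For
reject-option output, unknowns are excluded from the confusion table but
stay in coverage's denominator (coverage = classified / submitted); the
all-variant binary-fallback table is reported alongside. A measure with
a zero denominator is an explicit `None`, and OPM is undefined whenever
any constituent is; printed-table comparisons use round-half-even at two
decimals.

## Synthetic benchmark

The generator emulates the structure the method assumes, not any real
dataset's marginals:

* proteins grouped into families with heavy-tailed sizes (stresses the
  family-aware splitter); each protein has a class propensity and its
  variants follow it with probability 0.9, mimicking disease genes vs.
  frequently-polymorphic genes;
* roughly balanced classes (default 0.5), matching the balanced-training
  design the classifier expects;
* informative features uniform on unit intervals whose supports overlap
  by a single `overlap` dial (0 = disjoint, 1 = identical) — bounded
  supports make the overlap interpretation exact, so `overlap=0` implies
  perfectly separable classes and `overlap=1` an exact null;
* ω exponential with pathogenic scale 0.12 against neutral 0.8 at full
  signal (pathogenic variants sit at conserved sites), interpolating to
  the neutral scale as overlap → 1;
* independent standard-normal noise features;
* annotation sites placed as single-residue intervals over sampled
  variants so each type's realised pathogenic proportion matches its
  configured Pₐ (infeasible requests raise);
* GO annotations drawn from a toy tree ontology with class-skewed leaf
  pools.

What passing tests on this generator show: the pipeline's mechanics —
stratification, gating, selection, scoring — behave as specified under
known signal. What they do not show: performance on real variant data,
whose features are correlated, non-uniform, incompletely annotated and
label-noisy.

## Numerical and design choices

* Per-member determinism: member m draws its bootstrap and forest seeds
  from `SeedSequence(master, (m, stream))`, so results are independent of
  scheduling and bit-identical across reruns.
* Forests use `mtry` features per split and fully grown trees
  (scikit-learn defaults otherwise); the outer bootstrap replaces the
  forests' internal bagging (`bootstrap=False`) so the resampling the
  reliability interval measures happens in exactly one place.
* Missing values are median-imputed with training medians, except a
  missing GO feature routes the variant to a parallel fallback ensemble
  trained without the GO column — a protein with no GO annotation is a
  qualitatively different situation than a sporadically missing numeric
  value, and imputing the median LR would inject a fake class signal.
  Imputation-only mode exists.
* σ uses the sample (n−1) standard deviation over members.
* Desk-scale problem sizes in the test suite (tens of bootstrap members,
  tens of trees, hundreds of variants) are the package's chosen defaults
  for simulation-backed checks; the production defaults (200 × 300,
  mtry 2, confidence 0.95) are unchanged and used unless overridden.

## Known limitations

* The ω surrogate is a counting estimate and not comparable in scale to
  maximum-likelihood codon-model values; treat it as qualitative.
* Chebyshev gating is conservative; coverage at a given confidence is
  lower than a parametric interval would give.
* The GO feature is protein-level: it cannot separate pathogenic from
  neutral variants within one protein and relies on the other features
  for that distinction.
* Family-aware folds balance sizes greedily; with very skewed family
  multisets fold sizes can differ substantially (that is inherent to the
  constraint, not a bug).
* No genomic-coordinate or VCF ingestion: input is protein-space
  substitutions only, and ortholog retrieval/alignment happens upstream.
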