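# Methods

This note records the statistical and numerical conventions used by
`sapor`, so results are reproducible from the definitions alone.

## Curation

SMILES are standardized with RDKit's `rdMolStandardize`: `Cleanup`
followed by `ChargeParent` (largest organic fragment, neutralized), then
canonical SMILES output. Unparseable or non-standardizable inputs are
*rejections*, recorded with their row identifiers, never exceptions.
After standardization, compounds with identical canonical SMILES are
grouped: groups with a single label keep the first occurrence; groups
with conflicting labels are removed entirely. All counts appear in the
curation report.

## Descriptors

Two 2D descriptor backends: RDKit (`Descriptors.CalcMolDescriptors`,
≈ 210 descriptors) and Open Babel (`pybel.calcdesc`, the 25 numeric
descriptors; string-valued entries such as `cansmi`, `formula`, `InChI`
are excluded). Column names carry a backend prefix (`rdkit.`, `obabel.`).
Non-finite values and backend failures become missing values (NaN), never
zeros: a descriptor that cannot be computed (e.g. partial charges for
selenium compounds) is information-bearing missingness, not a zero.

## Cleaning

Order of operations: (1) duplicate rows (byte-identical feature vectors,
NaN matching NaN) are collapsed when labels agree and removed when they
conflict; (2) columns with ≥ 95 % missing values are dropped (inclusive
threshold); (3) columns whose modal value covers ≥ 99 % of the
*non-missing* entries are dropped (constant and all-missing columns are
special cases); (4) byte-identical duplicate columns are collapsed,
keeping the lexicographically first name. The `CleaningReport` records
every removed identifier and validates its own arithmetic
(`n_cols_in − dropped − collapsed = n_cols_out`, and likewise for rows).

## Preprocessing policies

Per model family (fit on training folds only, applied to held-out folds):

| family              | winsorize | scaling | imputation |
|---------------------|-----------|---------|------------|
| logistic regression | 5–95 %    | min–max | constant 1 |
| k-NN                | 5–95 %    | min–max | constant 1 |
| MLP                 | 5–95 %    | min–max | constant 1 |
| random forest       | 5–95 %    | none    | constant −99999 |
| gradient boosting   | 5–95 %    | none    | native missing handling |

Winsorization bounds use the linear-interpolation percentile convention
(`numpy.nanpercentile`, default `linear` method) computed on non-missing
training values; missing values pass through untouched. A training
column that is entirely missing raises. The standalone `minmax_scale`
operation errors on zero range per its contract; inside CV pipelines the
scaler is sklearn's `MinMaxScaler`, which maps a fold-constant column to
0 instead of aborting the fold. The imputation constants deliberately
sit outside (1, for min–max-scaled inputs) or far outside (−99999) the
data range so that MNAR missingness remains a learnable signal.

## Cross-validation and metrics

Stratified k-fold with shuffling; repeat r of an R-repeat run uses seed
`base_seed + r`. Metrics per fold: AUROC, AUPRC, and F1/precision/recall
at the 0.5 probability threshold (precision is defined as 0, with a
warning, when no positives are predicted). Summaries report the mean
with a normal-approximation 95 % confidence interval over folds.

## Corrected resampled t-test

For paired per-fold score differences `d` of length n from k-fold CV
(possibly repeated),

    t = mean(d) / sqrt( (1/n + tf/(1 − tf)) · var(d, ddof=1) ),  df = n − 1

with `tf` the test fraction, defaulting to `1/k`. For 10-fold CV,
`tf = 0.1` gives the variance-ratio term `1/9`; the worked example
(mean 0.01, sd 0.02, n = 100) yields t ≈ 1.4367. Degenerate cases:
zero variance with zero mean gives (0, 1); zero variance with non-zero
mean gives (±inf, 0). Pairwise model comparisons require identical fold
structure and apply Bonferroni correction over the number of pairs.

## Feature selection

1. Each feature is scored with the two-sample KS statistic between the
   class-0 and class-1 value distributions (`scipy.stats.ks_2samp`,
   asymptotic p-values; missing values dropped per feature). A feature
   with no observed values in one class scores D = 0 with a warning.
2. Spearman correlations are pairwise-complete with average-rank ties
   (pandas); undefined pairs are set to 0 with a warning.
3. Distance `1 − |ρ|` (option: signed `1 − ρ`), Ward linkage computed
   once and cut with `fcluster(..., criterion="maxclust")` at each k, so
   cuts are nested and the sweep costs one clustering plus one CV run
   per k.
4. Cluster representative = member with the largest KS statistic, ties
   broken lexicographically. Reported diagnostic: mean |ρ| over all
   within-cluster pairs (0 when all clusters are singletons).
5. `choose_k`: `fixed_k` (default 29) or `knee` = the smallest k whose
   CV AUROC is within a tolerance (default 0.01) of the largest-k entry
   in the trace.

The default sweep ranks and clusters on the full table (matching the
source procedure); a leakage-safe variant embeds `KSClusterSelector` as
a transformer inside the CV pipeline.

## Shapley explanations

Feature attributions are interventional Shapley values: the coalition
value `f_x(S)` is the mean model output with features in S fixed at the
explained row and the rest drawn from a background sample (≤ 256 rows,
fixed-seed subsample). Two independent implementations:

* `exact_shapley`: direct enumeration of all 2^M coalitions (M ≤ 20),
  the reference oracle;
* `TreeExplainer`: a per-leaf closed form for tree ensembles. For one
  background row, a leaf is reachable under coalition S iff the path
  features where the explained row takes the leaf's branch but the
  background row does not are all *in* S, and those where only the
  background row takes the branch are all *out*; the remaining features
  are irrelevant and contribute a binomial sum over Shapley weights.
  Supported models: LightGBM boosters, sklearn decision trees, random
  forests and gradient-boosted regressors (with init offset and learning
  rate folded in). NaN values follow each tree's default branch.

Attributions are computed on the ensemble's native additive scale (raw
margin for boosted classifiers). With `output="probability"` the
margin-scale φ of a binary classifier is rescaled proportionally by
`(p(x) − p_base) / (raw(x) − raw_base)` so the additive identity holds on
the probability scale; since the sigmoid is nonlinear, this is a linear
apportionment of the margin attribution, not an independent Shapley
computation. The identity `base + Σ φ = prediction` is asserted (1e−6)
on every explained row by construction of the containers.

Derived artifacts: global importance = mean |φ| per feature (descending,
name tie-break); beeswarm summary data with per-feature value
percentiles over non-missing entries (missing rows flagged); dependence
data with an optional decision cutoff — the zero crossing (midpoint
convention) of an isotonic fit of φ against the feature value, reported
only when the fitted curve changes sign; local profiles listing the
top-|φ| contributions plus an `other` remainder whose cumulative sum
reproduces `prediction − base` exactly.

## Applicability domain

Morgan fingerprints, 1024 bits, radius 2. Domain score = mean Tanimoto
similarity to the 5 most similar training fingerprints. Calibration:
90:10 train/validation split (seeded); training members score with
self-exclusion; threshold = 5th percentile of the validation scores.
Boundary convention: score equal to the threshold is inside. An empty
query fingerprint is outside by definition (with a warning).

## Synthetic ground truth

Correlated feature blocks use a one-factor model per block: feature j of
block b is `sqrt(w)·g_b + sqrt(1−w)·ε`, with block factors sharing a
global factor to set the between-block correlation. For bivariate
Gaussians the population Spearman correlation is `(6/π)·asin(ρ_Pearson/2)`
(0.8915 for ρ = 0.9); ground truth reports both. In informative blocks,
member 0 receives the full class shift and other members an attenuated
shift, making the within-block KS-argmax known by construction. MNAR
injection blanks values above the per-column `(1 − fraction)` quantile,
so missingness is value-dependent and deterministic.

Study conditions used in the verification suite: block recovery uses the
default spec (20 blocks × 8 features, within-ρ 0.9, between 0.05,
5 informative blocks, shift 1.0 attenuated ×0.5, n = 600); permutation
sanity uses n = 600 rows × 12 features with 5-fold × 4-repeat CV, sized
so the Monte-Carlo spread of the mean permuted AUROC stays within
± 0.05 of 0.5.

## Limitations

* The probability-scale attribution is a proportional rescaling (see
  above), not an exact Shapley value of the probability function.
* The default selection sweep computes rankings and clusters on the full
  table before CV, as in the source procedure; use the transformer
  variant when leakage-safe estimates are required.
* The applicability domain is purely structural (fingerprint
  similarity); it does not detect descriptor-space extrapolation.
* Only 2D descriptors are computed; tautomer enumeration and 3D
  conformer-dependent descriptors are out of scope.
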