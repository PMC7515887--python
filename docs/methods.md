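# Methods

## Scope and data model

The package analyses two data arms that meet in a biomarker short-list:
per-sample direct-infusion mass-spectral peak lists from two resistance
groups of grapevine genotypes, and a genes × samples qPCR Cq table for
reference-gene establishment and candidate-gene testing. All inputs and
outputs are plain TSV/JSON; in memory the central objects are a
`FeatureMatrix` (features × samples with an explicit preprocessing stage
tag) and pandas frames for Cq tables and reports.

## Peak alignment and preprocessing

Alignment pools all peaks, sorts by m/z and cuts the sorted sequence
wherever the gap between consecutive peaks exceeds the tolerance
(default 1 ppm, referenced to the smaller mass). These maximal runs are
the features; the representative m/z is the intensity-weighted mean of
the members. This single-linkage gap rule is deterministic and invariant
to the order of input samples; when one sample contributes two peaks to
a feature the more intense one wins and the collision is logged. Because
cluster gaps exceed the tolerance, consecutive representative m/z values
always differ by more than the tolerance.

The preprocessing chain is stage-locked (aligned → filtered → imputed →
normalized → glog → pareto); running a step out of order raises an error
rather than silently proceeding. Choices within the chain:

* **Occurrence filter.** A feature is kept when at least one genotype
  observes it in ≥ ⌈f·n⌉ of its n replicates (f = 2/3, so 2 of 3). A
  `strict` switch implements the literal strictly-greater reading
  (3 of 3). The any-genotype scope is deliberate: a compound present in
  only one genotype can still discriminate groups.
* **Imputation.** Missing cells become half the global minimum observed
  intensity — a detection-limit surrogate, appropriate when missingness
  is censoring at low intensity.
* **Internal-standard normalization.** Each sample column is divided by
  its standard-feature intensity (located within 1 ppm of the standard's
  theoretical m/z; absence and ambiguity are distinct errors), after
  which the standard row is removed.
* **glog.** x ↦ log2((x + √(x² + λ²))/2) with λ defaulting to half the
  smallest positive normalized intensity; λ = 0 reduces to log2. The
  transform stabilizes multiplicative variance while staying linear near
  zero.
* **Pareto scaling.** Per feature, center and divide by the square root
  of the sample SD (n − 1 denominator everywhere in the package).
  Zero-variance rows are zeroed and reported rather than producing NaN.

## PCA, clustering, OPLS-DA

PCA is an exact SVD of the centered sample × feature matrix; the retained
component count is the smallest k whose cumulative explained-variance
fraction reaches the threshold (default 0.95). Clustering is
agglomerative Ward linkage on Euclidean sample distances, exported as
Newick with height-difference branch lengths.

The classifier is a two-class OPLS-DA: with class labels encoded +1/−1
and X centered, the predictive weight vector is w ∝ Xᵀy. Each orthogonal
component removes the largest y-orthogonal variation (Trygg–Wold
iteration: loading p of the current predictive scores, orthogonalized
against w, then deflation of X). With zero orthogonal components the
model is exactly a one-component PLS regression — verified in the tests
against scikit-learn. Prediction is by the sign of ŷ; exact zeros go to
the +1 class and are logged. Default one orthogonal component; a sweep
helper reports metrics for 0–5.

Cross-validation is stratified k-fold (default k = 7, reduced with a
warning when the smaller class is smaller than k). Fold assignment
depends only on (seed, labels). Centering and Pareto statistics are
recomputed inside each training fold to avoid leakage; a `scale="none"`
mode reproduces whole-matrix preprocessing for pre-scaled input.
Accuracy is pooled over held-out folds, R²Y comes from the full-data
fit, and Q²Y = 1 − PRESS/SS_tot from pooled held-out predictions. The
permutation test shuffles labels, reruns the whole CV per permutation
and reports p = (1 + #{permuted ≥ observed})/(1 + N): never zero, and
ties count against significance. The class imbalance (21 vs 12) is
handled by stratification only; no reweighting.

## Univariate selection

Welch t-tests (a pooled-variance flag exists) on the glog-stage values;
the t statistic is invariant to the subsequent per-feature affine Pareto
step, so testing at either stage is equivalent. Fold change is the ratio
of group means on the normalized (pre-glog) intensity scale, oriented
resistant/susceptible: positive log2 FC means more abundant in the
resistant group. BH adjustment is applied over features with defined
p-values; degenerate features (zero variance in both groups at n = 2)
are reported missing and excluded from the family. A feature is
discriminatory when adjusted p < 0.01 and |log2 FC| ≥ 1.

## Annotation

Neutral monoisotopic masses come from an internal IUPAC isotope table
(cross-checked against pyteomics in the tests). Adduct m/z uses
full-precision electron-corrected ion constants — the proton as
1.00727646 Da, [M+Na]⁺/[M+K]⁺ as the element mass minus the electron,
[M+Cl]⁻ plus one electron. This explicit electron accounting reproduces
the leucine enkephalin calibrant pair 556.276575/554.262022 exactly at
six decimals, which folded rounded constants cannot do. Matching accepts
|ppm error| ≤ 2 against the theoretical adduct m/z; annotation is
putative (one query may hit several compound/adduct pairs) and results
are sorted by |ppm error| then compound id, independent of table order.
The remote annotation service and database ontologies are out of scope;
a local TSV compound table (id, name, formula, ;-separated pathway ids)
stands in, and pathway mapping is tabular: per pathway, annotated member
compounds with log2 FC clipped to ±5 and a direction label; empty
pathways appear with count 0.

## qPCR stability and candidate genes

Quantities are Q = E^(minCq − Cq) with per-gene efficiency E (default
2.0, measured values accepted; valid range (1, 2.2]).

* **geNorm.** M_j = mean over partners k of SD(log2 Q_j − log2 Q_k); the
  ranking iteratively excludes the highest-M gene (M recomputed each
  round) until the final unresolvable pair, which shares rank 1.
  V(n/n+1) is the SD of log2(NF_n/NF_{n+1}) with NF_n the per-sample
  geometric mean of the best n genes; the conventional 0.15 cut-off
  flags the optimal gene count.
* **NormFinder-style.** On log2 quantities centered per sample (removing
  the common template-amount effect): per gene and group, the intragroup
  variance v and the intergroup deviation d of the group means;
  SV = mean_g |d| + mean_g √(v/n_g). Groups of one sample are excluded
  with a warning; with fewer than two usable groups SV degrades to the
  SD of the centered values. This is an operationalization in the spirit
  of the published variance-decomposition method, not a line-by-line
  port; a strict estimator could be substituted behind the same
  interface.
* **BestKeeper.** Raw-Cq sample SD per gene, the per-sample geometric
  mean of Cq as the index, and Pearson r (with p) of each gene against
  it; SD > 1 cycle is flagged unstable. Documented as the one method
  that is *not* invariant to per-sample cycle shifts.
* **ΔCt.** Mean over partners of SD of pairwise Cq differences.

The composite ranking is the arithmetic mean of the geNorm, NormFinder
and BestKeeper ranks (ties share the minimum rank; ΔCt joins via a
switch), with a geometric-mean variant reported alongside; final order
breaks ties by geNorm rank then gene label.

Candidate genes are ΔCq-normalized by subtracting the per-sample
arithmetic mean of the reference Cq values — equivalently, dividing
quantities by the geometric mean of reference quantities, the standard
normalization-factor convention. This makes the result exactly invariant
to a constant cycle shift applied to a whole sample; a literal
geometric-mean-of-Cq mode is provided but is only approximately shift
invariant. Group discrimination uses Bartlett's test (two-group χ²(1)
form) and the Wilcoxon–Mann–Whitney test (exact when both groups ≤ 25
without ties, asymptotic with tie correction otherwise), each BH-adjusted
across genes separately; a gene is flagged reliable only when both
adjusted p ≤ 0.05. That conjunction requires significant
*heteroscedasticity* as well as a location shift — the rule is reproduced
as stated, not endorsed; under the generator's equal-variance shifts it
flags nothing, which is the mathematically expected outcome.

## Synthetic data generator

The generator's defaults encode the study conditions: 7 + 4 genotypes ×
3 biological replicates (21 vs 12 samples), 2000 features across
100–1000 Th, 190 discriminatory features with |log2 FC| drawn from
[1, 3] and random sign applied symmetrically about a log-normal base
abundance spanning ~2.5 decades, multiplicative log-normal intensity
noise with CV 0.3 (typical for direct-infusion profiling), uniform
±0.3 ppm m/z jitter (safely below the 1 ppm alignment tolerance), and a
leucine enkephalin internal standard present in every sample with its
own 20 % intensity variation so normalization is non-trivial.

Missingness is modelled as detection-limit censoring: the per-peak miss
probability is logistic in log intensity around a threshold solved (by
bisection) so that the marginal missing fraction equals the configured
rate. Low peaks therefore vanish preferentially, as in real spectra —
and half-minimum imputation then fills them with values close to truth.
Under missingness that is instead uniform over intensities, half-minimum
imputation plants large low-side outliers on high-intensity features and
measurably destroys t-test power; the censoring model is both the more
realistic choice and the one under which the documented recovery
properties (≥ 90 % of |log2 FC| ≥ 2 features at FDR 0.01) hold.

The Cq generator draws per-gene baselines, a shared per-sample effect
(SD 0.5 cycles, emulating template-amount variation) and per-gene noise
with the requested stability SDs; genes of interest add their group
shift (in cycles) in the susceptible group. Each generator call consumes
a single seeded RNG stream, so identical seeds give identical outputs.

What the simulations do *not* emulate: isotope patterns, correlated
features from shared metabolites/adducts, intensity-dependent m/z error,
calibration drift, plate/batch effects in qPCR, and non-Gaussian Cq
error. Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated statistical model, not robustness to every
artefact of real spectra.

## Numerical conventions and problem sizes

Sample SD (n − 1) throughout; ppm gaps referenced to the smaller mass,
ppm errors to the theoretical mass; p-values reported to 3 decimals,
m/z to 6; permutation exceedance uses ≥. Test-suite simulations use
reduced sizes (hundreds of features, tens of seeds) chosen so each
property suite completes in seconds while keeping comfortable margins to
its thresholds; the acceptance script uses the full study shape
(2000 features, 33 samples, 1000 permutations, five seeds).

## Known limitations

Only two-class OPLS-DA with a single predictive component; no VIP
scores, no multi-class extension, no plot rendering. Annotation has no
isotope-pattern or retention evidence, so hits are putative by design.
The NormFinder estimator is a documented approximation. Raw spectrum
reading (mzML) and peak picking are out of scope — peak lists are
accepted as produced upstream (the S/N ≥ 4 expectation is documented,
not enforced).
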