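# Methods

This note documents the models, conventions and numerical choices behind
`immunoselect`, in the spirit of a statistical package's model documentation:
what is computed, under what assumptions, with which defaults, and what the
synthetic-data validation does and does not demonstrate.

## Presentation scoring (PHBR)

A patient's ability to present a mutated residue is summarized per MHC class
as the harmonic mean of per-molecule best percentile ranks.

- **Scoring slots.** Class I uses the 6 HLA-A/B/C allele slots; class II uses
  12 slots: the 4 DPA1/DPB1 alpha-beta combinations, the 4 DQA1/DQB1
  combinations, and each DRB1 allele twice (DR alpha is invariant; doubling
  keeps DR, DP and DQ equally weighted). Homozygous alleles occupy two slots.
  Fixed slot counts mean zygosity acts through weighting of the harmonic
  mean, not through set size.
- **Windows.** All peptides of the configured lengths that contain at least
  one altered residue, clipped at protein termini: lengths 8–11 for class I,
  15 for class II (configurable). An interior missense mutation therefore
  yields 38 class I and 15 class II windows. Indel conventions: insertions
  mark the inserted residues plus one flanking residue on each side as
  altered; deletions mark the single junction residue. These conventions are
  config-visible because the upstream literature does not pin them down; they
  guarantee every window spans novel sequence. Windows containing
  non-standard residues (X, B, Z, …) are excluded with a logged count.
- **Aggregation.** Per molecule, the best (minimum) rank over the mutation's
  windows; per patient, `n / Σ(1/b_k)` over the n slots. The harmonic mean is
  dominated by the best-presenting molecule, which is the biologically
  relevant direction: one strong binder suffices for T-cell visibility. The
  score is bounded by the slot minimum and maximum and is monotone in every
  slot (tested against exact rational arithmetic).
- **Binding categories.** Strong/weak cutoffs at percentile ranks 0.5/2
  (class I) and 2/10 (class II), strict `<` with boundary values assigned to
  the poorer category — the boundary convention is a declared choice, tested
  explicitly.
- **Coordinates.** All text interfaces use 1-based inclusive residue
  coordinates; internal window arithmetic is 1-based as well, with converters
  exercised in tests.

Scores are kept on the raw percentile-rank scale; the natural-log transform
is applied only when building model designs.

## Affinity backends

Scoring consumes a `(peptide, molecule) → percentile rank ∈ (0, 100]`
contract. Production use supplies a precomputed rank table from an external
predictor (strict: a missing pair is an error, never skipped). The built-in
`SyntheticRankBackend` is a deterministic desk-scale backend for testing and
simulation: the rank is `100·Φ(z)` where `z` mixes an exact-uniform hash of
(peptide, molecule, seed) with a per-molecule seeded anchor-residue
preference over three anchor slots (second residue, centre, C-terminus),
standardized to zero mean and unit variance over random peptides. With mixing
weight 0.3 the marginal rank distribution over random 9-mers stays inside a
1% Kolmogorov–Smirnov band of Uniform(0, 100] while molecules still rank
shared peptides differently, so genotype structure propagates into PHBR
structure. It is a synthetic stand-in, not a trained predictor: it carries no
real binding-motif information.

## Selection models

Occurrence `y_ij ∈ {0,1}` of mutation `j` in patient `i` follows a logistic
model with a per-patient random intercept `η_i ~ N(0, σ²)` absorbing
patient-level mutation propensity. Four fixed-effect variants are supported:
class I + class II scores with sex interactions (1) or age interactions (2),
and single-score models with both sex and age interactions for class I (3)
and class II (4). Covariates are centered at their cohort means: natural-log
PHBR scores, sex coded 0 = male / 1 = female, age in years. The generative
simulator uses the same centering, so generating and recovered coefficients
share a scale. An intercept is always included for identifiability (the term
lists above omit it) and reported alongside the other terms.

- **Filtering before fitting:** patients need scores for both classes;
  mutations are retained when their expressed occurrence count is ≥ 2;
  patients with no observed expressed driver are dropped. The response is the
  raw occurrence indicator over the retained patient × mutation rectangle.
- **Estimation.** Marginal maximum likelihood: the random intercept is
  integrated out per patient by Gauss–Hermite quadrature (probabilists'
  nodes, default 25; 15 nodes reproduce the 25-node estimates to ~1e-8 at
  the intercept SDs arising in these designs and are used in
  replicate-heavy tests). Gradients are analytic; optimization is L-BFGS-B
  over (β, σ) with σ ≥ 0, started from the plain logistic solution (itself
  obtained by the same objective with σ fixed at 0), ftol 1e-9, max 500
  iterations. Convergence status, log-likelihood and the optimizer's
  log-likelihood trace are stored on the fit.
- **Inference.** Wald z and two-sided p per coefficient from the inverse
  observed information (central differences of the analytic gradient). When
  σ̂ collapses to the boundary (< 1e-4) the fixed-effect covariance is
  computed at σ = 0 and the σ standard error is reported as NaN rather than
  from a singular Hessian.
- **Identifiability.** Zero-variance design columns (e.g. sex terms in a
  single-sex cohort) are dropped and recorded in `dropped_terms`; the fit is
  flagged non-identifiable but the remaining terms are still estimated.
- **Quartile odds ratios.** `exp(β̂·(q75 − q25))` with empirical quartiles of
  the centered-log score column; the CI transforms the Wald interval of β̂.
  Degenerate quartiles (q75 = q25) return OR = 1 with a collapsed CI.

Validation: the implementation matches `lme4::glmer` (adaptive quadrature,
nAGQ = 25) to ~5e-3 on all coefficients and the intercept SD on a test
fixture, reproduces ordinary logistic regression when the generating σ is 0,
is equivariant to recoding sex 0/1 → 1/0, shows uniform null p-values over
200 replicate simulations, and covers generating values at the nominal 95%
rate over 100 replicate recovery simulations.

## Group comparisons and the permutation control

- **Pooling unit** is the (patient, mutation) observed-score pair, filtered
  to expressed occurrences by default; patients with no retained pairs
  contribute nothing.
- **Tests.** One-tailed Mann–Whitney U parameterized as (focal, reference,
  alternative "focal greater"): the focal group scoring *higher* means its
  observed drivers are presented *more poorly*. Exact enumeration is used
  when n + m ≤ 12 with no ties, otherwise the midrank normal approximation
  with tie and continuity corrections. Cliff's d follows the same
  orientation: d > 0 when the focal group tends to higher values. (Published
  analyses of this kind sometimes print the opposite sign for the same
  substantive finding; the orientation here is declared in the output
  metadata rather than guessed.) Benjamini–Hochberg adjustment runs across
  each pairwise comparison family. Fisher's exact test reports the sample
  odds ratio `ad/bc` (flagged infinite/NaN with zero cells or margins) with
  the exact hypergeometric p.
- **Age categories.** Below the 30th percentile = younger, above the 70th =
  older, middle excluded; computed pan-cohort by default with a per-tumor-type
  option.
- **Permutation null.** Each of `n_perm` (default 1000, minimum 100)
  iterations applies a random bijection of patients, reassigning every
  patient's mutation set to another patient's genotype (and group label);
  this preserves the multiset of per-mutation occurrence counts and the
  cohort's genotype multiset while destroying any genotype–mutation linkage.
  The statistic (difference of group medians by default; means selectable) is
  recomputed from the reassigned patients' PHBR rows, and the 99% interval is
  the empirical 0.5%/99.5% quantile pair (inverted-CDF definition).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
sex/age/tumor-type patient tables; genotypes drawn per gene from
allele-frequency pools (the defaults are synthetic frequency vectors loosely
shaped like European-ancestry populations — stand-ins, not reference data);
an optional log-normal between-sex tilt of the pools
(`group_frequency_perturbation`, 0 = identical pools, under which male/female
frequency vectors correlate > 0.99 at 2,000 patients); driver catalogs with
i.i.d.-uniform random protein contexts (scoring is sequence-agnostic, so
random contexts exercise it fully), an indel fraction of ~1.8% and DNA
substitution-class probabilities C>T 0.27 / T>C 0.095 / other 0.635,
matching the focal-class share of a recurrent driver set; occurrences drawn
from the selection model itself; VAF ~ Beta(2,3) with negative-binomial
mutant RNA reads (mean = depth × VAF, default depth 60, dispersion 2) and
the expressed flag at ≥ 5 reads — the read model is a package choice, as only
the labeling rule is externally specified; a patient's single mutation takes
VAF percentile rank 100 by convention. Signature activities are log-normal
with a configurable male/female mean ratio.

Not simulated: raw reads, tumor purity, clonal structure, germline variation,
linkage disequilibrium between HLA loci, real binding motifs, or survival.
Passing tests therefore demonstrate that the *statistical machinery* is
correct and calibrated under the assumed generating process — not that the
biological conclusions transfer to any real cohort.

## Problem sizes used in validation

Replicate-heavy checks use cohort sizes chosen for statistical power at
desk scale: null calibration runs 200 replicates of a 150-patient ×
60-mutation study; parameter recovery runs 100 replicates at 400 × 100
(standard errors there are small enough that interaction signs are recovered
in > 90% of replicates); permutation coverage uses 200 replicates at 120
patients with 200 permutations each, and the power check uses 500 patients.
The default end-to-end pipeline is 200 patients × 100 mutations with 1,000
permutations and completes in well under ten minutes on one CPU.

## Known limitations

- The GLMM supports a single random intercept (patient), not crossed or
  nested random effects; tumor-type fixed effects are deliberately absent
  from the model variants.
- Non-adaptive Gauss–Hermite quadrature loses accuracy if per-patient
  information is very high (thousands of mutations per patient) combined
  with large σ; the designs here are far from that regime.
- DRB3/4/5 paralogs are not modeled; allele names are normalized to
  two-field resolution (higher resolution is truncated with a warning).
- The allele allow-list of any particular external predictor is not
  hard-coded; incompatible patients should be filtered upstream or via a
  panel file.
- The expression classifier is a regularized logistic model with gene
  one-hots; unseen genes fall back to the no-gene-effect baseline.
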