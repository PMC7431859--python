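# immunoselect

Patient-specific MHC presentation scoring of cancer driver mutations, and the
biostatistics of immune selection: do sex and age modulate how strongly the
immune system prunes well-presented mutations from tumors?

The package is aimed at cancer immunoinformatics researchers who want a
tested, fully synthetic-data-driven reimplementation of this analysis stack —
every stage runs end to end on generated cohorts with known ground truth, so
the statistical machinery can be validated before it ever touches protected
patient data.

## What it computes

**PHBR scores.** For patient *i* and driver mutation *j*, every peptide
window covering the mutated residue(s) (8–11-mers for MHC class I, 15-mers
for class II) is scored against each of the patient's scoring molecules with
a percentile-rank affinity predictor (lower rank = better presentation). Each
molecule keeps its best (minimum) rank *b<sub>k</sub>*, and the PHBR score is
the harmonic mean over the patient's *n* scoring slots:

```
PHBR_ij = n / Σ_k (1 / b_k)      n = 6 (class I: HLA-A/B/C ×2)
                                 n = 12 (class II: 4 DP + 4 DQ + 4 DR)
```

Class II molecules are alpha/beta heterodimers: all four DPA1/DPB1 and
DQA1/DQB1 combinations, plus each DRB1 allele twice (the DR alpha chain is
invariant). Homozygous alleles occupy two slots, so the slot counts are fixed
regardless of zygosity. A *high* PHBR means the mutation is poorly presented
and invisible to T cells. Affinity prediction is a pluggable backend: bring a
precomputed rank table from any predictor, or use the built-in deterministic
synthetic backend.

**Selection models.** Mutation occurrence *y<sub>ij</sub>* ∈ {0,1} is related
to centered log-PHBR scores *x1* (class I), *x2* (class II) and a centered
covariate (sex coded 0/1 male/female, or age in years) by a random-intercept
logistic model, e.g. the sex variant:

```
logit P(y_ij = 1) = β0 + β1·x1_ij + β2·x2_ij + β3·Sex_i
                    + β4·(x1_ij × Sex_i) + β5·(x2_ij × Sex_i) + η_i,
η_i ~ N(0, σ²)
```

fit by marginal maximum likelihood (Gauss–Hermite quadrature over the
per-patient random intercept η, analytic gradients, quasi-Newton optimizer),
with Wald tests from the observed-information covariance. Positive β2 means
poorly presented mutations are more likely to be observed — immune selection;
a positive β5 means that selection is stronger in females. Effect sizes are
summarized as odds ratios between the 25th and 75th score percentiles,
`exp(β̂·(q75 − q25))`.

**Cohort statistics.** One-tailed Mann–Whitney U comparisons of pooled
observed-mutation scores between sex/age groups, Cliff's d effect sizes,
Benjamini–Hochberg adjustment across comparison families, Fisher's exact
tests, and a mutation-reassignment permutation control: mutation sets are
reassigned to randomly re-drawn patients (breaking the genotype–mutation
linkage while preserving per-mutation occurrence counts) and the group
statistic is compared with the 99% interval of its permutation null.

**Auxiliary analyses.** log2 male/female mutational-signature activity
ratios per tumor type, driver-per-signature percentages, presentation of
C>T / T>C substitutions versus other substitution classes across a whole
allele panel, and a logistic classifier predicting binary RNA expression
(≥5 mutant reads) from DNA VAF, within-patient VAF percentile rank, and gene.

**Synthetic cohorts.** `immunoselect.simulate` generates patient tables, HLA
genotypes from per-gene allele-frequency pools, driver catalogs with random
protein contexts, occurrences drawn from exactly the selection model above
(so recovered coefficients can be audited against the generating truth),
VAF-driven expression labels, and sex-biased signature activities.

## Worked example

```python
from immunoselect.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=7, out_dir="results"))
print(manifest["stages"]["models"]["estimates"]["1"])
```

With the default configuration (200 patients × 100 driver mutations,
occurrences generated with β2 = 0.31, β5 = 0.15, σ = 0.3), this prints the
recovered sex-model coefficients:

```
{'intercept': -2.559, 'phbr_i': 0.014, 'phbr_ii': 0.335,
 'sex': -0.103, 'phbr_i:sex': 0.016, 'phbr_ii:sex': 0.223}
```

The PHBR-II main effect (0.335) recovers the generating value 0.31 well
inside its standard error at this cohort size; the smaller interaction and
class I effects are noisier at n = 200, as expected. The bundle written to
`results/` also contains, from the same run:

- `quartile_odds_ratios.tsv` — the model-implied PHBR-II quartile odds ratio
  (1.41 here): mutations at the 75th percentile of log PHBR-II are ~1.4×
  more likely to be observed than those at the 25th;
- `comparisons_sex_II.tsv` — pooled female-vs-male class II comparison
  (medians 2.68 vs 2.57, one-tailed Mann–Whitney p = 0.020, Cliff's
  d = 0.067): females' observed drivers score higher, i.e. are presented
  more poorly, as the positive generating interaction implies;
- `permutation.tsv` — the observed sex gap against its 99% permutation null
  interval;
- `manifest.json` — versions, per-stage seeds, the config hash, and the
  generating truth recorded next to the estimates.

The same pipeline is available from the shell:

```bash
immunoselect run --seed 7 --out results
immunoselect simulate --seed 3 --n-patients 100 --n-mutations 50 --out syn/
immunoselect phbr --genotypes syn/genotypes.tsv --catalog syn/catalog.tsv \
    --proteins syn/proteins.fasta --mhc-class II --out syn/phbr_II.tsv
```

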