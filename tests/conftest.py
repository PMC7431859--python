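import numpy as np
import pytest

from immunoselect import glmm
from immunoselect.hla import HLAAllele, HLAGenotype
from immunoselect.peptides import SyntheticRankBackend
from immunoselect.phbr import PHBRMatrix, score_matrix
from immunoselect.simulate import (
    CohortConfig,
    DriverCatalogConfig,
    SelectionTruth,
    generate_cohort,
    generate_driver_catalog,
    simulate_expression,
    simulate_mutations,
)


def make_genotype(**overrides) -> HLAGenotype:
    """A fully heterozygous genotype; override per-gene pairs by gene name."""
    pairs = {
        "A": ("A*02:01", "A*01:01"),
        "B": ("B*07:02", "B*08:01"),
        "C": ("C*07:01", "C*07:02"),
        "DRB1": ("DRB1*15:01", "DRB1*03:01"),
        "DPA1": ("DPA1*01:03", "DPA1*02:01"),
        "DPB1": ("DPB1*04:01", "DPB1*02:01"),
        "DQA1": ("DQA1*01:02", "DQA1*05:01"),
        "DQB1": ("DQB1*03:01", "DQB1*06:02"),
    }
    pairs.update(overrides)
    return HLAGenotype({
        gene: tuple(HLAAllele.parse(a) for a in pair) for gene, pair in pairs.items()
    })


@pytest.fixture(scope="session")
def het_genotype():
    return make_genotype()


@pytest.fixture(scope="session")
def small_cohort():
    """50 patients, 30 mutations, scored for both classes."""
    cohort, genotypes = generate_cohort(CohortConfig(n_patients=50, seed=11))
    catalog, proteins = generate_driver_catalog(DriverCatalogConfig(n_mutations=30), seed=12)
    backend = SyntheticRankBackend(seed=13)
    phbr_i = score_matrix(genotypes, catalog, proteins, backend, "I")
    phbr_ii = score_matrix(genotypes, catalog, proteins, backend, "II")
    return {
        "cohort": cohort, "genotypes": genotypes, "catalog": catalog,
        "proteins": proteins, "backend": backend,
        "phbr_i": phbr_i, "phbr_ii": phbr_ii,
    }


@pytest.fixture(scope="session")
def scored_study(small_cohort):
    """The small cohort with occurrences and expression under known truth."""
    truth = SelectionTruth(beta1=0.048, beta2=0.31, beta3=-0.02, beta4=0.07,
                           beta5=0.15, theta_eta=0.3, intercept=-2.0)
    occurrence = simulate_mutations(
        small_cohort["cohort"], small_cohort["phbr_i"], small_cohort["phbr_ii"],
        truth, covariate="sex", seed=14,
    )
    expr_long, expressed = simulate_expression(occurrence, seed=15)
    matrix = PHBRMatrix(small_cohort["phbr_i"], small_cohort["phbr_ii"],
                        occurrence, expressed)
    return {**small_cohort, "truth": truth, "occurrence": occurrence,
            "expressed": expressed, "expr_long": expr_long, "matrix": matrix,
            "long": matrix.to_long()}
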