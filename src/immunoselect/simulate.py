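"""Synthetic cohorts with known ground truth.

Generates everything the analysis consumes: patient tables with sex, age and
tumor type; HLA genotypes drawn from per-gene allele-frequency pools (with
an optional between-group frequency perturbation — zero perturbation means
the sexes sample from identical pools, emulating cohorts whose male/female
allele-frequency vectors correlate near 1); driver-mutation catalogs with
random protein contexts; mutation occurrences drawn from the same
random-intercept logistic model the fitting side estimates, so recovered
coefficients can be compared to the truth that generated them; VAF-driven
RNA expression labels; and per-patient mutational-signature activities with
configurable sex bias.

Default allele pools are synthetic frequency vectors loosely shaped like
European-ancestry population frequencies; they are stand-ins, not reference
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from ._rng import child_rng
from .hla import ALL_GENES, HLAAllele, HLAGenotype
from .peptides import AMINO_ACIDS, DriverMutation

# synthetic per-gene allele pools (allele name, frequency); frequencies sum to 1
DEFAULT_ALLELE_POOL: dict[str, tuple[tuple[str, float], ...]] = {
    "A": (("A*02:01", 0.29), ("A*01:01", 0.16), ("A*03:01", 0.13), ("A*24:02", 0.11),
          ("A*11:01", 0.08), ("A*26:01", 0.05), ("A*32:01", 0.04), ("A*68:01", 0.04),
          ("A*23:01", 0.03), ("A*29:02", 0.03), ("A*31:01", 0.02), ("A*25:01", 0.02)),
    "B": (("B*07:02", 0.14), ("B*08:01", 0.12), ("B*44:02", 0.10), ("B*15:01", 0.08),
          ("B*35:01", 0.08), ("B*44:03", 0.07), ("B*51:01", 0.07), ("B*18:01", 0.06),
          ("B*40:01", 0.06), ("B*27:05", 0.05), ("B*57:01", 0.05), ("B*13:02", 0.04),
          ("B*38:01", 0.04), ("B*14:02", 0.04)),
    "C": (("C*07:01", 0.17), ("C*07:02", 0.15), ("C*04:01", 0.13), ("C*06:02", 0.10),
          ("C*03:04", 0.09), ("C*05:01", 0.08), ("C*03:03", 0.07), ("C*12:03", 0.06),
          ("C*02:02", 0.05), ("C*01:02", 0.04), ("C*08:02", 0.03), ("C*16:01", 0.03)),
    "DRB1": (("DRB1*15:01", 0.14), ("DRB1*03:01", 0.12), ("DRB1*07:01", 0.12),
             ("DRB1*04:01", 0.09), ("DRB1*01:01", 0.09), ("DRB1*11:01", 0.08),
             ("DRB1*13:01", 0.07), ("DRB1*13:02", 0.06), ("DRB1*08:01", 0.05),
             ("DRB1*04:04", 0.05), ("DRB1*09:01", 0.04), ("DRB1*12:01", 0.03),
             ("DRB1*14:01", 0.03), ("DRB1*16:01", 0.03)),
    "DPA1": (("DPA1*01:03", 0.77), ("DPA1*02:01", 0.13), ("DPA1*02:02", 0.06),
             ("DPA1*01:04", 0.04)),
    "DPB1": (("DPB1*04:01", 0.40), ("DPB1*02:01", 0.14), ("DPB1*04:02", 0.12),
             ("DPB1*03:01", 0.10), ("DPB1*01:01", 0.08), ("DPB1*06:01", 0.05),
             ("DPB1*05:01", 0.05), ("DPB1*11:01", 0.03), ("DPB1*13:01", 0.03)),
    "DQA1": (("DQA1*01:02", 0.20), ("DQA1*05:01", 0.18), ("DQA1*03:01", 0.14),
             ("DQA1*01:01", 0.12), ("DQA1*02:01", 0.11), ("DQA1*01:03", 0.09),
             ("DQA1*04:01", 0.06), ("DQA1*05:05", 0.05), ("DQA1*06:01", 0.05)),
    "DQB1": (("DQB1*03:01", 0.19), ("DQB1*06:02", 0.14), ("DQB1*02:01", 0.13),
             ("DQB1*05:01", 0.12), ("DQB1*03:02", 0.10), ("DQB1*02:02", 0.08),
             ("DQB1*06:03", 0.07), ("DQB1*04:02", 0.06), ("DQB1*03:03", 0.05),
             ("DQB1*05:02", 0.03), ("DQB1*06:04", 0.03)),
}

DEFAULT_TUMOR_TYPES = ("LUAD", "SKCM", "HNSC", "BLCA", "COAD", "STAD")
DEFAULT_SIGNATURES = ("01", "02", "05", "13")


@dataclass
class CohortConfig:
    """Study conditions for cohort generation."""

    n_patients: int = 200
    sex_fraction_female: float = 0.5
    age_mean: float = 60.0
    age_sd: float = 12.0
    age_min: float = 20.0
    age_max: float = 90.0
    tumor_type_labels: Sequence[str] = DEFAULT_TUMOR_TYPES
    allele_pool: Mapping[str, Sequence[tuple[str, float]]] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_POOL)
    )
    group_frequency_perturbation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ValueError("sex_fraction_female must be a probability")
        if self.group_frequency_perturbation < 0:
            raise ValueError("group_frequency_perturbation must be nonnegative")
        for gene in ALL_GENES:
            pool = self.allele_pool.get(gene)
            if not pool:
                raise ValueError(f"empty allele pool for gene {gene}")
            total = sum(f for _, f in pool)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"allele frequencies for gene {gene} sum to {total}, not 1")


@dataclass(frozen=True)
class SelectionTruth:
    """Generative coefficients of the occurrence model (the fitting target)."""

    beta1: float = 0.0   # PHBR-I main effect
    beta2: float = 0.0   # PHBR-II main effect
    beta3: float = 0.0   # sex or age main effect
    beta4: float = 0.0   # PHBR-I x covariate interaction
    beta5: float = 0.0   # PHBR-II x covariate interaction
    theta_eta: float = 0.0  # random-intercept SD
    intercept: float = -3.0

    def __post_init__(self):
        vals = (self.beta1, self.beta2, self.beta3, self.beta4, self.beta5,
                self.theta_eta, self.intercept)
        if not all(np.isfinite(vals)):
            raise ValueError("all truth parameters must be finite")
        if self.theta_eta < 0:
            raise ValueError("theta_eta must be nonnegative")


@dataclass
class DriverCatalogConfig:
    """Rules for the synthetic driver-mutation catalog."""

    n_mutations: int = 100
    protein_length_min: int = 300
    protein_length_max: int = 700
    fraction_indels: float = 18.0 / 1018.0  # indel share of a recurrent driver set
    substitution_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"C>T": 0.27, "T>C": 0.095, "other": 0.635}
    )
    signature_labels: Sequence[str] = DEFAULT_SIGNATURES
    min_recurrence: int = 3

    def __post_init__(self):
        if self.n_mutations < 1:
            raise ValueError("n_mutations must be >= 1")
        total = sum(self.substitution_class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"substitution class probabilities sum to {total}, not 1")
        if not 0.0 <= self.fraction_indels <= 1.0:
            raise ValueError("fraction_indels must be a probability")


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict[str, HLAGenotype]]:
    """Sample a patient table and full HLA genotypes.

    Sex is drawn Bernoulli(sex_fraction_female), age from a truncated normal
    in years, tumor type uniformly over the configured labels.  Genotypes
    draw two alleles per gene from the pool; with a positive
    ``group_frequency_perturbation`` each sex samples from a log-normally
    tilted copy of the pool (perturbation 0 keeps the pools identical).
    """
    rng = child_rng(config.seed, "cohort")
    n = config.n_patients
    pids = [f"P{i:05d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.sex_fraction_female, "female", "male")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n),
                  config.age_min, config.age_max)
    tumor = rng.choice(np.asarray(config.tumor_type_labels, dtype=object), size=n)
    cohort = pd.DataFrame({
        "patient_id": pids, "sex": sex, "age_years": np.round(age, 1), "tumor_type": tumor,
    })

    # per-sex allele frequency vectors (tilted only when perturbation > 0)
    freqs: dict[str, dict[str, np.ndarray]] = {}
    for gene, pool in config.allele_pool.items():
        base = np.array([f for _, f in pool])
        freqs[gene] = {}
        for group in ("male", "female"):
            if config.group_frequency_perturbation > 0:
                tilt_rng = child_rng(config.seed, f"tilt:{gene}:{group}")
                tilted = base * np.exp(
                    config.group_frequency_perturbation * tilt_rng.normal(size=base.size)
                )
                freqs[gene][group] = tilted / tilted.sum()
            else:
                freqs[gene][group] = base

    genotypes: dict[str, HLAGenotype] = {}
    geno_rng = child_rng(config.seed, "genotypes")
    for pid, s in zip(pids, sex):
        alleles = {}
        for gene, pool in config.allele_pool.items():
            names = [a for a, _ in pool]
            picks = geno_rng.choice(len(names), size=2, p=freqs[gene][s])
            pair = tuple(HLAAllele.parse(names[k]) for k in sorted(picks))
            alleles[gene] = pair
        genotypes[pid] = HLAGenotype(alleles)
    return cohort, genotypes


def generate_driver_catalog(
    config: DriverCatalogConfig, seed: int = 0
) -> tuple[list[DriverMutation], dict[str, str]]:
    """Sample a driver catalog with random protein contexts.

    Each mutation gets its own synthetic protein (i.i.d. uniform residues),
    a position, ref/alt residues or an inframe indel, a DNA substitution
    class and a signature label.  Proteins shorter than the longest peptide
    window are resampled.
    """
    rng = child_rng(seed, "catalog")
    classes = list(config.substitution_class_probs)
    class_p = np.array([config.substitution_class_probs[c] for c in classes])
    sig_map = {"C>T": "01", "T>C": "05"}
    other_sigs = [s for s in config.signature_labels if s not in ("01", "05")] or ["unassigned"]

    catalog: list[DriverMutation] = []
    proteins: dict[str, str] = {}
    aa = np.array(list(AMINO_ACIDS))
    for j in range(config.n_mutations):
        length = 0
        while length < 15:  # longest scoring window
            length = int(rng.integers(config.protein_length_min, config.protein_length_max + 1))
        seq = "".join(rng.choice(aa, size=length))
        protein_id = f"PROT{j:04d}"
        proteins[protein_id] = seq
        gene = f"GENE{j % 50:03d}"
        sub_class = classes[int(rng.choice(len(classes), p=class_p))]
        if sub_class in sig_map:
            signature = sig_map[sub_class] if sig_map[sub_class] in config.signature_labels else "unassigned"
        else:
            signature = str(other_sigs[int(rng.integers(len(other_sigs)))])

        is_indel = rng.random() < config.fraction_indels
        if not is_indel:
            pos = int(rng.integers(1, length + 1))
            ref = seq[pos - 1]
            alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
            mut = DriverMutation(f"MUT{j:04d}", gene, protein_id, "missense",
                                 pos, ref, alt, sub_class, signature)
        else:
            indel_len = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                pos = int(rng.integers(2, length - indel_len))
                mut = DriverMutation(f"MUT{j:04d}", gene, protein_id, "inframe_indel",
                                     pos, seq[pos - 1 : pos - 1 + indel_len], "",
                                     sub_class, signature)
            else:  # insertion
                pos = int(rng.integers(1, length))
                ins = "".join(rng.choice(aa, size=indel_len))
                mut = DriverMutation(f"MUT{j:04d}", gene, protein_id, "inframe_indel",
                                     pos, "", ins, sub_class, signature)
        catalog.append(mut)
    return catalog, proteins


def _centered_covariate(cohort: pd.DataFrame, covariate: Literal["sex", "age"]) -> np.ndarray:
    if covariate == "sex":
        vals = cohort["sex"].map({"male": 0.0, "female": 1.0}).to_numpy()
    elif covariate == "age":
        vals = cohort["age_years"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown covariate: {covariate!r}")
    return vals - vals.mean()


def mutation_probabilities(
    cohort: pd.DataFrame,
    phbr_i: pd.DataFrame,
    phbr_ii: pd.DataFrame,
    truth: SelectionTruth,
    covariate: Literal["sex", "age"] = "sex",
    eta: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cell-wise logistic occurrence probabilities under the generative model.

    Covariates are centered with the cohort means (the same convention the
    fitting side uses, so truth and recovered coefficients share a scale).
    """
    cohort = cohort.set_index("patient_id").loc[phbr_i.index].reset_index()
    for name, mat in (("PHBR-I", phbr_i), ("PHBR-II", phbr_ii)):
        arr = mat.to_numpy()
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            bad = np.argwhere(~(np.isfinite(arr) & (arr > 0)))[:5]
            cells = ", ".join(f"({mat.index[i]}, {mat.columns[j]})" for i, j in bad)
            raise ValueError(f"non-finite or nonpositive {name} entries at: {cells}")
    x1 = np.log(phbr_i.to_numpy())
    x2 = np.log(phbr_ii.loc[phbr_i.index, phbr_i.columns].to_numpy())
    x1c = x1 - x1.mean()
    x2c = x2 - x2.mean()
    cov = _centered_covariate(cohort, covariate)[:, None]
    lin = (truth.intercept + truth.beta1 * x1c + truth.beta2 * x2c + truth.beta3 * cov
           + truth.beta4 * x1c * cov + truth.beta5 * x2c * cov)
    if eta is not None:
        lin = lin + np.asarray(eta)[:, None]
    return pd.DataFrame(expit(lin), index=phbr_i.index, columns=phbr_i.columns)


def simulate_mutations(
    cohort: pd.DataFrame,
    phbr_i: pd.DataFrame,
    phbr_ii: pd.DataFrame,
    truth: SelectionTruth,
    covariate: Literal["sex", "age"] = "sex",
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the binary occurrence matrix from the generative selection model."""
    rng = child_rng(seed, "mutations")
    eta = truth.theta_eta * rng.standard_normal(len(phbr_i.index))
    p = mutation_probabilities(cohort, phbr_i, phbr_ii, truth, covariate, eta=eta)
    y = (rng.random(p.shape) < p.to_numpy()).astype(int)
    return pd.DataFrame(y, index=p.index, columns=p.columns)


def simulate_expression(
    occurrence: pd.DataFrame,
    seed: int = 0,
    mean_depth: float = 60.0,
    read_dispersion: float = 2.0,
    expressed_threshold: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate DNA VAF and mutant RNA reads for every occurred mutation.

    VAF is Beta(2, 3); mutant RNA reads are negative binomial with mean
    ``mean_depth * vaf``; a mutation is expressed when its mutant reads reach
    the threshold (default >= 5).  VAF percentile ranks are computed within
    each patient over their occurred mutations (a single mutation ranks 100).

    Returns ``(long_table, expressed_matrix)`` with the matrix aligned to the
    occurrence matrix (0 where not occurred).
    """
    rng = child_rng(seed, "expression")
    rows = []
    expressed = pd.DataFrame(0, index=occurrence.index, columns=occurrence.columns)
    occ = occurrence.to_numpy().astype(bool)
    for i, pid in enumerate(occurrence.index):
        muts = occurrence.columns[occ[i]]
        if len(muts) == 0:
            continue
        vaf = np.clip(rng.beta(2.0, 3.0, size=len(muts)), 1e-6, 1.0)
        mean_reads = mean_depth * vaf
        p_nb = read_dispersion / (read_dispersion + mean_reads)
        reads = rng.negative_binomial(read_dispersion, p_nb)
        pct = 100.0 * rankdata(vaf, method="average") / len(vaf)
        flags = reads >= expressed_threshold
        expressed.loc[pid, muts] = flags.astype(int)
        for m, v, r, q, f in zip(muts, vaf, reads, pct, flags):
            rows.append((pid, m, float(v), int(r), float(q), bool(f)))
    long = pd.DataFrame(
        rows, columns=["patient_id", "mutation_id", "vaf", "rna_mut_reads",
                       "vaf_percentile_rank", "expressed"],
    )
    return long, expressed


def simulate_signature_activities(
    cohort: pd.DataFrame,
    signature_labels: Sequence[str] = DEFAULT_SIGNATURES,
    sex_bias: Mapping[str, float] | None = None,
    seed: int = 0,
    log_sd: float = 0.5,
) -> pd.DataFrame:
    """Per-patient nonnegative signature activities with optional sex bias.

    Activities are log-normal; for a biased signature the male/female mean
    ratio equals the configured bias (bias 1 = unbiased).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if not signature_labels:
        raise ValueError("signature_labels must be nonempty")
    sex_bias = dict(sex_bias or {})
    for sig, b in sex_bias.items():
        if b <= 0:
            raise ValueError(f"sex bias for signature {sig} must be positive, got {b}")
    rng = child_rng(seed, "signatures")
    out = pd.DataFrame({
        "patient_id": cohort["patient_id"],
        "tumor_type": cohort["tumor_type"],
        "sex": cohort["sex"],
    })
    male = (cohort["sex"] == "male").to_numpy()
    for sig in signature_labels:
        bias = sex_bias.get(sig, 1.0)
        mu = np.where(male, np.log(bias), 0.0)
        out[f"sig_{sig}"] = rng.lognormal(mean=mu, sigma=log_sd)
    return out
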