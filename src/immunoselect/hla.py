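"""HLA genotypes and MHC scoring molecule sets.

A patient's class I scoring set is their 6 HLA-A/B/C allele slots (homozygous
alleles occupy two slots).  The class II scoring set has 12 slots: the 4
DPA1/DPB1 alpha-beta combinations, the 4 DQA1/DQB1 combinations, and each
DRB1 allele counted twice (the DR alpha chain is invariant, so a DR molecule
is determined by its beta allele; doubling keeps DR on the same footing as
DP and DQ).  Slot multiplicity is deliberate: it weights the harmonic mean,
so the 6/12 slot counts hold regardless of zygosity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_I_GENES = ("A", "B", "C")
CLASS_II_GENES = ("DRB1", "DPA1", "DPB1", "DQA1", "DQB1")
ALL_GENES = CLASS_I_GENES + CLASS_II_GENES

_ALLELE_RE = re.compile(r"^(?P<gene>[A-Z0-9]+)\*(?P<fields>\d+(?::\d+)+[A-Z]?)$")


class IncompleteGenotypeError(ValueError):
    """Raised when a scoring set is requested for a class with missing typing."""

    def __init__(self, missing_genes: Sequence[str]):
        self.missing_genes = tuple(missing_genes)
        super().__init__(f"incomplete HLA typing; missing gene(s): {', '.join(self.missing_genes)}")


@dataclass(frozen=True, order=True)
class HLAAllele:
    """One HLA allele in two-field nomenclature, e.g. ``A*02:01``."""

    gene: str
    name: str

    def __post_init__(self):
        m = _ALLELE_RE.match(self.name)
        if m is None:
            raise ValueError(f"unparseable HLA allele name: {self.name!r}")
        if m.group("gene") != self.gene:
            raise ValueError(f"allele {self.name!r} does not belong to gene {self.gene!r}")
        if self.gene not in ALL_GENES:
            raise ValueError(f"unsupported HLA gene: {self.gene!r}")

    @classmethod
    def parse(cls, name: str) -> "HLAAllele":
        """Parse an allele string, truncating to two-field resolution if needed."""
        m = _ALLELE_RE.match(name.strip())
        if m is None:
            raise ValueError(f"unparseable HLA allele name: {name!r}")
        fields = m.group("fields").rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ").split(":")
        if len(fields) > 2:
            logger.warning("truncating allele %s to two-field resolution", name)
            fields = fields[:2]
        return cls(gene=m.group("gene"), name=f"{m.group('gene')}*{':'.join(fields[:2])}")


@dataclass(frozen=True)
class MHCMolecule:
    """A scoring molecule: a class I allele or a class II alpha/beta heterodimer.

    DR molecules carry only the beta allele (DRA1 is invariant).
    """

    mhc_class: Literal["I", "II"]
    alleles: tuple[HLAAllele, ...]

    def __post_init__(self):
        if self.mhc_class == "I":
            if len(self.alleles) != 1 or self.alleles[0].gene not in CLASS_I_GENES:
                raise ValueError("class I molecule must be a single A/B/C allele")
        else:
            genes = tuple(a.gene for a in self.alleles)
            if genes not in (("DPA1", "DPB1"), ("DQA1", "DQB1"), ("DRB1",)):
                raise ValueError(f"invalid class II heterodimer genes: {genes}")

    @property
    def name(self) -> str:
        return "/".join(a.name for a in self.alleles)

    @classmethod
    def parse(cls, text: str) -> "MHCMolecule":
        alleles = tuple(HLAAllele.parse(part) for part in text.strip().split("/"))
        mhc_class = "I" if alleles[0].gene in CLASS_I_GENES else "II"
        return cls(mhc_class, alleles)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


@dataclass
class HLAGenotype:
    """Two allele slots per gene; homozygotes repeat the allele."""

    alleles: Mapping[str, tuple[HLAAllele, HLAAllele]] = field(default_factory=dict)

    def missing_genes(self, mhc_class: Literal["I", "II"]) -> tuple[str, ...]:
        genes = CLASS_I_GENES if mhc_class == "I" else CLASS_II_GENES
        return tuple(g for g in genes if g not in self.alleles)

    def is_complete(self, mhc_class: Literal["I", "II"]) -> bool:
        return not self.missing_genes(mhc_class)


#: ordered scoring slots; a list of MHCMolecule with multiplicity
MoleculeSet = list


def assemble_molecules(genotype: HLAGenotype, mhc_class: Literal["I", "II"]) -> MoleculeSet:
    """Build the ordered scoring slots for one class of a genotype.

    Class I yields exactly 6 slots (A, B, C in gene order, alleles sorted
    within each gene).  Class II yields exactly 12: 4 DP combinations,
    4 DQ combinations, then each DRB1 allele twice; within each group slots
    are sorted lexicographically by molecule name.  Duplicate slots are
    preserved — they weight the harmonic mean.
    """
    if mhc_class not in ("I", "II"):
        raise ValueError(f"unknown MHC class: {mhc_class!r}")
    missing = genotype.missing_genes(mhc_class)
    if missing:
        raise IncompleteGenotypeError(missing)

    slots: MoleculeSet = []
    if mhc_class == "I":
        for gene in CLASS_I_GENES:
            for allele in sorted(genotype.alleles[gene]):
                slots.append(MHCMolecule("I", (allele,)))
        assert len(slots) == 6
        return slots

    for alpha_gene, beta_gene in (("DPA1", "DPB1"), ("DQA1", "DQB1")):
        combos = [
            MHCMolecule("II", (alpha, beta))
            for alpha, beta in product(genotype.alleles[alpha_gene], genotype.alleles[beta_gene])
        ]
        slots.extend(sorted(combos, key=lambda m: m.name))
    dr = [MHCMolecule("II", (b,)) for b in sorted(genotype.alleles["DRB1"]) for _ in range(2)]
    slots.extend(dr)
    assert len(slots) == 12
    return slots


# ---------------------------------------------------------------------------
# Genotype tables (TSV: patient_id, gene, allele; one row per slot)
# ---------------------------------------------------------------------------

def genotypes_to_frame(genotypes: Mapping[str, HLAGenotype]) -> pd.DataFrame:
    rows = []
    for pid, gt in genotypes.items():
        for gene in ALL_GENES:
            if gene in gt.alleles:
                for allele in gt.alleles[gene]:
                    rows.append((pid, gene, allele.name))
    return pd.DataFrame(rows, columns=["patient_id", "gene", "allele"])


def genotypes_from_frame(frame: pd.DataFrame) -> dict[str, HLAGenotype]:
    required = {"patient_id", "gene", "allele"}
    if not required.issubset(frame.columns):
        raise ValueError(f"genotype table needs columns {sorted(required)}")
    out: dict[str, HLAGenotype] = {}
    for (pid, gene), grp in frame.groupby(["patient_id", "gene"], sort=False):
        if len(grp) != 2:
            raise ValueError(f"patient {pid} gene {gene}: expected 2 allele slots, found {len(grp)}")
        pair = tuple(HLAAllele.parse(a) for a in grp["allele"])
        gt = out.setdefault(str(pid), HLAGenotype({}))
        gt.alleles = {**gt.alleles, gene: pair}  # type: ignore[assignment]
    return out


def read_genotypes(path) -> dict[str, HLAGenotype]:
    return genotypes_from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_genotypes(genotypes: Mapping[str, HLAGenotype], path) -> None:
    genotypes_to_frame(genotypes).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele-frequency structure between cohort groups
# ---------------------------------------------------------------------------

def allele_frequencies(
    genotypes: Mapping[str, HLAGenotype],
    grouping: Mapping[str, object],
    mhc_class: Literal["I", "II"],
) -> pd.DataFrame:
    """Per-group allele frequencies over the union of observed alleles.

    Returns a DataFrame indexed by (gene, allele) with one column per group;
    within each gene and group the frequencies sum to 1.  Patients missing a
    gene's typing simply contribute no slots for that gene.

    Raises ``ValueError`` for a group level with no patients.
    """
    genes = CLASS_I_GENES if mhc_class == "I" else CLASS_II_GENES
    levels = sorted({str(v) for v in grouping.values()})
    members: dict[str, list[str]] = {lv: [] for lv in levels}
    for pid, lv in grouping.items():
        members[str(lv)].append(pid)
    for lv, pids in members.items():
        if not pids:
            raise ValueError(f"empty group level: {lv!r}")

    counts: dict[str, dict[tuple[str, str], int]] = {lv: {} for lv in levels}
    for lv, pids in members.items():
        for pid in pids:
            gt = genotypes.get(pid)
            if gt is None:
                continue
            for gene in genes:
                for allele in gt.alleles.get(gene, ()):
                    key = (gene, allele.name)
                    counts[lv][key] = counts[lv].get(key, 0) + 1
        if not counts[lv]:
            raise ValueError(f"empty group level: {lv!r} (no genotyped patients)")

    universe = sorted({k for c in counts.values() for k in c})
    index = pd.MultiIndex.from_tuples(universe, names=["gene", "allele"])
    freq = pd.DataFrame(0.0, index=index, columns=levels)
    for lv in levels:
        for key, n in counts[lv].items():
            freq.loc[key, lv] = n
        for gene in genes:
            if gene in freq.index.get_level_values("gene"):
                sub = freq.loc[gene, lv]
                total = sub.sum()
                if total > 0:
                    freq.loc[(gene, slice(None)), lv] = (sub / total).to_numpy()
    return freq


def genotype_frequency_correlation(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Pearson correlation of two aligned allele-frequency vectors.

    Returns NaN (flagged missing) when either vector has zero variance.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frequency vectors must be aligned on the same allele universe")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
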