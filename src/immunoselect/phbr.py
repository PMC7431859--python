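"""PHBR scoring: harmonic-mean aggregation of best per-molecule ranks.

For one patient and one mutation, each of the patient's scoring molecules
contributes its *best* (minimum) percentile rank over all mutant peptide
windows covering the altered residues; the PHBR score is the harmonic mean
of those per-slot best ranks across the 6 class I or 12 class II slots.
The harmonic mean is dominated by the best-presenting molecule: a single
strong binder pulls the score down, so a low PHBR means the mutation is
visible to that patient's immune system and a high PHBR means it is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .hla import HLAGenotype, MHCMolecule, assemble_molecules
from .peptides import DriverMutation, RankBackend, apply_mutation, default_lengths, extract_windows

SLOT_COUNT = {"I": 6, "II": 12}

#: strong/weak percentile-rank cutoffs per class (strict <; boundary values
#: fall in the poorer category)
BINDING_CUTOFFS = {"I": (0.5, 2.0), "II": (2.0, 10.0)}


def best_residue_rank(
    rank_lookup: Mapping[tuple[str, str], float],
    molecule: MHCMolecule,
    windows: Sequence[str],
) -> float:
    """Minimum rank over a mutation's windows for one molecule.

    Every window must be scored; a missing (peptide, molecule) entry is an
    error, never silently skipped.
    """
    if not windows:
        raise ValueError("no windows to score")
    ranks = []
    for pep in windows:
        key = (pep, molecule.name)
        if key not in rank_lookup:
            raise KeyError(f"unscored window: peptide {pep!r}, molecule {molecule.name}")
        ranks.append(float(rank_lookup[key]))
    return min(ranks)


def phbr(per_slot_best_ranks: Sequence[float], mhc_class: Literal["I", "II"] | None = None) -> float:
    """Harmonic mean ``n / sum(1/s_k)`` of per-slot best ranks.

    If ``mhc_class`` is given the slot count is enforced (6 for class I, 12
    for class II).  All inputs must be strictly positive.
    """
    s = np.asarray(per_slot_best_ranks, dtype=float)
    if s.size == 0:
        raise ValueError("empty slot list")
    if mhc_class is not None and s.size != SLOT_COUNT[mhc_class]:
        raise ValueError(f"class {mhc_class} requires {SLOT_COUNT[mhc_class]} slots, got {s.size}")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("per-slot best ranks must be finite and > 0")
    return float(s.size / np.sum(1.0 / s))


def classify_binding(value: float, mhc_class: Literal["I", "II"]) -> str:
    """Strong/weak/nonbinder call at the conventional percentile-rank cutoffs.

    Class I: <0.5 strong, <2 weak; class II: <2 strong, <10 weak.  Boundary
    values are assigned to the poorer category (strict <).
    """
    if mhc_class not in BINDING_CUTOFFS:
        raise ValueError(f"unknown MHC class: {mhc_class!r}")
    if not (value > 0):
        raise ValueError("score must be > 0")
    strong, weak = BINDING_CUTOFFS[mhc_class]
    if value < strong:
        return "strong"
    if value < weak:
        return "weak"
    return "nonbinder"


def fraction_presented(scores: pd.DataFrame, threshold: float) -> pd.Series:
    """Per-patient fraction of mutations scoring below ``threshold``.

    NaN for a patient with no scored mutations (flagged missing).
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    if scores.shape[1] == 0:
        return pd.Series(np.nan, index=scores.index)
    return (scores < threshold).mean(axis=1)


@dataclass
class PHBRMatrix:
    """Aligned patients x mutations matrices for one study.

    ``phbr_i`` / ``phbr_ii`` are raw percentile-rank-scale PHBR scores (the
    log transform happens inside the model module); their row sets may differ
    when patients are typed for only one class.  ``occurrence`` and
    ``expressed`` are binary and share the union row index.
    """

    phbr_i: pd.DataFrame
    phbr_ii: pd.DataFrame
    occurrence: pd.DataFrame | None = None
    expressed: pd.DataFrame | None = None

    @property
    def mutations(self) -> pd.Index:
        return self.phbr_i.columns

    def patients_with_both(self) -> pd.Index:
        return self.phbr_i.index.intersection(self.phbr_ii.index)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (patient_id, mutation_id, class, phbr, occurred, expressed)."""
        frames = []
        for cls, mat in (("I", self.phbr_i), ("II", self.phbr_ii)):
            long = mat.stack().rename("phbr").reset_index()
            long.columns = ["patient_id", "mutation_id", "phbr"]
            long.insert(2, "class", cls)
            if self.occurrence is not None:
                occ = self.occurrence.stack()
                long["occurred"] = occ.reindex(
                    pd.MultiIndex.from_frame(long[["patient_id", "mutation_id"]])
                ).to_numpy()
            if self.expressed is not None:
                ex = self.expressed.stack()
                long["expressed"] = ex.reindex(
                    pd.MultiIndex.from_frame(long[["patient_id", "mutation_id"]])
                ).to_numpy()
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


def score_matrix(
    genotypes: Mapping[str, HLAGenotype],
    catalog: Sequence[DriverMutation],
    proteins: Mapping[str, str],
    backend: RankBackend,
    mhc_class: Literal["I", "II"],
    lengths: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Dense patients x mutations PHBR matrix for one class.

    Patients with incomplete typing for the class are excluded (they remain
    eligible for the other class).  Scores are computed by pooling every
    unique (peptide, molecule) pair across the cohort, taking per-molecule
    best ranks per mutation, then harmonic-mean aggregation over each
    patient's slots.
    """
    lengths = tuple(lengths) if lengths is not None else default_lengths(mhc_class)

    complete = {
        pid: gt for pid, gt in genotypes.items() if gt.is_complete(mhc_class)
    }
    if not complete:
        raise ValueError(f"no patient has complete class {mhc_class} typing")

    slot_sets = {pid: assemble_molecules(gt, mhc_class) for pid, gt in complete.items()}
    molecules: dict[str, MHCMolecule] = {}
    for slots in slot_sets.values():
        for mol in slots:
            molecules.setdefault(mol.name, mol)
    mol_names = sorted(molecules)
    mol_index = {name: k for k, name in enumerate(mol_names)}

    # enumerate windows once per mutation
    mut_windows: list[tuple[str, list[str]]] = []
    all_peptides: list[str] = []
    for mut in catalog:
        protein = proteins[mut.protein_id]
        mutant, altered = apply_mutation(protein, mut)
        win = extract_windows(mutant, altered, lengths, mhc_class, mut.mutation_id)
        peps = list(dict.fromkeys(win.peptides))
        if not peps:
            raise ValueError(f"{mut.mutation_id}: no scoreable windows")
        mut_windows.append((mut.mutation_id, peps))
        all_peptides.extend(peps)
    unique_peptides = list(dict.fromkeys(all_peptides))
    pep_index = {p: i for i, p in enumerate(unique_peptides)}

    # rank matrix: peptides x molecules
    R = np.empty((len(unique_peptides), len(mol_names)))
    for name in mol_names:
        R[:, mol_index[name]] = backend.rank(unique_peptides, molecules[name])

    # per-mutation best rank per molecule
    B = np.empty((len(mut_windows), len(mol_names)))
    for j, (_, peps) in enumerate(mut_windows):
        rows = [pep_index[p] for p in peps]
        B[j] = R[rows].min(axis=0)

    # per-patient harmonic mean over slots
    pids = sorted(complete)
    out = np.empty((len(pids), len(mut_windows)))
    for i, pid in enumerate(pids):
        cols = [mol_index[m.name] for m in slot_sets[pid]]
        slot_vals = B[:, cols]  # mutations x slots
        out[i] = slot_vals.shape[1] / (1.0 / slot_vals).sum(axis=1)

    return pd.DataFrame(out, index=pd.Index(pids, name="patient_id"),
                        columns=pd.Index([m for m, _ in mut_windows], name="mutation_id"))
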