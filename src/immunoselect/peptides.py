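"""Mutant peptide construction and the affinity-predictor contract.

Given a protein-level driver mutation we build the mutant protein, mark the
altered residues, and enumerate every peptide window of the configured
lengths that covers at least one altered residue (clipped at the protein
termini).  Default window lengths are 8-11 residues for MHC class I and 15
for class II.

Affinity prediction is a pluggable contract: any backend that maps a
(peptide, molecule) pair to a percentile rank in (0, 100] — lower rank =
better predicted presentation — can drive the scoring.  The in-repo
``SyntheticRankBackend`` is a deterministic stand-in for tools like
NetMHCpan: its marginal rank distribution over random peptides is uniform,
and each molecule carries a seeded anchor-residue preference so different
genotypes produce different presentation structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import stable_u32
from .hla import MHCMolecule

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
NONSTANDARD = set("XBZJUO*")

CLASS_I_LENGTHS = (8, 9, 10, 11)
CLASS_II_LENGTHS = (15,)


def default_lengths(mhc_class: Literal["I", "II"]) -> tuple[int, ...]:
    return CLASS_I_LENGTHS if mhc_class == "I" else CLASS_II_LENGTHS


class RefMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class DriverMutation:
    """A protein-level missense mutation or inframe indel.

    Positions are 1-based residue indices into the reference protein.  For a
    missense mutation ``ref``/``alt`` are single residues; an inframe
    insertion has empty ``ref`` (``alt`` inserted after ``position``), an
    inframe deletion has empty ``alt`` (``ref`` residues removed starting at
    ``position``).
    """

    mutation_id: str
    gene: str
    protein_id: str
    kind: Literal["missense", "inframe_indel"]
    position: int
    ref: str
    alt: str
    substitution_class: str = "other"  # C>T | T>C | other (DNA-level label)
    signature: str = "unassigned"

    def __post_init__(self):
        if self.kind == "missense":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("missense mutation must have single ref and alt residues")
            if self.ref == self.alt:
                raise ValueError("missense ref and alt residues must differ")
        elif self.kind == "inframe_indel":
            if bool(self.ref) == bool(self.alt):
                raise ValueError("inframe indel must be a pure insertion (empty ref) or deletion (empty alt)")
        else:
            raise ValueError(f"unknown mutation kind: {self.kind!r}")
        if self.position < 1:
            raise ValueError("position is a 1-based residue index")


def apply_mutation(protein: str, mutation: DriverMutation) -> tuple[str, frozenset[int]]:
    """Apply a mutation to a protein sequence.

    Returns ``(mutant_sequence, altered_positions)`` with altered positions as
    1-based indices into the *mutant* sequence.  Missense alters the single
    substituted position.  Insertions alter the inserted residues plus one
    flanking residue on each side; deletions alter the single junction
    residue (the residue now preceding the deletion site, or the first
    residue if the deletion was N-terminal).
    """
    pos0 = mutation.position - 1
    if mutation.kind == "missense":
        if pos0 >= len(protein):
            raise RefMismatchError(
                f"{mutation.mutation_id}: position {mutation.position} beyond protein length {len(protein)}"
            )
        found = protein[pos0]
        if found != mutation.ref:
            raise RefMismatchError(
                f"{mutation.mutation_id}: ref mismatch at position {mutation.position}: "
                f"expected {mutation.ref!r}, found {found!r}"
            )
        mutant = protein[:pos0] + mutation.alt + protein[pos0 + 1 :]
        return mutant, frozenset({mutation.position})

    if mutation.ref:  # deletion of len(ref) residues starting at position
        end0 = pos0 + len(mutation.ref)
        if end0 > len(protein):
            raise RefMismatchError(
                f"{mutation.mutation_id}: deletion runs past protein end ({end0} > {len(protein)})"
            )
        found = protein[pos0:end0]
        if found != mutation.ref:
            raise RefMismatchError(
                f"{mutation.mutation_id}: expected {mutation.ref!r} at position "
                f"{mutation.position}, found {found!r}"
            )
        mutant = protein[:pos0] + protein[end0:]
        # junction = the residue that now sits where the deleted block began
        junction = min(max(mutation.position, 1), len(mutant))
        return mutant, frozenset({junction})

    # insertion after `position`
    if pos0 >= len(protein):
        raise RefMismatchError(
            f"{mutation.mutation_id}: insertion anchor {mutation.position} beyond protein length"
        )
    mutant = protein[: pos0 + 1] + mutation.alt + protein[pos0 + 1 :]
    inserted = range(mutation.position + 1, mutation.position + 1 + len(mutation.alt))
    altered = set(inserted)
    altered.add(mutation.position)  # left flank
    right = mutation.position + len(mutation.alt) + 1
    if right <= len(mutant):
        altered.add(right)
    return mutant, frozenset(altered)


@dataclass(frozen=True)
class MutantWindows:
    mutation_id: str
    mhc_class: Literal["I", "II"]
    windows: tuple[tuple[str, int, int], ...]  # (peptide, 1-based start in mutant, length)

    @property
    def peptides(self) -> tuple[str, ...]:
        return tuple(w[0] for w in self.windows)


def extract_windows(
    mutant: str,
    altered_positions: Iterable[int],
    lengths: Sequence[int],
    mhc_class: Literal["I", "II"] = "I",
    mutation_id: str = "",
) -> MutantWindows:
    """All substrings of each configured length that contain an altered residue.

    Windows are clipped at the protein termini; duplicates (same peptide,
    start, length) cannot arise, but the same peptide sequence may appear at
    different starts and is kept — the scoring layer deduplicates by
    sequence.  Windows containing non-standard residues (X, B, Z, ...) are
    excluded with a logged count.
    """
    altered = sorted(set(int(p) for p in altered_positions))
    n = len(mutant)
    if not altered:
        raise ValueError("no altered positions supplied")
    if altered[0] < 1 or altered[-1] > n:
        raise ValueError(f"altered position outside sequence of length {n}: {altered}")
    out: list[tuple[str, int, int]] = []
    seen: set[tuple[int, int]] = set()
    n_dropped = 0
    for L in sorted(set(lengths)):
        for p in altered:
            lo = max(1, p - L + 1)
            hi = min(p, n - L + 1)
            for start in range(lo, hi + 1):
                if (start, L) in seen:
                    continue
                seen.add((start, L))
                pep = mutant[start - 1 : start - 1 + L]
                if NONSTANDARD.intersection(pep):
                    n_dropped += 1
                    continue
                out.append((pep, start, L))
    if n_dropped:
        logger.info("%s: excluded %d windows with non-standard residues", mutation_id, n_dropped)
    out.sort(key=lambda w: (w[2], w[1]))
    return MutantWindows(mutation_id, mhc_class, tuple(out))


# ---------------------------------------------------------------------------
# Rank tables
# ---------------------------------------------------------------------------

class RankBackend(Protocol):
    def rank(self, peptides: Sequence[str], molecule: MHCMolecule) -> np.ndarray: ...


def predict_ranks(
    peptides: Sequence[str],
    molecules: Sequence[MHCMolecule],
    backend: RankBackend,
) -> pd.DataFrame:
    """Score every (peptide, molecule) pair with the backend.

    Returns a long-format rank table with columns peptide, molecule, rank.
    Backend exceptions are re-raised with the offending context attached.
    """
    peptides = list(dict.fromkeys(peptides))  # dedupe, preserve order
    frames = []
    for mol in molecules:
        try:
            ranks = np.asarray(backend.rank(peptides, mol), dtype=float)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"rank backend failed for molecule {mol.name}") from exc
        if ranks.shape != (len(peptides),):
            raise RuntimeError(f"backend returned {ranks.shape} ranks for {len(peptides)} peptides")
        if np.any(~np.isfinite(ranks)) or np.any(ranks <= 0) or np.any(ranks > 100):
            bad = int(np.flatnonzero(~((ranks > 0) & (ranks <= 100)))[0])
            raise RuntimeError(
                f"backend rank out of (0, 100] for peptide {peptides[bad]!r}, molecule {mol.name}"
            )
        frames.append(pd.DataFrame({"peptide": peptides, "molecule": mol.name, "rank": ranks}))
    return pd.concat(frames, ignore_index=True)


def read_rank_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"peptide": str, "molecule": str})
    required = {"peptide", "molecule", "rank"}
    if not required.issubset(table.columns):
        raise ValueError(f"rank table needs columns {sorted(required)}")
    return validate_rank_table(table)


def validate_rank_table(table: pd.DataFrame) -> pd.DataFrame:
    ranks = pd.to_numeric(table["rank"], errors="coerce")
    bad = ~((ranks > 0) & (ranks <= 100))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"rank out of (0, 100] at line {line}")
    dup = table.duplicated(subset=["peptide", "molecule"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"duplicate (peptide, molecule) pair at line {line}")
    out = table.copy()
    out["rank"] = ranks
    return out


def write_rank_table(table: pd.DataFrame, path) -> None:
    validate_rank_table(table).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Synthetic rank backend
# ---------------------------------------------------------------------------

def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized SplitMix64 finalizer (uint64 in, uint64 out)."""
    with np.errstate(over="ignore"):
        z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def _hash_peptides(peptides: Sequence[str]) -> np.ndarray:
    """FNV-1a style content hash of each peptide, vectorized over peptides."""
    h = np.full(len(peptides), 0xCBF29CE484222325, dtype=np.uint64)
    prime = np.uint64(0x100000001B3)
    maxlen = max((len(p) for p in peptides), default=0)
    codes = np.zeros((len(peptides), maxlen), dtype=np.uint64)
    for i, p in enumerate(peptides):
        codes[i, : len(p)] = np.frombuffer(p.encode("ascii"), dtype=np.uint8)
    with np.errstate(over="ignore"):
        for col in range(maxlen):
            h = (h ^ codes[:, col]) * prime
    return h


@dataclass
class SyntheticRankBackend:
    """Deterministic synthetic percentile-rank predictor.

    The rank for (peptide, molecule) is ``100 * Phi(z)`` with

        z = rho * anchor(peptide, molecule) + sqrt(1 - rho^2) * Phi^-1(u)

    where ``u`` is an exact Uniform(0,1) hash of (peptide, molecule, seed)
    and ``anchor`` is a per-molecule, seeded preference over the residues at
    three anchor slots (second position, centre, C-terminus), standardized to
    mean 0 / variance 1 over random peptides.  Over random peptides the
    marginal rank distribution is uniform to within the smoothing of the
    anchor mixture (held inside a 1% Kolmogorov-Smirnov band in tests), while
    molecules with different anchor preferences rank the same peptides
    differently — so genotype structure propagates into PHBR structure.
    """

    seed: int = 0
    anchor_weight: float = 0.3
    _tables: dict = field(default_factory=dict, repr=False)

    def _anchor_table(self, molecule: MHCMolecule) -> np.ndarray:
        key = molecule.name
        if key not in self._tables:
            rng = np.random.default_rng(
                [int(self.seed) & 0x7FFFFFFF, stable_u32("anchor:" + key)]
            )
            w = rng.normal(size=(3, len(AMINO_ACIDS)))
            # standardize each slot over the 20 equiprobable residues
            w -= w.mean(axis=1, keepdims=True)
            w /= np.sqrt((w**2).mean(axis=1, keepdims=True))
            self._tables[key] = w / np.sqrt(3.0)
        return self._tables[key]

    def rank(self, peptides: Sequence[str], molecule: MHCMolecule) -> np.ndarray:
        peptides = list(peptides)
        if not peptides:
            return np.empty(0)
        w = self._anchor_table(molecule)
        anchor = np.empty(len(peptides))
        for i, pep in enumerate(peptides):
            a1, a2, a3 = pep[1], pep[len(pep) // 2], pep[-1]
            anchor[i] = (
                w[0, _AA_INDEX[a1]] + w[1, _AA_INDEX[a2]] + w[2, _AA_INDEX[a3]]
            )
        h = _hash_peptides(peptides)
        with np.errstate(over="ignore"):
            h = _splitmix64(
                h
                ^ np.uint64(stable_u32("mol:" + molecule.name))
                ^ (np.uint64(int(self.seed) & 0x7FFFFFFF) << np.uint64(32))
            )
        u = (h >> np.uint64(11)).astype(np.float64) * (2.0**-53)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        rho = self.anchor_weight
        z = rho * anchor + np.sqrt(1.0 - rho**2) * norm.ppf(u)
        ranks = 100.0 * norm.cdf(z)
        return np.maximum(ranks, 1e-8)


@dataclass
class TableRankBackend:
    """Serve ranks from a precomputed rank table; missing pairs are errors."""

    table: pd.DataFrame

    def __post_init__(self):
        self.table = validate_rank_table(self.table)
        self._lookup = self.table.set_index(["peptide", "molecule"])["rank"]

    def rank(self, peptides: Sequence[str], molecule: MHCMolecule) -> np.ndarray:
        out = np.empty(len(peptides))
        missing = []
        for i, pep in enumerate(peptides):
            try:
                out[i] = self._lookup[(pep, molecule.name)]
            except KeyError:
                missing.append((pep, molecule.name))
        if missing:
            shown = ", ".join(f"({p}, {m})" for p, m in missing[:10])
            raise KeyError(f"{len(missing)} missing (peptide, molecule) ranks; first: {shown}")
        return out
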