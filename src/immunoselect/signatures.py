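"""Mutational-signature sex ratios and substitution-class presentation.

Signature attribution matrices are consumed, not computed: the package takes
per-patient activity tables (and per-mutation signature labels) as given and
asks (a) whether any signature's activity differs between the sexes within a
tumor type, and (b) whether C>T / T>C driver mutations — the hallmarks of
the endogenous clock-like signatures — are presented differently from other
substitutions across a whole allele panel, independent of who carries them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .hla import MHCMolecule
from .peptides import DriverMutation, RankBackend, apply_mutation, default_lengths, extract_windows
from .stats import GroupComparison, bh_adjust, cliffs_d, mann_whitney_one_tailed


@dataclass
class SignatureSexRatio:
    tumor_type: str
    signature: str
    log2_ratio: float           # log2(male mean / female mean)
    p: float
    p_bh: float | None
    n_male: int
    n_female: int
    skipped: bool = False


def signature_sex_ratios(
    activities: pd.DataFrame,
    min_per_sex: int = 2,
    center: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Per (tumor_type, signature): log2 male/female activity ratio and test.

    The ratio uses group means by default (median selectable).  The one-tailed
    Mann-Whitney p is taken in the direction of the observed ratio, and BH
    adjustment runs across the full tumor-type x signature family.  Strata
    with fewer than ``min_per_sex`` patients of either sex are skipped with a
    flag; a zero female mean flags the ratio infinite.
    """
    sig_cols = [c for c in activities.columns if c.startswith("sig_")]
    if not sig_cols:
        raise ValueError("no signature activity columns (expected sig_* columns)")
    agg = np.mean if center == "mean" else np.median
    rows: list[SignatureSexRatio] = []
    for tt, grp in activities.groupby("tumor_type", sort=True):
        males = grp[grp["sex"] == "male"]
        females = grp[grp["sex"] == "female"]
        for col in sig_cols:
            sig = col[len("sig_"):]
            if len(males) < min_per_sex or len(females) < min_per_sex:
                rows.append(SignatureSexRatio(str(tt), sig, float("nan"), float("nan"),
                                              None, len(males), len(females), skipped=True))
                continue
            m, f = agg(males[col]), agg(females[col])
            ratio = float("inf") if f == 0 else float(np.log2(m / f)) if m > 0 else float("-inf")
            direction = "greater" if (np.isfinite(ratio) and ratio >= 0) or ratio == float("inf") else "less"
            _, p = mann_whitney_one_tailed(males[col], females[col], direction)
            rows.append(SignatureSexRatio(str(tt), sig, ratio, p, None,
                                          len(males), len(females)))
    tested = [r for r in rows if not r.skipped and np.isfinite(r.p)]
    if tested:
        for r, q in zip(tested, bh_adjust([r.p for r in tested])):
            r.p_bh = float(q)
    return pd.DataFrame([r.__dict__ for r in rows])


def driver_signature_fractions(labels: Sequence[str]) -> pd.Series:
    """Percentage of the driver set attributed to each signature (sums to 100)."""
    labels = ["unassigned" if not lb else str(lb) for lb in labels]
    if not labels:
        raise ValueError("empty driver catalog")
    counts = pd.Series(labels).value_counts().sort_index()
    return 100.0 * counts / counts.sum()


def substitution_class_presentation(
    catalog: Sequence[DriverMutation],
    proteins: Mapping[str, str],
    allele_panel: Sequence[MHCMolecule],
    backend: RankBackend,
    mhc_class: Literal["I", "II"],
    focal_classes: tuple[str, ...] = ("C>T", "T>C"),
    pooling: Literal["best_rank", "all_windows"] = "best_rank",
) -> GroupComparison:
    """Compare presentation of C>T / T>C drivers vs other substitutions.

    Scores are pooled per (mutation, allele) across the whole panel — every
    allele, not patient genotypes — as each allele's best rank over the
    mutation's windows (or every per-window rank with ``pooling=
    "all_windows"``).  The one-tailed alternative is "focal classes score
    higher" (presented more poorly); Cliff's d uses the same orientation.
    """
    if not allele_panel:
        raise ValueError("allele panel must be nonempty")
    focal_vals, other_vals = [], []
    missense = [m for m in catalog if m.kind == "missense"]
    for mut in missense:
        mutant, altered = apply_mutation(proteins[mut.protein_id], mut)
        win = extract_windows(mutant, altered, default_lengths(mhc_class), mhc_class, mut.mutation_id)
        peps = list(dict.fromkeys(win.peptides))
        sink = focal_vals if mut.substitution_class in focal_classes else other_vals
        for mol in allele_panel:
            ranks = np.asarray(backend.rank(peps, mol), dtype=float)
            if pooling == "best_rank":
                sink.append(float(ranks.min()))
            else:
                sink.extend(ranks.tolist())
    if not focal_vals or not other_vals:
        return GroupComparison("+".join(focal_classes), "other", len(focal_vals),
                               len(other_vals), float("nan"), float("nan"),
                               float("nan"), float("nan"), float("nan"))
    x, y = np.asarray(focal_vals), np.asarray(other_vals)
    u, p = mann_whitney_one_tailed(x, y, "greater")
    return GroupComparison(
        "+".join(focal_classes), "other", x.size, y.size,
        float(np.median(x)), float(np.median(y)), u, p, cliffs_d(x, y),
    )


def read_allele_panel(path) -> list[MHCMolecule]:
    """Allele panel file: one molecule per line (class II heterodimers as alpha/beta)."""
    panel = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                panel.append(MHCMolecule.parse(line))
    return panel
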