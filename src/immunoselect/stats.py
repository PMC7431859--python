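"""Group-level statistics for presentation-score comparisons.

One-tailed Mann-Whitney U (exact enumeration for small samples, midrank /
continuity-corrected normal approximation otherwise), Cliff's d effect
sizes, Benjamini-Hochberg adjustment, Fisher's exact test, pooled
group-vs-group score comparisons, and the mutation-reassignment permutation
null that breaks the genotype-mutation linkage while preserving per-mutation
occurrence counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MAX_TOTAL = 12  # exact Mann-Whitney enumeration up to n + m = 12


def mann_whitney_one_tailed(
    x: Sequence[float], y: Sequence[float], alternative: Literal["greater", "less"]
) -> tuple[float, float]:
    """One-tailed Mann-Whitney U test of ``x`` against ``y``.

    ``alternative="greater"`` tests whether x tends to exceed y.  Uses exact
    enumeration when n + m <= 12 and there are no ties, otherwise the normal
    approximation on midranks with tie correction and continuity correction.
    Returns ``(U, p)`` with U the statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= EXACT_MAX_TOTAL and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def cliffs_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's d = (#{x_i > y_j} - #{x_i < y_j}) / (n*m), via sorting (O(n log n))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()   # y_j <  x_i
    not_less = np.searchsorted(ys, x, side="right").sum()  # y_j <= x_i
    less = x.size * y.size - not_less                      # y_j >  x_i
    return float((greater - less) / (x.size * y.size))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(
    table: Sequence[Sequence[int]], alternative: Literal["two-sided", "greater", "less"] = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 count table.

    Returns the sample odds ratio ``(a*d)/(b*c)`` (inf with a zero in b or c,
    NaN for a degenerate zero margin) and the exact hypergeometric p-value.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be a 2x2 array of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan"), 1.0  # degenerate margin
    (a, b), (c, d) = t
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = float(a * d) / float(b * c)
    _, p = sps.fisher_exact(t, alternative=alternative)
    return odds, float(p)


# ---------------------------------------------------------------------------
# Pooled observed-score comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """A one-tailed comparison of pooled observed scores between two groups.

    The pooling unit is the (patient, mutation) observed-score pair.  The
    focal group is listed first; ``p`` tests ``focal greater`` (higher PHBR =
    worse presentation).  Cliff's d follows the same orientation: d > 0 when
    the focal group tends to have *higher* values.
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_one_tailed: float
    cliffs_d: float
    p_bh: float | None = None

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a, "group_b": self.group_b,
            "n_a": self.n_a, "n_b": self.n_b,
            "median_a": self.median_a, "median_b": self.median_b,
            "U": self.u_statistic, "p_one_tailed": self.p_one_tailed,
            "cliffs_d": self.cliffs_d, "p_bh": self.p_bh,
        }


def age_categories(
    ages: pd.Series,
    lower_pct: float = 30.0,
    upper_pct: float = 70.0,
    tumor_type: pd.Series | None = None,
) -> pd.Series:
    """Label patients younger/older by age percentiles; the middle band is NaN.

    With ``tumor_type`` given, thresholds are computed within each tumor type
    rather than pan-cohort.
    """
    def _cat(a: pd.Series) -> pd.Series:
        lo, hi = np.percentile(a.dropna(), [lower_pct, upper_pct])
        out = pd.Series(pd.NA, index=a.index, dtype="object")
        out[a < lo] = "younger"
        out[a > hi] = "older"
        return out

    if tumor_type is None:
        return _cat(ages)
    return ages.groupby(tumor_type, group_keys=False).apply(_cat)


def pooled_observed_scores(
    long_scores: pd.DataFrame,
    grouping: pd.Series,
    mhc_class: Literal["I", "II"],
    require_expressed: bool = True,
) -> dict[str, np.ndarray]:
    """Pool observed (optionally expressed-only) scores per group level.

    ``long_scores`` is the long-format PHBR table; ``grouping`` maps
    patient_id -> group label (NaN labels are dropped).  Patients with no
    retained (observed, expressed) driver mutations contribute nothing.
    """
    t = long_scores[long_scores["class"] == mhc_class]
    mask = t["occurred"].astype(bool)
    if require_expressed and "expressed" in t.columns:
        mask &= t["expressed"].astype(bool)
    t = t[mask]
    labels = t["patient_id"].map(grouping)
    t = t[labels.notna()]
    labels = labels[labels.notna()]
    all_levels = sorted({str(lv) for lv in grouping.dropna().unique()})
    return {lv: t.loc[labels.astype(str) == lv, "phbr"].to_numpy() for lv in all_levels}


def compare_observed_scores(
    long_scores: pd.DataFrame,
    grouping: pd.Series,
    mhc_class: Literal["I", "II"],
    require_expressed: bool = True,
    focal_order: Sequence[str] | None = None,
) -> list[GroupComparison]:
    """All pairwise one-tailed comparisons of pooled observed scores.

    Each pair (a, b) is ordered by ``focal_order`` (or sorted labels) and
    tests "a greater" (focal group scores higher = presented worse).
    BH adjustment is applied across the pairwise family.  Pairs with an
    empty group are flagged missing (NaN statistics).
    """
    pools = pooled_observed_scores(long_scores, grouping, mhc_class, require_expressed)
    levels = [lv for lv in (focal_order or sorted(pools))] if focal_order else sorted(pools)
    out: list[GroupComparison] = []
    for a, b in combinations(levels, 2):
        xa, xb = pools.get(a, np.empty(0)), pools.get(b, np.empty(0))
        if xa.size == 0 or xb.size == 0:
            out.append(GroupComparison(a, b, xa.size, xb.size,
                                       float("nan"), float("nan"),
                                       float("nan"), float("nan"), float("nan")))
            continue
        u, p = mann_whitney_one_tailed(xa, xb, "greater")
        out.append(GroupComparison(
            a, b, int(xa.size), int(xb.size),
            float(np.median(xa)), float(np.median(xb)),
            u, p, cliffs_d(xa, xb),
        ))
    valid = [c for c in out if np.isfinite(c.p_one_tailed)]
    if valid:
        adj = bh_adjust([c.p_one_tailed for c in valid])
        for c, q in zip(valid, adj):
            c.p_bh = float(q)
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in comparisons])


# ---------------------------------------------------------------------------
# Mutation-reassignment permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    observed: float
    null_sample: np.ndarray
    ci_low: float
    ci_high: float
    outside_ci: bool
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.observed,
            "null_mean": float(np.mean(self.null_sample)),
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "outside_ci": self.outside_ci, "n_perm": self.n_perm, "seed": self.seed,
        }


def _group_statistic(
    scores: np.ndarray,
    occurrence: np.ndarray,
    labels: np.ndarray,
    focal: str,
    reference: str,
    statistic: Literal["median", "mean"],
) -> float:
    agg = np.median if statistic == "median" else np.mean
    occ = occurrence.astype(bool)
    focal_vals = scores[labels == focal][occ[labels == focal]]
    ref_vals = scores[labels == reference][occ[labels == reference]]
    if focal_vals.size == 0 or ref_vals.size == 0:
        return float("nan")
    return float(agg(focal_vals) - agg(ref_vals))


def permutation_null(
    scores: pd.DataFrame,
    occurrence: pd.DataFrame,
    grouping: pd.Series,
    focal: str,
    reference: str,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: Literal["median", "mean"] = "median",
) -> PermutationNull:
    """Mutation-reassignment null for the focal-minus-reference score gap.

    The observed statistic is the difference of group medians (or means) of
    pooled observed scores.  Each permutation reassigns every patient's
    mutation set to a uniformly re-drawn patient (a random bijection of
    patients, so per-mutation occurrence counts and the cohort's genotype
    multiset are both preserved) and recomputes the statistic from the
    reassigned patients' PHBR rows.  The 99% CI is the empirical 0.5% / 99.5%
    quantile pair of the null sample.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    common = scores.index.intersection(occurrence.index)
    labels = grouping.reindex(common)
    keep = labels.notna().to_numpy()
    S = scores.loc[common].to_numpy()[keep]
    Y = occurrence.loc[common, scores.columns].to_numpy()[keep]
    lab = labels.to_numpy(dtype=object)[keep].astype(str)
    for lv in (focal, reference):
        if lv not in set(lab):
            raise ValueError(f"degenerate grouping: level {lv!r} has no patients")

    observed = _group_statistic(S, Y, lab, focal, reference, statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n = S.shape[0]
    for k in range(n_perm):
        perm = rng.permutation(n)
        # patient perm[i]'s mutation set is reassigned to patient i's genotype
        null[k] = _group_statistic(S, Y[perm], lab, focal, reference, statistic)
    lo, hi = np.quantile(null, [0.005, 0.995], method="inverted_cdf")
    outside = bool(observed < lo or observed > hi)
    return PermutationNull(observed, null, float(lo), float(hi), outside, n_perm, seed)
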