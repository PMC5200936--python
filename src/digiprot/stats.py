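"""Nonparametric cross-group inference.

Lineage-level comparisons of protein length (and of exon number / exon
length) use the rank-based Kruskal-Wallis test rather than ANOVA: the
distributions are heavily right-skewed, so a test on ranks is the robust
choice.  A significant omnibus test is followed by pairwise two-sample
Kruskal-Wallis tests (on a pair of groups this is the tie-corrected rank-sum
chi-square test), Benjamini-Hochberg FDR adjustment over all pairs, and a
compact letter display in which two groups share a letter exactly when their
adjusted pairwise p-value is at or above alpha.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class DegenerateDataError(ValueError):
    """Test undefined on this input (e.g. all paired differences zero)."""


@dataclass
class KWResult:
    H: float
    df: int
    p: float


@dataclass
class LetterDisplay:
    letters: dict[str, str]  # group -> letter string, e.g. "ab"
    alpha: float


@dataclass
class WilcoxonResult:
    statistic: float
    p: float
    paired: bool


def kruskal_wallis(*groups) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test across two or more samples."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group must be non-empty")
    pooled = np.concatenate(arrays)
    df = len(arrays) - 1
    if np.all(pooled == pooled[0]):
        # every observation identical: no evidence of any difference
        return KWResult(H=0.0, df=df, p=1.0)
    H, p = sps.kruskal(*arrays)
    return KWResult(H=float(H), df=df, p=float(p))


def pairwise_posthoc(
    samples: dict[str, np.ndarray] | dict[str, list], adjust: str = "BH"
) -> pd.DataFrame:
    """Pairwise two-sample Kruskal-Wallis tests with BH-FDR adjustment.

    Returns a tidy frame (group_a, group_b, p_raw, p_adj) over all
    g(g-1)/2 unordered pairs.
    """
    if adjust != "BH":
        raise ValueError(f"unsupported adjustment {adjust!r}")
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pairs = list(itertools.combinations(names, 2))
    raw = [kruskal_wallis(samples[a], samples[b]).p for a, b in pairs]
    _, adj, _, _ = multipletests(raw, method="fdr_bh")
    return pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_adj": adj,
        }
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    _, adj, _, _ = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")
    return adj


_LETTER_POOL = string.ascii_lowercase + string.ascii_uppercase


def compact_letters(
    pairwise: pd.DataFrame,
    alpha: float = 0.05,
    order: list[str] | None = None,
) -> LetterDisplay:
    """Compact letter display via the insert-and-absorb algorithm.

    ``pairwise`` is the frame from :func:`pairwise_posthoc` (columns
    group_a, group_b, p_adj).  Two groups share at least one letter iff
    their adjusted p >= alpha.  Groups are processed in ``order`` when
    given (conventionally descending median), otherwise in first-appearance
    order; letters are assigned in that order.

    The algorithm starts with one letter covering everything and, for each
    significantly different pair found sharing a letter, duplicates the
    letter into two copies with one endpoint deleted from each, then absorbs
    any letter column whose group set is a subset of another's.  The result
    is irredundant (no column subset of another) though not always the
    global minimum letter count.
    """
    if order is None:
        seen: list[str] = []
        for col in ("group_a", "group_b"):
            for g in pairwise[col]:
                if g not in seen:
                    seen.append(g)
        order = seen
    idx = {g: i for i, g in enumerate(order)}
    sig_pairs = set()
    for _, row in pairwise.iterrows():
        a, b = row["group_a"], row["group_b"]
        if a not in idx or b not in idx:
            raise ValueError(f"pair ({a}, {b}) not covered by the group order")
        if row["p_adj"] < alpha:
            sig_pairs.add(frozenset((a, b)))

    # columns: sets of groups sharing a letter
    columns: list[set[str]] = [set(order)]
    for pair in sorted(sig_pairs, key=lambda fs: sorted(idx[g] for g in fs)):
        a, b = sorted(pair, key=lambda g: idx[g])
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop empties, strict subsets of another column, duplicates
        columns = []
        for col in new_columns:
            if not col:
                continue
            if any(col < other for other in new_columns):
                continue
            if col not in columns:
                columns.append(col)

    # ensure every group has a letter (isolated after deletions)
    lettered = set().union(*columns) if columns else set()
    for g in order:
        if g not in lettered:
            columns.append({g})

    # letters assigned by first (highest-ranked) member
    columns.sort(key=lambda col: min(idx[g] for g in col))
    if len(columns) > len(_LETTER_POOL):
        raise ValueError("too many letter columns to label")
    letters = {g: "" for g in order}
    for letter, col in zip(_LETTER_POOL, columns):
        for g in order:
            if g in col:
                letters[g] += letter
    return LetterDisplay(letters=letters, alpha=alpha)


def wilcoxon(sample_a, sample_b, paired: bool = False) -> WilcoxonResult:
    """Two-sided Wilcoxon test: signed-rank when paired, rank-sum otherwise.

    Exact p for n <= 25 (no ties), normal approximation with continuity
    correction beyond that.  Paired zero differences are dropped before
    ranking; all-zero differences raise :class:`DegenerateDataError`.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        d = a - b
        d = d[d != 0]
        if d.size == 0:
            raise DegenerateDataError("all paired differences are zero")
        use_exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
        res = sps.wilcoxon(
            a, b, zero_method="wilcox", correction=not use_exact,
            alternative="two-sided", method="exact" if use_exact else "approx",
        )
        return WilcoxonResult(statistic=float(res.statistic), p=float(res.pvalue), paired=True)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (a.size <= 25 and b.size <= 25) else "asymptotic"
    if method == "exact" and np.intersect1d(a, b).size == 0 and (
        np.unique(a).size == a.size and np.unique(b).size == b.size
    ):
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return WilcoxonResult(statistic=float(res.statistic), p=float(res.pvalue), paired=False)
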