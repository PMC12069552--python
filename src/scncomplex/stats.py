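"""Nonparametric group comparisons used on binding and intensity data.

Groups of per-nucleus measurements are compared with the Kruskal-Wallis
rank test followed by Dunn's pairwise post hoc z-tests; p-values are
adjusted by the Benjamini-Hochberg step-up and summarised as compact letter
displays (groups sharing a letter are not significantly different).
Proportions (e.g. division frequencies under two treatments) are compared
with Pearson's chi-squared test with Yates' continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupLetterAssignment",
    "kruskal_wallis",
    "dunn_bh",
    "compact_letters",
    "chi2_yates",
]


@dataclass
class GroupLetterAssignment:
    """Compact letter display with the adjusted pairwise p-value matrix."""

    letters: dict[str, str]
    p_matrix: pd.DataFrame
    alpha: float


def _check_groups(samples: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for label, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 1:
            raise ValueError(f"group {label!r} is empty")
        out[str(label)] = arr
    return out


def kruskal_wallis(samples: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value."""
    groups = _check_groups(samples)
    arrays = list(groups.values())
    if len(np.unique(np.concatenate(arrays))) == 1:
        warnings.warn("all values identical across groups; H = 0, p = 1")
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _dunn_pvalues(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Two-sided Dunn z-test p-values with tie correction, unadjusted."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    pos = 0
    for g in labels:
        k = groups[g].size
        mean_ranks[g] = ranks[pos : pos + k].mean()
        pos += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    p = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt(base_var * (1.0 / groups[g1].size + 1.0 / groups[g2].size))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        pval = 2.0 * sps.norm.sf(abs(z))
        p.loc[g1, g2] = p.loc[g2, g1] = pval
    return p


def compact_letters(p_matrix: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a pairwise p-matrix.

    Two groups share a letter iff their (adjusted) pairwise p >= alpha.
    """
    labels = list(p_matrix.index)
    # letter sets start as one set containing everything; each significant
    # pair splits the sets it co-occupies (insert), duplicates are absorbed
    sets: list[set[str]] = [set(labels)]
    for g1, g2 in combinations(labels, 2):
        if p_matrix.loc[g1, g2] < alpha:
            for s in [s for s in sets if g1 in s and g2 in s]:
                sets.remove(s)
                s1 = s - {g2}
                s2 = s - {g1}
                for cand in (s1, s2):
                    if cand and not any(cand <= other for other in sets):
                        sets.append(cand)
                sets = [s for s in sets if not any(s < o for o in sets if o is not s)]
    sets.sort(key=lambda s: min(labels.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in labels}
    for i, s in enumerate(sets):
        for g in labels:
            if g in s:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def dunn_bh(
    samples: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupLetterAssignment:
    """Dunn's post hoc test with Benjamini-Hochberg adjustment and letters."""
    groups = _check_groups(samples)
    raw = _dunn_pvalues(groups)
    labels = list(raw.index)
    pairs = list(combinations(labels, 2))
    flat = np.array([raw.loc[a, b] for a, b in pairs])
    adjusted = multipletests(flat, method="fdr_bh")[1]
    adj = raw.copy()
    for (a, b), p in zip(pairs, adjusted):
        adj.loc[a, b] = adj.loc[b, a] = p
    return GroupLetterAssignment(
        letters=compact_letters(adj, alpha=alpha), p_matrix=adj, alpha=alpha
    )


def chi2_yates(table) -> tuple[float, float]:
    """Pearson's chi-squared with Yates' continuity correction on a 2x2 table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=True)
    return float(stat), float(p)
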