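"""Independent oracles used across the test suite.

Everything here recomputes quantities by a different route from the package:
raw CSV table lookups for descriptors, subset-enumeration and permutation
averaging for Shapley values, all-pairs counting for ROC AUC. The frozen
evaluation-table rows carry published confusion counts and the metric values
printed alongside them (printed values are truncated to the shown decimals,
so the comparison tolerance is one unit of the last printed digit).
"""
from __future__ import annotations

from importlib import resources
from itertools import combinations, permutations
from math import factorial

import numpy as np
import pandas as pd

# ---------------------------------------------------------------- descriptors

def read_raw_table(fname: str) -> pd.DataFrame:
    """Read a bundled scale CSV directly, bypassing the package loader."""
    ref = resources.files("tcrh.tables") / fname
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#").set_index("residue")


def brute_force_family(seq: str, fname: str) -> np.ndarray:
    """Per-dimension mean via explicit per-residue dict lookups."""
    df = read_raw_table(fname)
    out = []
    for col in df.columns:
        lookup = df[col].to_dict()
        out.append(sum(lookup[a] for a in seq) / len(seq))
    return np.array(out)


# ---------------------------------------------------------------- shapley

def coalition_value(score_fn, x: np.ndarray, background: np.ndarray,
                    subset: tuple) -> float:
    """v(S): mean score over background rows with S replaced by x's values."""
    masked = background.copy()
    for j in subset:
        masked[:, j] = x[j]
    return float(np.mean(score_fn(masked)))


def shapley_subset_formula(score_fn, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by direct subset enumeration:
    phi_i = sum_S |S|!(M-|S|-1)!/M! * (v(S u {i}) - v(S))."""
    M = x.size
    values = {}
    for r in range(M + 1):
        for S in combinations(range(M), r):
            values[S] = coalition_value(score_fn, x, background, S)
    phi = np.zeros(M)
    for i in range(M):
        others = [j for j in range(M) if j != i]
        for r in range(M):
            for S in combinations(others, r):
                w = factorial(r) * factorial(M - r - 1) / factorial(M)
                phi[i] += w * (values[tuple(sorted(S + (i,)))] - values[S])
    return phi


def shapley_permutation_average(score_fn, x: np.ndarray,
                                background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by averaging marginal contributions over all M!
    orderings (tractable for small M)."""
    M = x.size
    cache = {}

    def v(subset):
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = coalition_value(score_fn, x, background, key)
        return cache[key]

    phi = np.zeros(M)
    for perm in permutations(range(M)):
        seen = []
        for i in perm:
            phi[i] += v(seen + [i]) - v(seen)
            seen.append(i)
    return phi / factorial(M)


# ---------------------------------------------------------------- ROC

def auc_pair_counting(scores, y) -> float:
    """All positive-negative pair comparison, ties counted 1/2."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ------------------------------------------------- published evaluation rows
# (model, TP, TN, FP, FN, accuracy, precision, recall, specificity, f1)
# as printed; printed values are truncated to the shown decimals.
PUBLISHED_ROWS = [
    ("XGB", 31859, 654, 21817, 104, "0.597", "0.593", "0.996", "0.029", "0.744"),
    ("GBT", 31248, 2329, 20142, 715, "0.617", "0.608", "0.977", "0.104", "0.749"),
    ("RF", 31963, 0, 22471, 0, "0.587", "0.587", "1.00", "0.0", "0.739"),
    ("SVM", 30403, 14593, 7878, 1560, "0.826", "0.794", "0.951", "0.649", "0.865"),
    ("TCR-HE", 29567, 18297, 4174, 2396, "0.879", "0.876", "0.925", "0.814", "0.9"),
    ("TCR-Hb", 18760, 28780, 766, 2994, "0.93", "0.96", "0.86", "0.97", "0.91"),
    ("TCR-HbE", 29570, 19143, 3328, 2393, "0.89", "0.898", "0.92", "0.85", "0.91"),
    ("TCR-RS", 18382, 28771, 691, 3045, "0.93", "0.96", "0.86", "0.98", "0.91"),
]


def assert_matches_printed(computed: float, printed: str) -> None:
    """Printed values are truncated to their decimals; accept one last-digit ulp."""
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    assert abs(computed - float(printed)) < 10.0 ** (-decimals), (
        f"computed {computed!r} vs printed {printed!r}")
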