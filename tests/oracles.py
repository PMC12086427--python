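"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written the slow, obvious way (explicit loops, library
statistics calls) and deliberately shares no code with the package
internals beyond numpy/scipy.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def pairwise_pattern_correlations(data: np.ndarray) -> np.ndarray:
    """T x T Pearson correlations via an explicit pairwise loop."""
    T = data.shape[0]
    r = np.eye(T)
    for i in range(T):
        for j in range(i + 1, T):
            r[i, j] = r[j, i] = stats.pearsonr(data[i], data[j]).statistic
    return r


def fit_score(data: np.ndarray, boundaries) -> float:
    """Mean correlation of each timepoint with its state's mean template.

    Patterns are z-scored across channels before templates are formed, as in
    the implementation under test.
    """
    data = np.asarray(data, dtype=float)
    z = (data - data.mean(1, keepdims=True)) / data.std(1, keepdims=True)
    T = data.shape[0]
    edges = [0, *sorted(int(b) for b in boundaries), T]
    total = 0.0
    for i in range(len(edges) - 1):
        seg = z[edges[i]: edges[i + 1]]
        template = seg.mean(axis=0)
        for row in seg:
            if np.std(template) == 0:
                continue
            total += stats.pearsonr(row, template).statistic
    return total / T


def tdistance(data: np.ndarray, boundaries) -> float:
    """Pooled two-sample t between within-state and adjacent-state pair pools."""
    r = pairwise_pattern_correlations(np.asarray(data, dtype=float))
    T = data.shape[0]
    edges = [0, *sorted(int(b) for b in boundaries), T]
    state = np.zeros(T, dtype=int)
    for s, b in enumerate(edges[1:-1], start=1):
        state[b:] = s
    within, between = [], []
    for i in range(T):
        for j in range(i + 1, T):
            if state[i] == state[j]:
                within.append(r[i, j])
            elif abs(state[i] - state[j]) == 1:
                between.append(r[i, j])
    return stats.ttest_ind(within, between, equal_var=True).statistic


def window_cross_correlation(data: np.ndarray, index: int, h: int) -> float:
    """Mean pre x post pattern correlation via two explicit loops."""
    vals = []
    for i in range(index - h, index):
        for j in range(index, index + h):
            vals.append(stats.pearsonr(data[i], data[j]).statistic)
    return float(np.mean(vals))


def best_boundary_matching(true_b, est_b, tol) -> int:
    """Maximum number of one-to-one boundary matches within tolerance."""
    true_b, est_b = list(true_b), list(est_b)
    best = 0
    k = min(len(true_b), len(est_b))
    for subset in itertools.combinations(range(len(true_b)), k):
        for perm in itertools.permutations(range(len(est_b)), k):
            n = sum(
                abs(true_b[subset[i]] - est_b[perm[i]]) <= tol for i in range(k)
            )
            best = max(best, n)
    return best
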