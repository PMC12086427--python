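"""Pattern change around state boundaries relative to mid-state baseline.

For each boundary, every timepoint pattern in the 2 s before the boundary is
correlated with every timepoint pattern in the 2 s after it, and the
correlations are averaged to one value per boundary.  The median across
boundaries (medians resist the skew of correlation distributions) is
compared with the same quantity computed at state midpoints, which absorbs
individual differences in overall temporal autocorrelation::

    delta = median(boundary window correlations) - median(mid-state window correlations)

Negative delta means the pattern changes more sharply at boundaries than
within states, i.e. boundaries are *distinct*.

The module also provides the within-event similarity test: whether pattern
similarity within (behaviorally defined) events exceeds a duration-preserving
event-shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError
from .gsbs import StateSegmentation, _prefix2d, _block, pattern_correlation_matrix

__all__ = [
    "DistinctivenessResult",
    "window_cross_correlation",
    "boundary_distinctiveness",
    "within_event_similarity_test",
]


@dataclass
class DistinctivenessResult:
    per_boundary_corr: np.ndarray
    boundary_median: float
    midstate_corr: np.ndarray
    midstate_median: float
    delta: float
    halfwidth_s: float
    n_excluded_edges: int
    n_short_states: int = 0

    def to_row(self) -> dict:
        return {
            "boundary_median": self.boundary_median,
            "midstate_median": self.midstate_median,
            "delta": self.delta,
            "n_boundaries_used": int(self.per_boundary_corr.size),
            "n_excluded_edges": self.n_excluded_edges,
            "n_short_states": self.n_short_states,
        }


def window_cross_correlation(
    data: np.ndarray, index: int, halfwidth_samples: int
) -> float:
    """Mean pre x post pattern correlation around one sample index.

    The pre window is ``[index - halfwidth, index)`` and the post window
    ``[index, index + halfwidth)`` (the boundary sample itself belongs to the
    post window, consistent with the half-open boundary convention).  The
    value is the mean over all (pre, post) timepoint pairs of the Pearson
    correlation between their spatial patterns.
    """
    data = np.asarray(data, dtype=float)
    T = data.shape[0]
    index = int(index)
    h = int(halfwidth_samples)
    if h < 1:
        raise ValueError("halfwidth_samples must be >= 1")
    if index - h < 0 or index + h > T:
        raise IndexError(
            f"window [{index - h}, {index + h}) out of range for T={T}"
        )
    window = data[index - h: index + h]
    r = pattern_correlation_matrix(window)  # raises on zero-variance patterns
    return float(r[:h, h:].mean())


def boundary_distinctiveness(
    data: np.ndarray,
    seg: StateSegmentation,
    halfwidth_s: float = 2.0,
) -> DistinctivenessResult:
    """Median boundary-window correlation minus mid-state baseline.

    ``data`` is the time x channel matrix the segmentation was fit on.  The
    halfwidth (default 2 s; ~10 samples at 5.12 Hz, rounded to the nearest
    sample) defines both windows.  Boundaries whose windows would cross the
    recording edges are excluded and counted; states shorter than twice the
    halfwidth contribute no baseline sample, which guarantees baseline
    windows never straddle a boundary.
    """
    data = np.asarray(data, dtype=float)
    T = data.shape[0]
    if T != seg.T:
        raise ValueError("data length does not match segmentation T")
    h = max(int(round(halfwidth_s * seg.sampling_rate_hz)), 1)

    per_boundary = []
    n_excluded = 0
    for b in seg.boundaries:
        if b - h < 0 or b + h > T:
            n_excluded += 1
            continue
        per_boundary.append(window_cross_correlation(data, int(b), h))
    if not per_boundary:
        raise DegenerateDataError("no boundary with full windows inside the recording")

    edges = np.concatenate(([0], seg.boundaries, [T]))
    midstate = []
    n_short = 0
    for i in range(len(edges) - 1):
        s, e = int(edges[i]), int(edges[i + 1])
        if e - s < 2 * h:
            n_short += 1
            continue
        mid = (s + e) // 2
        if mid - h < 0 or mid + h > T:
            n_excluded += 1
            continue
        midstate.append(window_cross_correlation(data, mid, h))
    if not midstate:
        raise DegenerateDataError("no state long enough for a mid-state baseline")

    per_boundary = np.asarray(per_boundary)
    midstate = np.asarray(midstate)
    bmed = float(np.median(per_boundary))
    mmed = float(np.median(midstate))
    return DistinctivenessResult(
        per_boundary_corr=per_boundary,
        boundary_median=bmed,
        midstate_corr=midstate,
        midstate_median=mmed,
        delta=bmed - mmed,
        halfwidth_s=float(halfwidth_s),
        n_excluded_edges=n_excluded,
        n_short_states=n_short,
    )


def within_event_similarity_test(
    data: np.ndarray,
    event_boundaries,
    n_shuffles: int = 1000,
    seed: int | None = None,
) -> tuple[float, np.ndarray, float]:
    """Mean within-event pattern similarity against an event-shuffle null.

    The observed statistic is the mean pattern correlation over all timepoint
    pairs falling inside the same event.  The null shuffles the order of the
    events while preserving their durations and recomputes the statistic;
    ``p`` is the fraction of null values at least as large as the observed.

    Returns ``(observed, null_samples, p)``.
    """
    data = np.asarray(data, dtype=float)
    T = data.shape[0]
    event_boundaries = np.asarray(event_boundaries, dtype=int)
    if event_boundaries.size < 1:
        raise DegenerateDataError("need >= 2 events")
    if event_boundaries.min() <= 0 or event_boundaries.max() >= T:
        raise ValueError("event boundaries must lie strictly inside (0, T)")
    r = pattern_correlation_matrix(data)
    p2 = _prefix2d(r)

    def within_mean(edges: np.ndarray) -> float:
        total, count = 0.0, 0
        for i in range(len(edges) - 1):
            s, e = int(edges[i]), int(edges[i + 1])
            length = e - s
            if length >= 2:
                total += (_block(p2, s, e, s, e) - length) / 2.0
                count += length * (length - 1) // 2
        if count == 0:
            raise DegenerateDataError("no within-event timepoint pairs")
        return total / count

    edges = np.concatenate(([0], event_boundaries, [T]))
    observed = within_mean(edges)
    durations = np.diff(edges)
    rng = np.random.default_rng(seed)
    null = np.empty(int(n_shuffles))
    for i in range(int(n_shuffles)):
        perm = rng.permutation(durations)
        null[i] = within_mean(np.concatenate(([0], np.cumsum(perm))))
    p = float(np.mean(null >= observed))
    return float(observed), null, p
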