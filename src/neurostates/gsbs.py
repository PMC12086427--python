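"""Greedy state boundary search (GSBS) on a single subject's time series.

The algorithm treats each timepoint as a spatial pattern (one value per
channel) and iteratively places state boundaries so as to maximize the mean
Pearson correlation between every timepoint's pattern and the mean pattern
("state template") of the state it belongs to.  After each placement,
existing boundaries may be fine-tuned by one-sample shifts.  Model selection
uses the *t-distance*: a two-sample t-statistic separating the distribution
of pattern correlations for timepoint pairs *within* a state from pairs in
temporally *adjacent* states.  Because slow signal drifts make very small
state counts spuriously attractive, the selected state count is the first
t-distance peak at or above a minimum (default 15 states).

Implementation notes
--------------------
Patterns are z-scored across channels once (Pearson correlation is invariant
to this per-pattern affine transform).  With z-scored patterns the sum of
correlations of a state's timepoints with the state's mean template has the
closed form ``||S|| / sqrt(C)`` where ``S`` is the sum of the state's
z-scored patterns and ``C`` the channel count.  Candidate placements are
therefore scored from cumulative sums in O(C) each, and the full greedy fit
to ``k_max`` states costs O(k_max * T * C).  The t-distance curve is computed
from 2-D prefix sums over the T x T pattern-correlation matrix, O(k) per
candidate state count after an O(T^2) setup.
"""

from __future__ import annotations

import bisect
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import DegenerateDataError
from .recording import Recording

__all__ = [
    "StateSegmentation",
    "GSBSResult",
    "pattern_correlation_matrix",
    "fit_gsbs",
    "tdistance",
    "select_k",
    "segment_subject",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class StateSegmentation:
    """Boundary locations and model-selection diagnostics for one subject.

    ``boundaries`` are 0-based sample indices with the half-open convention:
    boundary ``b`` means the state change occurs between samples ``b - 1``
    and ``b``.  ``selected_k`` states correspond to ``selected_k - 1``
    boundaries.
    """

    boundaries: np.ndarray
    selected_k: int
    tdistance_curve: dict[int, float]
    T: int
    sampling_rate_hz: float
    subject_id: str = "unknown"
    selection_warning: bool = False

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if self.boundaries.size:
            if self.boundaries.min() <= 0 or self.boundaries.max() >= self.T:
                raise ValueError("boundaries must lie strictly inside (0, T)")
            if np.any(np.diff(self.boundaries) <= 0):
                raise ValueError("boundaries must be strictly increasing")
        if self.selected_k != self.boundaries.size + 1:
            raise ValueError("selected_k must equal len(boundaries) + 1")
        self.tdistance_curve = {int(k): float(v) for k, v in self.tdistance_curve.items()}
        if self.tdistance_curve and self.selected_k not in self.tdistance_curve:
            raise ValueError("selected_k missing from tdistance_curve domain")

    @property
    def k(self) -> int:
        return self.selected_k

    @property
    def boundary_times_s(self) -> np.ndarray:
        return self.boundaries / self.sampling_rate_hz

    @property
    def durations(self) -> np.ndarray:
        """State durations in samples (first and last states included)."""
        edges = np.concatenate(([0], self.boundaries, [self.T]))
        return np.diff(edges)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "T": int(self.T),
            "sampling_rate_hz": self.sampling_rate_hz,
            "boundaries": [int(b) for b in self.boundaries],
            "boundary_times_s": [float(t) for t in self.boundary_times_s],
            "selected_k": int(self.selected_k),
            "selection_warning": bool(self.selection_warning),
            "tdistance_curve": {str(k): v for k, v in self.tdistance_curve.items()},
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "StateSegmentation":
        return cls(
            boundaries=np.asarray(d["boundaries"], dtype=int),
            selected_k=int(d["selected_k"]),
            tdistance_curve={int(k): float(v) for k, v in d["tdistance_curve"].items()},
            T=int(d["T"]),
            sampling_rate_hz=float(d["sampling_rate_hz"]),
            subject_id=d.get("subject_id", "unknown"),
            selection_warning=bool(d.get("selection_warning", False)),
        )

    @classmethod
    def from_json(cls, path) -> "StateSegmentation":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GSBSResult:
    """Full greedy-search trace: boundary sets and fit metrics per state count."""

    boundaries_by_k: dict[int, np.ndarray]
    tdistance_curve: dict[int, float]
    fit_curve: dict[int, float]
    T: int
    n_channels: int


# ---------------------------------------------------------------------------
# pattern similarity primitives


def _zscore_patterns(data: np.ndarray) -> np.ndarray:
    """Z-score each timepoint's spatial pattern across channels (ddof=0)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a time x channel matrix")
    if data.shape[1] < 2:
        raise ValueError("need >= 2 channels")
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateDataError(
            f"zero-variance spatial pattern at sample {int(bad[0])}"
        )
    return (data - mu) / sd[:, None]


def pattern_correlation_matrix(data: np.ndarray) -> np.ndarray:
    """T x T Pearson correlations between all pairs of spatial patterns."""
    z = _zscore_patterns(data)
    r = (z @ z.T) / z.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def _prefix2d(m: np.ndarray) -> np.ndarray:
    """2-D inclusive prefix sums, padded so P[i, j] = sum(m[:i, :j])."""
    p = np.zeros((m.shape[0] + 1, m.shape[1] + 1))
    np.cumsum(np.cumsum(m, axis=0), axis=1, out=p[1:, 1:])
    return p


def _block(p: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> float:
    return p[r1, c1] - p[r0, c1] - p[r1, c0] + p[r0, c0]


def _tdistance_from_prefix(p: np.ndarray, q: np.ndarray, edges: np.ndarray) -> float:
    """Pooled-variance two-sample t from correlation prefix sums.

    ``edges`` delimit states as half-open intervals ``[edges[i], edges[i+1])``.
    Within-state pairs are unordered pairs inside one state (length-1 states
    contribute none); between pairs are all cross pairs of temporally
    adjacent states.
    """
    n_states = len(edges) - 1
    sw = sqw = 0.0
    nw = 0
    sb = sqb = 0.0
    nb = 0
    for i in range(n_states):
        s, e = int(edges[i]), int(edges[i + 1])
        length = e - s
        if length >= 2:
            sw += (_block(p, s, e, s, e) - length) / 2.0
            sqw += (_block(q, s, e, s, e) - length) / 2.0
            nw += length * (length - 1) // 2
        if i + 1 < n_states:
            s2, e2 = int(edges[i + 1]), int(edges[i + 2])
            sb += _block(p, s, e, s2, e2)
            sqb += _block(q, s, e, s2, e2)
            nb += length * (e2 - s2)
    if nw < 2 or nb < 2:
        raise DegenerateDataError(
            "t-distance needs >= 2 within-state and >= 2 adjacent-state pairs"
        )
    mw, mb = sw / nw, sb / nb
    ssw = max(sqw - nw * mw * mw, 0.0)
    ssb = max(sqb - nb * mb * mb, 0.0)
    sp2 = (ssw + ssb) / (nw + nb - 2)
    if sp2 <= 0.0:
        # all pair correlations identical within each pool; separation is
        # infinitely sharp in whichever direction the means differ
        return float(np.inf) if mw > mb else (float(-np.inf) if mw < mb else 0.0)
    return float((mw - mb) / np.sqrt(sp2 * (1.0 / nw + 1.0 / nb)))


def tdistance(data: np.ndarray, boundaries) -> float:
    """t-distance of a boundary set on time x channel data.

    Two-sample Student t (pooled variance) comparing pattern correlations of
    within-state timepoint pairs against pairs spanning temporally adjacent
    states.  Larger values indicate better-separated states.
    """
    data = np.asarray(data, dtype=float)
    boundaries = np.asarray(boundaries, dtype=int)
    T = data.shape[0]
    if boundaries.size:
        if boundaries.min() <= 0 or boundaries.max() >= T:
            raise ValueError("boundaries must lie strictly inside (0, T)")
        if np.any(np.diff(boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
    r = pattern_correlation_matrix(data)
    p, q = _prefix2d(r), _prefix2d(r * r)
    edges = np.concatenate(([0], boundaries, [T]))
    return _tdistance_from_prefix(p, q, edges)


# ---------------------------------------------------------------------------
# greedy search


def _segment_norms(Z: np.ndarray, a, b) -> np.ndarray:
    return np.linalg.norm(Z[b] - Z[a], axis=-1)


def _fit_score(Z: np.ndarray, edges: np.ndarray, n_channels: int, T: int) -> float:
    """Mean correlation of each timepoint's pattern with its state template."""
    norms = _segment_norms(Z, edges[:-1], edges[1:])
    return float(norms.sum() / (np.sqrt(n_channels) * T))


def _finetune(bounds: list[int], Z: np.ndarray, T: int, max_passes: int = 100) -> None:
    """Shift boundaries +/-1 sample while the global fit score improves.

    Only strict improvements are accepted (zero-gain moves would allow
    drift); among equally improving shifts the earlier position wins.
    """
    for _ in range(max_passes):
        improved = False
        for i in range(len(bounds)):
            prev = bounds[i - 1] if i else 0
            nxt = bounds[i + 1] if i + 1 < len(bounds) else T
            b = bounds[i]
            base = np.linalg.norm(Z[b] - Z[prev]) + np.linalg.norm(Z[nxt] - Z[b])
            best_b, best_gain = b, 0.0
            for cand in (b - 1, b + 1):
                if prev < cand < nxt:
                    gain = (
                        np.linalg.norm(Z[cand] - Z[prev])
                        + np.linalg.norm(Z[nxt] - Z[cand])
                        - base
                    )
                    if gain > best_gain:
                        best_gain, best_b = gain, cand
            if best_b != b:
                bounds[i] = best_b
                improved = True
        if not improved:
            break


def _best_single(Z: np.ndarray, edges: np.ndarray, bounds: list[int], T: int):
    """Best single-boundary placement: (gain, index) with earliest tie-break."""
    starts = np.empty(T, dtype=int)
    ends = np.empty(T, dtype=int)
    for i in range(len(edges) - 1):
        starts[edges[i]:edges[i + 1]] = edges[i]
        ends[edges[i]:edges[i + 1]] = edges[i + 1]
    t_idx = np.arange(1, T)
    gains = (
        _segment_norms(Z, starts[t_idx], t_idx)
        + _segment_norms(Z, t_idx, ends[t_idx])
        - _segment_norms(Z, starts[t_idx], ends[t_idx])
    )
    gains[starts[t_idx] == t_idx] = -np.inf  # existing boundaries
    j = int(np.argmax(gains))  # first occurrence = earliest position
    return float(gains[j]), int(t_idx[j])


def _best_pair(Z: np.ndarray, edges: np.ndarray):
    """Best simultaneous two-boundary placement within a single state."""
    best_gain, best_pair = -np.inf, None
    for i in range(len(edges) - 1):
        s, e = int(edges[i]), int(edges[i + 1])
        if e - s < 3:
            continue
        cands = np.arange(s + 1, e)
        left = _segment_norms(Z, s, cands)            # ||Z[b] - Z[s]||
        right = _segment_norms(Z, cands, e)           # ||Z[e] - Z[b]||
        mid = np.linalg.norm(Z[cands][None, :, :] - Z[cands][:, None, :], axis=-1)
        total = left[:, None] + mid + right[None, :] - _segment_norms(Z, s, e)
        iu = np.triu_indices(len(cands), k=1)
        if iu[0].size == 0:
            continue
        vals = total[iu]
        j = int(np.argmax(vals))
        if vals[j] > best_gain:
            best_gain = float(vals[j])
            best_pair = (int(cands[iu[0][j]]), int(cands[iu[1][j]]))
    return best_gain, best_pair


def fit_gsbs(
    data: np.ndarray,
    k_max: int,
    fine_tune: bool = True,
    double_split: bool = False,
) -> GSBSResult:
    """Run the greedy boundary search up to ``k_max`` states.

    Parameters
    ----------
    data
        Time x channel matrix (transpose of the Recording orientation).
    k_max
        Largest state count to evaluate; boundary sets and the t-distance are
        recorded for every attained ``k`` from 2 to ``k_max``.
    fine_tune
        After each placement, allow previously placed boundaries to shift one
        sample in either direction while the fit score improves.
    double_split
        Also consider splitting one state into three by placing two
        boundaries at once; the pair is taken when its mean per-boundary fit
        gain beats the best single placement.  Off by default: single
        placement is the canonical procedure, and with pair placements the
        attained state counts may skip values.

    Returns
    -------
    GSBSResult
        Boundary sets, t-distance curve and fit-score curve indexed by state
        count.
    """
    data = np.asarray(data, dtype=float)
    T, C = data.shape
    k_max = int(k_max)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if k_max > T - 1:
        raise ValueError(f"k_max ({k_max}) exceeds T - 1 ({T - 1})")
    z = _zscore_patterns(data)
    Z = np.zeros((T + 1, C))
    np.cumsum(z, axis=0, out=Z[1:])
    r = (z @ z.T) / C
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    p, q = _prefix2d(r), _prefix2d(r * r)

    bounds: list[int] = []
    boundaries_by_k: dict[int, np.ndarray] = {}
    tdist: dict[int, float] = {}
    fit_curve: dict[int, float] = {}
    while len(bounds) + 1 < k_max:
        edges = np.concatenate(([0], bounds, [T])).astype(int)
        gain1, b1 = _best_single(Z, edges, bounds, T)
        placed = [b1]
        if double_split and len(bounds) + 2 < k_max:
            gain2, pair = _best_pair(Z, edges)
            if pair is not None and gain2 / 2.0 > gain1:
                placed = list(pair)
        for b in placed:
            bisect.insort(bounds, b)
        if fine_tune:
            _finetune(bounds, Z, T)
        k = len(bounds) + 1
        edges = np.concatenate(([0], bounds, [T])).astype(int)
        boundaries_by_k[k] = np.asarray(bounds, dtype=int)
        fit_curve[k] = _fit_score(Z, edges, C, T)
        try:
            tdist[k] = _tdistance_from_prefix(p, q, edges)
        except DegenerateDataError:
            tdist[k] = float("nan")
    return GSBSResult(
        boundaries_by_k=boundaries_by_k,
        tdistance_curve=tdist,
        fit_curve=fit_curve,
        T=T,
        n_channels=C,
    )


# ---------------------------------------------------------------------------
# model selection


def _select_k(tdistance_curve: dict[int, float], k_min: int) -> tuple[int, bool]:
    ks = sorted(tdistance_curve)
    if not ks or max(ks) < k_min + 1 or min(ks) > k_min:
        raise ValueError(
            f"t-distance curve must cover state counts {k_min}..{k_min + 1}"
        )
    curve = tdistance_curve
    for i, k in enumerate(ks):
        if k < k_min or i == 0 or i == len(ks) - 1:
            continue
        left, right = curve[ks[i - 1]], curve[ks[i + 1]]
        here = curve[k]
        if np.isnan(here) or np.isnan(left) or np.isnan(right):
            continue
        if here > left and here > right:
            return k, False
    eligible = [k for k in ks if k >= k_min and not np.isnan(curve[k])]
    best = max(eligible, key=lambda k: curve[k])
    return best, True


def select_k(tdistance_curve: dict[int, float], k_min: int = 15) -> int:
    """First t-distance peak at or above ``k_min`` states.

    A peak is a state count whose t-distance exceeds both neighbouring model
    fits.  If no peak exists at or beyond ``k_min``, the argmax over
    ``k >= k_min`` is returned and a warning is emitted.
    """
    k, fallback = _select_k(tdistance_curve, int(k_min))
    if fallback:
        warnings.warn(
            f"no t-distance peak at k >= {k_min}; falling back to argmax k={k}",
            RuntimeWarning,
            stacklevel=2,
        )
    return k


def segment_subject(
    rec: Recording,
    k_min: int = 15,
    k_max_policy: int | str = "seconds",
    fine_tune: bool = True,
) -> StateSegmentation:
    """Segment one (already downsampled, channel-selected) recording.

    Under the default ``"seconds"`` policy the maximum state count equals the
    floor of the recording duration in seconds (e.g. 489 for a 489-s
    recording); an explicit integer overrides it.  The state count is chosen
    as the first t-distance peak at or above ``k_min``.
    """
    data = rec.data.T  # algorithm operates on time x channel
    T = data.shape[0]
    if k_max_policy == "seconds":
        k_max = int(np.floor(rec.duration_s))
    else:
        k_max = int(k_max_policy)
    k_max = min(k_max, T - 1)
    if k_max < k_min + 1:
        raise ValueError(
            f"k_max ({k_max}) must exceed k_min ({k_min}) for first-peak selection"
        )
    result = fit_gsbs(data, k_max=k_max, fine_tune=fine_tune)
    k, fallback = _select_k(result.tdistance_curve, int(k_min))
    return StateSegmentation(
        boundaries=result.boundaries_by_k[k],
        selected_k=k,
        tdistance_curve=result.tdistance_curve,
        T=T,
        sampling_rate_hz=rec.sampling_rate_hz,
        subject_id=rec.subject_id,
        selection_warning=fallback,
    )
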