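"""Group statistics and memory-linkage regressions.

Covers the summary-level statistics used for recall measures (pooled
two-sample t with Cohen's d, one-sample t against zero, 2x2 mixed ANOVA for
age x cue-type designs) and the bootstrap moderation regression that links a
neural measure to the proportion of internal details recalled::

    proportion_internal ~ neural + group + neural x group

with subject-level (case) bootstrap resampling, stratified by age group so
that every replicate contains both groups, and coefficient estimates taken
as the median of the bootstrap distribution (default 5,000 replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError

__all__ = [
    "SubjectMemory",
    "RegressionResult",
    "pooled_t_test",
    "one_sample_t",
    "one_sample_t_from_stats",
    "mixed_anova_2x2",
    "bootstrap_regression",
]

TERMS = ("intercept", "neural", "group", "neural_x_group")


@dataclass
class SubjectMemory:
    """Already-scored memory summaries for one subject.

    ``detail_counts`` maps category -> count for the free-recall categories
    (event, perceptual, conceptual, external, incorrect).  When present, the
    proportion of internal details must equal
    ``(event + perceptual + conceptual) / total details``.
    """

    subject_id: str
    group: str
    proportion_internal: float
    detail_counts: dict[str, int] | None = None
    cued_within_acc: float = float("nan")
    cued_between_acc: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 <= self.proportion_internal <= 1:
            raise ValueError("proportion_internal must be in [0, 1]")
        for acc in (self.cued_within_acc, self.cued_between_acc):
            if not np.isnan(acc) and not 0 <= acc <= 1:
                raise ValueError("cued-recall accuracies must be in [0, 1]")
        if self.detail_counts is not None:
            c = self.detail_counts
            internal = c["event"] + c["perceptual"] + c["conceptual"]
            total = internal + c["external"] + c["incorrect"]
            if total > 0:
                expected = internal / total
                if abs(expected - self.proportion_internal) > 1e-6:
                    raise ValueError(
                        f"proportion_internal {self.proportion_internal} inconsistent "
                        f"with detail counts (expected {expected:.6f})"
                    )


@dataclass
class RegressionResult:
    """OLS point fit plus bootstrap medians and percentile CIs per term."""

    coef_point: dict[str, float]
    coef_boot_median: dict[str, float]
    boot_ci: dict[str, tuple[float, float]]
    coef_p: dict[str, float]
    model_F: float
    model_p: float
    B: int
    seed: int | None
    n_dropped: int = 0
    group_coding: str = "older=0, younger=1; neural measure uncentered"

    def to_dict(self) -> dict:
        return {
            "terms": list(TERMS),
            "coef_point": self.coef_point,
            "coef_boot_median": self.coef_boot_median,
            "boot_ci": {k: list(v) for k, v in self.boot_ci.items()},
            "coef_p": self.coef_p,
            "model_F": self.model_F,
            "model_p": self.model_p,
            "B": self.B,
            "seed": self.seed,
            "n_dropped": self.n_dropped,
            "group_coding": self.group_coding,
        }


# ---------------------------------------------------------------------------
# t statistics


def pooled_t_test(m1, sd1, n1, m2, sd2, n2):
    """Two-sample pooled-variance t from summary statistics.

    Returns ``(t, df, p, d)`` with two-sided p and Cohen's d computed against
    the pooled SD.  Degenerate zero-variance input with equal means yields
    ``t = 0``; with unequal means it raises.
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if m1 == m2:
            return 0.0, df, 1.0, 0.0
        raise DegenerateDataError("zero pooled SD with unequal means")
    t, p = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    d = (m1 - m2) / np.sqrt(sp2)
    return float(t), df, float(p), float(d)


def one_sample_t(values, mu: float = 0.0):
    """One-sample t of ``values`` against ``mu``; returns ``(t, df, p, d)``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance: one-sample t undefined")
    t, p = stats.ttest_1samp(values, mu)
    d = (values.mean() - mu) / sd
    return float(t), values.size - 1, float(p), float(d)


def one_sample_t_from_stats(m: float, sd: float, n: int, mu: float = 0.0):
    """Summary-statistic variant of :func:`one_sample_t`."""
    n = int(n)
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise DegenerateDataError("zero variance: one-sample t undefined")
    t = (m - mu) / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p), float((m - mu) / sd)


# ---------------------------------------------------------------------------
# mixed ANOVA


def mixed_anova_2x2(within_means, group_labels) -> pd.DataFrame:
    """Classical 2 (between) x 2 (within) mixed-design ANOVA on condition means.

    Parameters
    ----------
    within_means
        Array-like of shape (n_subjects, 2): each subject's mean in the two
        within-subject conditions (e.g. within-event and between-event cue
        accuracy).
    group_labels
        Length-n sequence of group labels (exactly two distinct values,
        each with >= 2 subjects).

    Returns
    -------
    DataFrame indexed by effect (``group``, ``condition``, ``interaction``)
    with columns F, df1, df2, p and partial eta squared.
    """
    y = np.asarray(within_means, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("within_means must have shape (n_subjects, 2)")
    if not np.isfinite(y).all():
        bad = int(np.argwhere(~np.isfinite(y).all(axis=1)).ravel()[0])
        raise ValueError(f"missing condition mean for subject index {bad}")
    groups = np.asarray(group_labels)
    levels = sorted(set(groups.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    n_g = np.array([(groups == lv).sum() for lv in levels])
    if (n_g < 2).any():
        raise ValueError("each group needs >= 2 subjects")
    N, K = y.shape

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[groups == lv].mean() for lv in levels])
    cond_means = y.mean(axis=0)
    cell_means = np.array([y[groups == lv].mean(axis=0) for lv in levels])

    ss_group = K * float(np.sum(n_g * (group_means - grand) ** 2))
    ss_subj = K * float(
        sum(
            np.sum((subj_means[groups == lv] - group_means[i]) ** 2)
            for i, lv in enumerate(levels)
        )
    )
    ss_cond = N * float(np.sum((cond_means - grand) ** 2))
    ss_inter = float(
        np.sum(
            n_g[:, None]
            * (cell_means - group_means[:, None] - cond_means[None, :] + grand) ** 2
        )
    )
    ss_within_subj = float(np.sum((y - subj_means[:, None]) ** 2))
    ss_err_w = ss_within_subj - ss_cond - ss_inter

    df_group, df_subj = 1, N - 2
    df_cond, df_inter, df_err = 1, 1, (N - 2) * (K - 1)
    ms = lambda ss, df: ss / df if df > 0 else np.nan

    rows = {}
    for name, ss_eff, df1, ss_err, df2 in (
        ("group", ss_group, df_group, ss_subj, df_subj),
        ("condition", ss_cond, df_cond, ss_err_w, df_err),
        ("interaction", ss_inter, df_inter, ss_err_w, df_err),
    ):
        F = ms(ss_eff, df1) / ms(ss_err, df2) if ss_err > 0 else 0.0
        p = float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        rows[name] = {"F": float(F), "df1": df1, "df2": df2, "p": p, "eta_p2": float(eta)}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# bootstrap moderation regression


def _design(x: np.ndarray, g01: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, g01, x * g01])


def bootstrap_regression(
    y,
    x,
    group_labels,
    B: int = 5000,
    seed: int | None = None,
) -> RegressionResult:
    """OLS of memory on a neural measure with age-group moderation, bootstrapped.

    The design is ``y ~ 1 + x + group + x:group`` with group coded 0 (older)
    / 1 (younger) and ``x`` left uncentered.  Case resampling of subjects is
    stratified by age group so both groups appear in every replicate;
    replicates with a singular design are dropped (an error is raised if
    more than 10% drop).  Coefficients are reported both as the full-sample
    OLS point estimate and as the bootstrap median, with percentile 95% CIs.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(group_labels)
    if y.size != x.size or y.size != groups.size:
        raise ValueError("y, x and group_labels must have equal length")
    if y.size < 8:
        raise ValueError("need >= 8 subjects")
    g01 = np.where(groups == "younger", 1.0, np.where(groups == "older", 0.0, np.nan))
    if np.isnan(g01).any():
        raise ValueError("group labels must be 'younger' or 'older'")
    if len(set(g01.tolist())) < 2:
        raise ValueError("both age groups must be represented")

    X = _design(x, g01)
    fit = sm.OLS(y, X).fit()
    coef_point = dict(zip(TERMS, map(float, fit.params)))
    coef_p = dict(zip(TERMS, map(float, fit.pvalues)))

    rng = np.random.default_rng(seed)
    B = int(B)
    idx_old = np.flatnonzero(g01 == 0.0)
    idx_young = np.flatnonzero(g01 == 1.0)
    res_old = idx_old[rng.integers(0, idx_old.size, size=(B, idx_old.size))]
    res_young = idx_young[rng.integers(0, idx_young.size, size=(B, idx_young.size))]
    idx = np.concatenate([res_old, res_young], axis=1)  # (B, n)
    Xb = X[idx]                                          # (B, n, 4)
    yb = y[idx]                                          # (B, n)
    G = np.einsum("bij,bik->bjk", Xb, Xb)
    h = np.einsum("bij,bi->bj", Xb, yb)
    det = np.abs(np.linalg.det(G))
    scale = np.median(det[det > 0]) if (det > 0).any() else 1.0
    good = det > 1e-12 * scale
    n_dropped = int(B - good.sum())
    if n_dropped > 0.1 * B:
        raise DegenerateDataError(
            f"{n_dropped}/{B} bootstrap replicates had singular designs"
        )
    coefs = np.linalg.solve(G[good], h[good][..., None])[..., 0]  # (B_good, 4)
    boot_median = dict(zip(TERMS, map(float, np.median(coefs, axis=0))))
    lo, hi = np.percentile(coefs, [2.5, 97.5], axis=0)
    boot_ci = {t: (float(lo[i]), float(hi[i])) for i, t in enumerate(TERMS)}
    return RegressionResult(
        coef_point=coef_point,
        coef_boot_median=boot_median,
        boot_ci=boot_ci,
        coef_p=coef_p,
        model_F=float(fit.fvalue),
        model_p=float(fit.f_pvalue),
        B=B,
        seed=seed,
        n_dropped=n_dropped,
    )
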