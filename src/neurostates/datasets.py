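"""Bundled worked-example summary statistics.

Published group-level recall summaries (mean, SD, n per age group) from a
movie-viewing study of 28 younger and 26 older adults, plus the durations of
the cued-recall video clips.  These are inputs for the summary-statistic
tests in :mod:`neurostates.memory_stats`; the per-subject data behind them
are not distributed with this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["example_recall_summaries", "example_clip_duration_summary"]


_RECALL_ROWS = [
    # measure, m_young, sd_young, m_old, sd_old
    ("cued_within", 0.779, 0.160, 0.727, 0.236),
    ("cued_between", 0.677, 0.198, 0.551, 0.248),
    ("free_event", 54.7, 25.1, 57.0, 18.9),
    ("free_perceptual", 10.3, 5.83, 12.9, 9.37),
    ("free_conceptual", 5.50, 4.97, 10.7, 7.55),
    ("free_external", 5.00, 4.55, 10.3, 10.5),
    ("free_incorrect", 4.32, 2.93, 5.19, 3.32),
    ("proportion_internal", 0.888, 0.049, 0.853, 0.063),
]

N_YOUNGER = 28
N_OLDER = 26


def example_recall_summaries() -> pd.DataFrame:
    """Group recall summaries: one row per measure with (M, SD, n) per group."""
    df = pd.DataFrame(
        _RECALL_ROWS, columns=["measure", "m_young", "sd_young", "m_old", "sd_old"]
    ).set_index("measure")
    df["n_young"] = N_YOUNGER
    df["n_old"] = N_OLDER
    return df


def example_clip_duration_summary() -> dict:
    """Durations of the 10 between-event vs 10 within-event cue clips (s)."""
    return {
        "between": {"m": 5.60, "sd": 1.43, "n": 10},
        "within": {"m": 5.30, "sd": 0.95, "n": 10},
    }
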