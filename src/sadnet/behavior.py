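"""Working-memory scoring, training index and sadness-group split."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic import CohortDataset, TrialRecord, PARADIGMS


def score_block(trials: list[TrialRecord]) -> tuple[int, int, float]:
    """Score one WM block: (errors, inhibition_errors, mean_rt).

    Errors count incorrect responses; an inhibition error is a catch
    trial answered "yes" (the probed distractor was mistaken for a
    target).  Missing responses count as errors and are excluded from
    the mean reaction time.
    """
    if not trials:
        raise ValueError("trial list is empty")
    errors = 0
    inhibition_errors = 0
    rts = []
    n_missing = 0
    for t in trials:
        if t.response is None:
            errors += 1
            n_missing += 1
            continue
        rts.append(t.reaction_time)
        if not t.correct:
            errors += 1
        if t.is_catch and t.response:
            inhibition_errors += 1
    if n_missing:
        warnings.warn(f"{n_missing} trial(s) without a response counted as errors")
    mean_rt = float(np.mean(rts)) if rts else float("nan")
    return errors, inhibition_errors, mean_rt


def training_index(mean_rt_wm1: float, mean_rt_wm2: float) -> float:
    """(rt1 - rt2) / (rt1 + rt2): positive means faster second block."""
    if mean_rt_wm1 <= 0 or mean_rt_wm2 <= 0:
        raise ValueError("reaction times must be positive")
    return (mean_rt_wm1 - mean_rt_wm2) / (mean_rt_wm1 + mean_rt_wm2)


def split_sadness_groups(ratings) -> tuple[list[str], float]:
    """Label subjects by sadness intensity relative to the overall mean.

    "high-sadness" iff the rating is strictly above the mean of all
    ratings; ties at the mean go to "low-sadness".  Returns the labels
    and the mean used.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size < 2:
        raise ValueError("need at least 2 ratings to split")
    mean = float(ratings.mean())
    labels = ["high-sadness" if r > mean else "low-sadness" for r in ratings]
    if all(lab == "low-sadness" for lab in labels):
        warnings.warn("all ratings equal: every subject labeled low-sadness")
    return labels, mean


def median_split(values) -> tuple[list[str], float]:
    """Generic strict-above-median split into "high" / "low" labels."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to split")
    med = float(np.median(values))
    return ["high" if v > med else "low" for v in values], med


def summarize_cohort(dataset: CohortDataset) -> pd.DataFrame:
    """One behavioral-summary row per subject.

    Columns: per-paradigm error counts, inhibition-error counts and
    mean RTs, the training index, the sadness rating and the group
    label recomputed from the cohort's own ratings via the
    above-the-mean rule.
    """
    labels, rating_mean = split_sadness_groups(dataset.ratings())
    rows = []
    for sub, label in zip(dataset.subjects, labels):
        row: dict = {"subject_id": sub.subject_id, "rating": sub.rating, "group": label}
        rts = {}
        for paradigm in PARADIGMS:
            errors, inhib, mean_rt = score_block(sub.trials[paradigm])
            short = "wm1" if paradigm == PARADIGMS[0] else "wm2"
            row[f"errors_{short}"] = errors
            row[f"inhibition_errors_{short}"] = inhib
            row[f"mean_rt_{short}"] = mean_rt
            rts[short] = mean_rt
        row["training_index"] = training_index(rts["wm1"], rts["wm2"])
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["rating_mean"] = rating_mean
    return frame
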