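"""Descriptive behavioural summaries of two-stage trial logs.

All statistics here work identically on human-format and synthetic logs:
free-choice preference per block and its within-block dynamics, stage-1
preference conditioned on the previous trial's stage-1 selection, the
2 x 2 stay table (previous reward x previous coherence) of successive
free-trial stage-2 choices, a logistic estimate of the preference reversal
point against the forced reward probability, and the odds ratio of
repeating a rewarded stage-1 selection.

No inferential statistics: the original analyses' mixed-model machinery is
replaced by plain descriptive summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import TEST, records_to_frame
from .task import FREE


class BehaviorDataError(ValueError):
    """Log lacks the trials a summary needs."""


def as_frame(logs) -> pd.DataFrame:
    """Accept a DataFrame, a list of records, or a list of record lists."""
    if isinstance(logs, pd.DataFrame):
        return logs
    if len(logs) > 0 and isinstance(logs[0], (list, tuple)):
        return pd.concat([records_to_frame(list(lg)) for lg in logs],
                         ignore_index=True)
    return records_to_frame(list(logs))


# ---------------------------------------------------------------------------
# Stage-1 preference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreferenceSummary:
    per_subject: pd.DataFrame  # subject_id, block_index, n_test, prop_free
    series: pd.DataFrame       # block_index, trial_index, prop_free
    block_means: pd.Series     # cohort mean per block


def choice_preference(logs) -> PreferenceSummary:
    """Proportion of test-phase stage-1 choices that selected the free cue,
    per subject per block, with the cohort trial-indexed dynamics."""
    df = as_frame(logs)
    test = df[df["phase"] == TEST]
    if len(test) == 0:
        raise BehaviorDataError("log contains no test-phase trials")
    is_free = (test["stage1_option"] == FREE).astype(float)
    test = test.assign(chose_free=is_free)
    per_subject = (
        test.groupby(["subject_id", "block_index"])["chose_free"]
        .agg(n_test="count", prop_free="mean").reset_index())
    series = (
        test.groupby(["block_index", "trial_index"])["chose_free"]
        .mean().rename("prop_free").reset_index())
    block_means = per_subject.groupby("block_index")["prop_free"].mean()
    return PreferenceSummary(per_subject=per_subject, series=series,
                             block_means=block_means)


def smooth_series(series: pd.DataFrame, window: int = 2) -> pd.DataFrame:
    """Moving-average smoothing of the preference dynamics (the raw series
    is always kept; this returns a smoothed copy)."""
    out = series.copy()
    out["prop_free"] = (
        out.groupby("block_index")["prop_free"]
        .transform(lambda s: s.rolling(window, min_periods=1).mean()))
    return out


def conditional_stage1_preference(logs) -> pd.DataFrame:
    """P(free | previous test trial free) and P(free | previous forced),
    per subject per block; the first test trial of a block is excluded."""
    df = as_frame(logs)
    test = df[df["phase"] == TEST].sort_values(
        ["subject_id", "block_index", "trial_index"])
    rows = []
    for (sid, b), grp in test.groupby(["subject_id", "block_index"]):
        opts = (grp["stage1_option"] == FREE).to_numpy()
        prev = opts[:-1]
        cur = opts[1:]
        n_after_free = int(prev.sum())
        n_after_forced = int((~prev).sum())
        rows.append({
            "subject_id": sid, "block_index": b,
            "p_free_after_free":
                float(cur[prev].mean()) if n_after_free else np.nan,
            "p_free_after_forced":
                float(cur[~prev].mean()) if n_after_forced else np.nan,
            "n_after_free": n_after_free,
            "n_after_forced": n_after_forced,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage-2 stay behaviour
# ---------------------------------------------------------------------------

STAY_CELLS = (("rewarded", "coherent"), ("rewarded", "incoherent"),
              ("unrewarded", "coherent"), ("unrewarded", "incoherent"))


def stay_probabilities(logs) -> pd.DataFrame:
    """2 x 2 stay table of successive free-trial stage-2 choices.

    For each pair of successive test-phase free-choice trials within a
    block (intervening forced trials allowed: the conditioning trial is
    the most recent free trial), the earlier trial is classified by its
    reward and coherence, and *stay* means the later *emitted* action
    repeats the earlier emitted action (the subject controls only the
    action, not the displayed target).  Cells without observations are
    NaN with count 0.
    """
    df = as_frame(logs)
    test = df[(df["phase"] == TEST) & (df["stage1_option"] == FREE)]
    test = test.sort_values(["subject_id", "block_index", "trial_index"])
    rows = []
    for sid, grp in test.groupby("subject_id"):
        stats = {cell: [0, 0] for cell in STAY_CELLS}  # [n, n_stay]
        for _, blk in grp.groupby("block_index"):
            actions = blk["stage2_action"].to_numpy()
            rewards = blk["reward"].to_numpy()
            coherent = blk["coherent"].to_numpy()
            for i in range(1, len(actions)):
                cell = ("rewarded" if rewards[i - 1] else "unrewarded",
                        "coherent" if coherent[i - 1] else "incoherent")
                stats[cell][0] += 1
                stats[cell][1] += int(actions[i] == actions[i - 1])
        row: dict = {"subject_id": sid}
        for (rw, co), (n, n_stay) in stats.items():
            key = f"{rw}_{co}"
            row[f"stay_{key}"] = n_stay / n if n else np.nan
            row[f"n_{key}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Preference reversal point
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReversalEstimate:
    value: float  # NaN when undefined
    message: str
    intercept: float = np.nan
    slope: float = np.nan

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.value))


def reversal_point(block_prefs: pd.DataFrame) -> ReversalEstimate:
    """Forced reward probability at which the cohort is indifferent.

    Fits a binomial-logit GLM of per-subject free-choice proportion
    against ``p_forced`` and returns the 0.5 crossing (-b0/b1); this is a
    descriptive logistic interpolation, not the original mixed-model
    estimate.  ``block_prefs`` needs columns ``p_forced`` and
    ``prop_free`` (one row per subject x block).
    """
    x = block_prefs["p_forced"].to_numpy(dtype=float)
    y = block_prefs["prop_free"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        return ReversalEstimate(np.nan, "need >= 2 distinct p_forced levels")
    if np.allclose(y, y[0]):
        return ReversalEstimate(np.nan, "degenerate (constant) preferences")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit()
    except Exception as err:  # perfect separation, singular fits
        return ReversalEstimate(np.nan, f"logistic fit failed: {err}")
    b0, b1 = res.params
    if b1 == 0 or not np.isfinite(b1):
        return ReversalEstimate(np.nan, "flat logistic fit",
                                intercept=b0, slope=b1)
    crossing = -b0 / b1
    if not 0.0 <= crossing <= 1.0:
        return ReversalEstimate(np.nan,
                                f"no 0.5 crossing in [0, 1] "
                                f"(extrapolates to {crossing:.3f})",
                                intercept=b0, slope=b1)
    return ReversalEstimate(float(crossing), "ok", intercept=float(b0),
                            slope=float(b1))


# ---------------------------------------------------------------------------
# Reward-repetition effect
# ---------------------------------------------------------------------------

def reward_repetition_effect(logs) -> tuple[float, pd.DataFrame]:
    """Odds ratio of repeating the previous stage-1 selection after a
    rewarded versus unrewarded previous trial.

    Pools consecutive test-trial pairs within block across subjects into
    a 2 x 2 contingency table; zero cells get the Haldane-Anscombe 0.5
    correction.  Returns (odds ratio, table).
    """
    df = as_frame(logs)
    test = df[df["phase"] == TEST].sort_values(
        ["subject_id", "block_index", "trial_index"])
    counts = np.zeros((2, 2))  # [prev rewarded][repeated]
    for _, grp in test.groupby(["subject_id", "block_index"]):
        opts = grp["stage1_option"].to_numpy()
        rew = grp["reward"].to_numpy()
        for i in range(1, len(opts)):
            counts[int(rew[i - 1]), int(opts[i] == opts[i - 1])] += 1
    table = pd.DataFrame(counts.astype(int),
                         index=["prev_unrewarded", "prev_rewarded"],
                         columns=["switched", "repeated"])
    if counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
        raise BehaviorDataError("a margin of the 2x2 table is empty")
    c = counts + 0.5 if (counts == 0).any() else counts
    odds_ratio = (c[1, 1] * c[0, 0]) / (c[1, 0] * c[0, 1])
    return float(odds_ratio), table
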