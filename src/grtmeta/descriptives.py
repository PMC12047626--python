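"""Descriptive companion analyses.

Confidence reclassification (4 levels to confident / not-confident),
participant exclusion rules, per-state mean confidence, and the Friedman
rank test comparing mean confidence between metacognitive states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import StimulusCondition
from .trials import TrialRecord

__all__ = [
    "FriedmanResult",
    "ExclusionReport",
    "reclassify_confidence",
    "apply_exclusions",
    "state_mean_confidence",
    "friedman_test",
    "descriptives_report",
]

log = logging.getLogger(__name__)

CONFIDENT = "CONFIDENT"
NOT_CONFIDENT = "NOT_CONFIDENT"

_FAMOUS = (StimulusCondition.CORRECT_NAME, StimulusCondition.INCORRECT_NAME)


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    p: float


@dataclass
class ExclusionReport:
    retained: list[str]
    excluded: dict[str, str]  # participant id -> reason


def reclassify_confidence(confidence4: int) -> str:
    """Collapse the 4-level rating: "very"/"somewhat" confident (4, 3)
    become CONFIDENT; "a little"/"not at all" (2, 1) NOT_CONFIDENT."""
    if confidence4 in (3, 4):
        return CONFIDENT
    if confidence4 in (1, 2):
        return NOT_CONFIDENT
    raise ValueError(f"confidence level must be 1..4, got {confidence4!r}")


def _by_participant(trials) -> dict[str, list[TrialRecord]]:
    groups: dict[str, list[TrialRecord]] = {}
    for t in trials:
        groups.setdefault(t.participant_id, []).append(t)
    return groups


def apply_exclusions(
    trials,
    recall_max: float = 0.80,
    recog_min: float = 0.51,
) -> ExclusionReport:
    """Exclude participants who recalled more than ``recall_max`` of the
    famous names, or whose recognition accuracy on famous recall-failed
    trials fell below ``recog_min``.  Both comparisons are strict, so a
    participant at exactly the threshold is retained.

    Recognition accuracy is computed over famous trials only: catch
    trials have no correct answer, so accuracy is undefined there.
    """
    retained: list[str] = []
    excluded: dict[str, str] = {}
    for pid, recs in _by_participant(trials).items():
        famous = [t for t in recs if t.condition in _FAMOUS]
        if not famous:
            raise ValueError(f"participant {pid!r} has no famous trials")
        recall_prop = np.mean([t.recalled for t in famous])
        if recall_prop > recall_max:
            excluded[pid] = "recall"
            continue
        scored = [t for t in famous if not t.recalled]
        accuracy = np.mean([t.recog_accurate for t in scored]) if scored else 1.0
        if accuracy < recog_min:
            excluded[pid] = "recognition"
            continue
        retained.append(pid)
    return ExclusionReport(retained=retained, excluded=excluded)


def state_mean_confidence(
    trials,
    judgment: str = "TOT",
    include_catch: bool = True,
) -> pd.DataFrame:
    """Per-participant mean 4-level confidence in state-present versus
    state-absent trials (TOT yes/no or FOK high/low), over recall-failed
    trials.  Catch trials carry metacognitive responses and are included
    by default.  Participants lacking trials in either state are dropped
    from the paired table (logged).
    """
    if judgment not in ("TOT", "FOK"):
        raise ValueError(f"judgment must be TOT or FOK, got {judgment!r}")
    rows = []
    dropped = []
    for pid, recs in _by_participant(trials).items():
        eligible = [
            t
            for t in recs
            if not t.recalled
            and (include_catch or t.condition != StimulusCondition.CATCH)
        ]
        if judgment == "TOT":
            present = [t.confidence4 for t in eligible if t.tot == "yes"]
            absent = [t.confidence4 for t in eligible if t.tot == "no"]
        else:
            present = [t.confidence4 for t in eligible if t.fok == "high"]
            absent = [t.confidence4 for t in eligible if t.fok == "low"]
        if not present or not absent:
            dropped.append(pid)
            continue
        rows.append(
            {
                "participant_id": pid,
                "mean_conf_present": float(np.mean(present)),
                "mean_conf_absent": float(np.mean(absent)),
                "n_present": len(present),
                "n_absent": len(absent),
            }
        )
    if dropped:
        log.info(
            "%s mean-confidence comparison: dropped %d participant(s) "
            "lacking trials in one state: %s",
            judgment,
            len(dropped),
            dropped,
        )
    if not rows:
        raise ValueError("no participant has trials in both states")
    return pd.DataFrame(rows).set_index("participant_id")


def friedman_test(values) -> FriedmanResult:
    """Friedman rank test over an (n participants x k conditions) table.

    Within-row average ranks with the standard tie correction; the
    statistic is asymptotically chi-squared with k - 1 degrees of
    freedom.  An input with every row completely tied returns statistic
    0 and p = 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) table")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells are not allowed")
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * float(np.sum(col_sums**2) - n**2 * k * (k + 1) ** 2 / 4.0)
    denom = float(np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0)
    statistic = 0.0 if denom == 0.0 else numer / denom
    p = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0
    return FriedmanResult(statistic=float(statistic), df=k - 1, p=p)


def descriptives_report(trials, include_catch: bool = True) -> dict:
    """Mean-confidence comparisons and Friedman tests for both judgments."""
    out: dict = {}
    for judgment in ("TOT", "FOK"):
        table = state_mean_confidence(
            trials, judgment=judgment, include_catch=include_catch
        )
        fr = friedman_test(
            table[["mean_conf_present", "mean_conf_absent"]].to_numpy()
        )
        out[judgment] = {
            "n_participants": int(len(table)),
            "grand_mean_present": float(table["mean_conf_present"].mean()),
            "grand_mean_absent": float(table["mean_conf_absent"].mean()),
            "friedman_chi2": fr.statistic,
            "friedman_df": fr.df,
            "friedman_p": fr.p,
            "table": table,
        }
    return out
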