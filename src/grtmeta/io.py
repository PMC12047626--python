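"""Reading, writing and aggregating trial-level data.

Trial files are tab-separated text with a fixed header::

    participant_id  session  block  trial  condition  recalled  tot  fok  recog_response  confidence4

Missing values are empty fields, booleans are 0/1, categorical codes are
lowercase (``correct_name``/``incorrect_name``/``catch``, ``yes``/``no``,
``high``/``low``, ``correct``/``incorrect``).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .descriptives import CONFIDENT, reclassify_confidence
from .model import (
    ConfCategory,
    CountTable,
    JointResponse,
    MetacogResponse,
    StimulusCondition,
)
from .trials import CONDITION_CODES, CONDITION_LABELS, TrialRecord

__all__ = ["read_trials", "write_trials", "aggregate_counts", "TRIAL_COLUMNS"]

log = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "participant_id",
    "session",
    "block",
    "trial",
    "condition",
    "recalled",
    "tot",
    "fok",
    "recog_response",
    "confidence4",
]


class TrialParseError(ValueError):
    """A trial file violated the documented schema."""


def write_trials(trials, path) -> None:
    rows = []
    for t in trials:
        rows.append(
            {
                "participant_id": t.participant_id,
                "session": t.session,
                "block": t.block,
                "trial": t.trial,
                "condition": CONDITION_LABELS[t.condition],
                "recalled": int(t.recalled),
                "tot": t.tot or "",
                "fok": t.fok or "",
                "recog_response": t.recog_response or "",
                "confidence4": "" if t.confidence4 is None else t.confidence4,
            }
        )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_trials(path) -> list[TrialRecord]:
    """Parse and validate a trial file; schema violations are reported
    with the offending line number (header is line 1)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TrialParseError(f"{path}: empty trial file") from None
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise TrialParseError(f"{path}: no trial records")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2
        try:
            condition = CONDITION_CODES.get(row.condition)
            if condition is None:
                raise ValueError(f"unknown condition code {row.condition!r}")
            if row.recalled not in ("0", "1"):
                raise ValueError(f"recalled must be 0/1, got {row.recalled!r}")
            records.append(
                TrialRecord(
                    participant_id=row.participant_id,
                    session=int(row.session),
                    block=int(row.block),
                    trial=int(row.trial),
                    condition=condition,
                    recalled=row.recalled == "1",
                    tot=row.tot or None,
                    fok=row.fok or None,
                    recog_response=row.recog_response or None,
                    confidence4=int(row.confidence4) if row.confidence4 else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise TrialParseError(f"{path}, line {lineno}: {exc}") from None
    return records


def aggregate_counts(trials, judgment: str = "TOT") -> list[CountTable]:
    """Bin recall-failed trials into 3 x 6 multinomial count tables.

    The metacognitive axis encodes the chosen judgment (TOT yes or FOK
    high maps to PRESENT); the confidence axis combines the reclassified
    2-level confidence with the recognition response: confident +
    "correct" is CONF_CORRECT, confident + "incorrect" is CONF_INCORRECT,
    anything not confident is NOT_CONF.  Participants with an all-zero
    stimulus row are dropped with a warning.
    """
    if judgment not in ("TOT", "FOK"):
        raise ValueError(f"judgment must be TOT or FOK, got {judgment!r}")
    counts: dict[str, np.ndarray] = {}
    for t in trials:
        if t.recalled:
            continue
        grid = counts.setdefault(
            t.participant_id, np.zeros((3, 6), dtype=np.int64)
        )
        present = (t.tot == "yes") if judgment == "TOT" else (t.fok == "high")
        metacog = MetacogResponse.PRESENT if present else MetacogResponse.ABSENT
        if reclassify_confidence(t.confidence4) == CONFIDENT:
            confcat = (
                ConfCategory.CONF_CORRECT
                if t.recog_response == "correct"
                else ConfCategory.CONF_INCORRECT
            )
        else:
            confcat = ConfCategory.NOT_CONF
        grid[int(t.condition), JointResponse(metacog, confcat).index] += 1

    tables = []
    for pid in sorted(counts):
        grid = counts[pid]
        if np.any(grid.sum(axis=1) == 0):
            warnings.warn(
                f"participant {pid!r} has an empty stimulus row after "
                "aggregation; dropped",
                stacklevel=2,
            )
            continue
        tables.append(CountTable(pid, grid, judgment=judgment))
    if not tables:
        raise ValueError("no usable participants after aggregation")
    return tables


# ---------------------------------------------------------------------------
# Curve / band delimited-text export
# ---------------------------------------------------------------------------

def write_curve(curve, path) -> None:
    """SvM curve as tab-separated text with a commented header block."""
    with open(path, "w") as fh:
        fh.write(f"# grtmeta svm curve\n# judgment = {curve.judgment}\n")
        fh.write(f"# y_star = {curve.y_star!r}\n# L_star = {curve.L_star!r}\n")
        fh.write(
            "# participant_positions = "
            + ",".join(repr(float(v)) for v in curve.participant_positions)
            + "\n"
        )
        fh.write("y\trel_likelihood\tmeta_d\n")
        for y, L, md in zip(curve.y_grid, curve.rel_likelihood, curve.meta_d):
            fh.write(f"{float(y)!r}\t{float(L)!r}\t{float(md)!r}\n")


def read_curve(path):
    from .svm import SvMCurve

    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
        else:
            body_start = i
            break
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    positions = (
        [float(v) for v in meta["participant_positions"].split(",")]
        if meta.get("participant_positions")
        else []
    )
    return SvMCurve(
        y_grid=df["y"].to_numpy(),
        rel_likelihood=df["rel_likelihood"].to_numpy(),
        meta_d=df["meta_d"].to_numpy(),
        y_star=float(meta["y_star"]),
        L_star=float(meta["L_star"]),
        participant_positions=np.array(positions),
        judgment=meta.get("judgment", "TOT"),
    )


def write_band(band, path) -> None:
    with open(path, "w") as fh:
        fh.write("# grtmeta bootstrap band\n")
        fh.write(f"# n_boot = {band.n_boot}\n# level = {band.level!r}\n")
        fh.write(f"# n_failed = {band.n_failed}\n# seed = {band.seed}\n")
        fh.write("L\tlower\tupper\n")
        for L, lo, hi in zip(band.L_grid, band.lower, band.upper):
            fh.write(f"{float(L)!r}\t{float(lo)!r}\t{float(hi)!r}\n")


def read_band(path):
    from .bootstrap import BootstrapBand

    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
        else:
            body_start = i
            break
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    return BootstrapBand(
        L_grid=df["L"].to_numpy(),
        lower=df["lower"].to_numpy(),
        upper=df["upper"].to_numpy(),
        level=float(meta["level"]),
        n_boot=int(meta["n_boot"]),
        n_failed=int(meta["n_failed"]),
        seed=None if meta.get("seed") in (None, "None") else int(meta["seed"]),
    )
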