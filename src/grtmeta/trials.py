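"""Trial-level records from the two-stage metamemory task.

Each trial shows a stimulus (a face paired with a correct name, an
incorrect name, or a non-famous catch face with no correct answer) and
first asks for recall.  Successful recall terminates the trial, so only
recall failures carry the metacognitive (TOT/FOK) judgments, the binary
recognition response and the 4-level post-decision confidence rating.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import StimulusCondition

__all__ = ["TrialRecord", "CONDITION_CODES", "CONDITION_LABELS"]

CONDITION_CODES = {
    "correct_name": StimulusCondition.CORRECT_NAME,
    "incorrect_name": StimulusCondition.INCORRECT_NAME,
    "catch": StimulusCondition.CATCH,
}
CONDITION_LABELS = {v: k for k, v in CONDITION_CODES.items()}


@dataclass
class TrialRecord:
    """One behavioral trial.

    ``tot`` is "yes"/"no", ``fok`` is "high"/"low", ``recog_response`` is
    "correct"/"incorrect" (the participant's claim about the name shown),
    ``confidence4`` runs 1 ("not at all confident") to 4 ("very
    confident").  All four are None on recalled trials.
    ``recog_accurate`` is None on catch trials, which have no correct
    answer.
    """

    participant_id: str
    session: int
    block: int
    trial: int
    condition: StimulusCondition
    recalled: bool
    tot: str | None = None
    fok: str | None = None
    recog_response: str | None = None
    recog_accurate: bool | None = None
    confidence4: int | None = None

    def __post_init__(self) -> None:
        meta_fields = (self.tot, self.fok, self.recog_response, self.confidence4)
        if self.recalled:
            if any(v is not None for v in meta_fields) or self.recog_accurate is not None:
                raise ValueError(
                    "recalled trial must not carry metacognitive fields "
                    "(the trial terminates on successful recall)"
                )
        else:
            if any(v is None for v in meta_fields):
                raise ValueError(
                    "recall-failed trial must carry tot, fok, "
                    "recog_response and confidence4"
                )
            if self.tot not in ("yes", "no"):
                raise ValueError(f"invalid tot code {self.tot!r}")
            if self.fok not in ("high", "low"):
                raise ValueError(f"invalid fok code {self.fok!r}")
            if self.recog_response not in ("correct", "incorrect"):
                raise ValueError(
                    f"invalid recog_response code {self.recog_response!r}"
                )
            if self.confidence4 not in (1, 2, 3, 4):
                raise ValueError(
                    f"confidence4 must be 1..4, got {self.confidence4}"
                )
        if self.condition == StimulusCondition.CATCH:
            if self.recog_accurate is not None:
                raise ValueError("catch trials have no recognition accuracy")
            if self.recalled:
                raise ValueError("catch trials can never be recalled")
        elif not self.recalled:
            expected = (
                self.recog_response == "correct"
                if self.condition == StimulusCondition.CORRECT_NAME
                else self.recog_response == "incorrect"
            )
            if self.recog_accurate is None:
                self.recog_accurate = expected
            elif self.recog_accurate != expected:
                raise ValueError(
                    "recog_accurate inconsistent with condition and response"
                )
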