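"""Synthetic metamemory studies with known ground truth.

Emulates the two-stage celebrity-naming design: 600 trials per
participant (200 each of correct-name, incorrect-name and catch), recall
drop-out on famous trials, metacognitive judgments only on recall
failures, and catch trials that can never be recalled.  Behavioral
responses are generated from a ground-truth group model with
per-participant scaling and criteria, so every pipeline stage can be
exercised against known parameters.

Simplifications relative to real data (documented in the methods note):
recall success is an independent coin flip; a single metacognitive
evidence axis drives both TOT and FOK through offset criteria; the
4-level confidence rating is produced by splitting the two confidence
regions at fixed sub-criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import (
    GroupModel,
    ParticipantParams,
    StimulusCondition,
    participant_covariance,
)
from .trials import CONDITION_LABELS, TrialRecord

__all__ = [
    "StudyConfig",
    "default_group_model",
    "sample_population",
    "simulate_trials",
    "generate_study",
    "recovery_harness",
]

BLOCK_SIZE_PER_CONDITION = 10  # 10 trials of each condition per block
N_SESSIONS = 2


def default_group_model() -> GroupModel:
    """The default generating model: famous conditions at x = +/-1 with
    metacognitive mean 1, opposite-sign correlations (+0.5 / -0.5), catch
    at the origin with zero correlation.  Under this model confidence
    sensitivity grows with metacognitive evidence — the qualitative
    pattern the analysis is designed to detect."""
    return GroupModel(
        means=np.array([[1.0, 1.0], [-1.0, 1.0], [0.0, 0.0]]),
        correlations=np.array([0.5, -0.5, 0.0]),
    )


@dataclass
class StudyConfig:
    """Design and population parameters of a simulated study."""

    n_participants: int = 70
    trials_per_condition: int = 200
    recall_rate_famous: float = 0.35
    kappa_log_loc: float = float(np.log(2.0))
    kappa_log_sd: float = 0.3
    lam_range: tuple[float, float] = (0.35, 0.65)
    criterion_noise_sd: float = 0.3
    c_y_anchor: float = 0.5
    c_x1_anchor: float = -1.0
    c_x2_anchor: float = 1.0
    fok_offset: float = 0.4  # FOK criterion sits this far below the TOT one
    sub_split_confident: float = 0.6  # "very" vs "somewhat" confident
    sub_split_not: float = 0.35  # "not at all" vs "a little" confident
    group: GroupModel = field(default_factory=default_group_model)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.recall_rate_famous < 1.0:
            raise ValueError("recall_rate_famous must lie in [0, 1)")
        if not 0.0 < self.lam_range[0] < self.lam_range[1] < 1.0:
            raise ValueError("lam_range must be an interval inside (0, 1)")
        if self.criterion_noise_sd < 0:
            raise ValueError("criterion noise sd must be non-negative")
        if not self.c_x1_anchor < self.c_x2_anchor:
            raise ValueError("criterion anchors must satisfy c_x1 < c_x2")
        if self.fok_offset <= 0:
            raise ValueError("fok_offset must be positive")


def sample_population(config: StudyConfig, seed: int) -> list[ParticipantParams]:
    """Draw per-participant scaling and criteria from the population
    hyperpriors: log-normal kappa, uniform lambda, Gaussian criterion
    noise around the anchors (confidence criteria re-ordered if noise
    crosses them)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(config.n_participants):
        kappa = float(np.exp(rng.normal(config.kappa_log_loc, config.kappa_log_sd)))
        lam = float(rng.uniform(*config.lam_range))
        c_y = config.c_y_anchor + rng.normal(0.0, config.criterion_noise_sd)
        cx = np.sort(
            np.array([config.c_x1_anchor, config.c_x2_anchor])
            + rng.normal(0.0, config.criterion_noise_sd, size=2)
        )
        if cx[1] - cx[0] < 1e-6:
            cx[1] = cx[0] + 1e-6
        out.append(
            ParticipantParams(
                participant_id=f"p{i + 1:03d}",
                kappa=kappa,
                lam=lam,
                c_y=float(c_y),
                c_x1=float(cx[0]),
                c_x2=float(cx[1]),
            )
        )
    return out


def _confidence4(x: float, part: ParticipantParams, config: StudyConfig) -> int:
    """4-level rating from recognition evidence: the confident region
    (outside the criteria) splits into 3/4, the not-confident band into
    2 (near a criterion) / 1 (deep inside)."""
    if x > part.c_x2:
        return 4 if x > part.c_x2 + config.sub_split_confident else 3
    if x < part.c_x1:
        return 4 if x < part.c_x1 - config.sub_split_confident else 3
    return 1 if min(x - part.c_x1, part.c_x2 - x) > config.sub_split_not else 2


def simulate_trials(
    group: GroupModel,
    part: ParticipantParams,
    config: StudyConfig,
    seed: int,
) -> list[TrialRecord]:
    """Simulate one participant's full session set.

    Famous trials are recalled with probability ``recall_rate_famous``
    (independently of evidence); catch trials are never recalled.  On
    recall failure, bivariate evidence (x, y) is drawn from the
    participant's scaled distribution for that stimulus; TOT is reported
    iff y exceeds c_y, high FOK iff y exceeds c_y - fok_offset, the
    recognition response is "correct" iff x exceeds the criteria
    midpoint, and confidence is read off the x position.
    """
    rng = np.random.default_rng(seed)
    tpc = config.trials_per_condition
    n_blocks = max(1, (3 * tpc) // (3 * BLOCK_SIZE_PER_CONDITION))
    mid = 0.5 * (part.c_x1 + part.c_x2)

    # block structure: 10 trials per condition per block, shuffled
    per_block = [tpc // n_blocks] * n_blocks
    for i in range(tpc - sum(per_block)):
        per_block[i] += 1

    records: list[TrialRecord] = []
    trial_no = 0
    for b in range(n_blocks):
        conditions = [
            s for s in StimulusCondition for _ in range(per_block[b])
        ]
        rng.shuffle(conditions)
        session = 1 if b < n_blocks / N_SESSIONS else 2
        for cond in conditions:
            trial_no += 1
            cond = StimulusCondition(cond)
            famous = cond != StimulusCondition.CATCH
            if famous and rng.random() < config.recall_rate_famous:
                records.append(
                    TrialRecord(
                        participant_id=part.participant_id,
                        session=session,
                        block=b + 1,
                        trial=trial_no,
                        condition=cond,
                        recalled=True,
                    )
                )
                continue
            cov = participant_covariance(
                group.correlation(cond), part.kappa, part.lam
            )
            x, y = rng.multivariate_normal(group.mean(cond), cov)
            records.append(
                TrialRecord(
                    participant_id=part.participant_id,
                    session=session,
                    block=b + 1,
                    trial=trial_no,
                    condition=cond,
                    recalled=False,
                    tot="yes" if y > part.c_y else "no",
                    fok="high" if y > part.c_y - config.fok_offset else "low",
                    recog_response="correct" if x > mid else "incorrect",
                    confidence4=_confidence4(x, part, config),
                )
            )
    return records


def generate_study(
    config: StudyConfig,
) -> tuple[list[TrialRecord], dict]:
    """Full synthetic study: all participants' trials plus a serializable
    ground-truth record (group model, participant parameters, seeds)."""
    ss = np.random.SeedSequence(config.seed)
    pop_seed, *trial_seeds = ss.generate_state(config.n_participants + 1)
    participants = sample_population(config, int(pop_seed))
    trials: list[TrialRecord] = []
    for part, seed in zip(participants, trial_seeds):
        trials.extend(simulate_trials(config.group, part, config, int(seed)))
    truth = {
        "format": "grtmeta-ground-truth",
        "seed": config.seed,
        "group": {
            "means": config.group.means.tolist(),
            "correlations": config.group.correlations.tolist(),
        },
        "participants": [
            {
                "participant_id": p.participant_id,
                "kappa": p.kappa,
                "lam": p.lam,
                "c_y": p.c_y,
                "c_x1": p.c_x1,
                "c_x2": p.c_x2,
            }
            for p in participants
        ],
        "config": {
            k: v
            for k, v in asdict(config).items()
            if k != "group"
        },
    }
    return trials, truth


def truth_to_model(truth: dict):
    """Rebuild (GroupModel, participants) from a ground-truth record."""
    group = GroupModel(
        means=np.array(truth["group"]["means"]),
        correlations=np.array(truth["group"]["correlations"]),
    )
    parts = [ParticipantParams(**p) for p in truth["participants"]]
    return group, parts


def recovery_harness(
    config: StudyConfig,
    judgment: str = "TOT",
    n_restarts: int = 20,
    fit_seed: int = 0,
    curve_L_range: tuple[float, float] = (0.5, 5.0),
    curve_points: int = 101,
    metad_starts: int = 6,
) -> dict:
    """Parameter-recovery study: simulate, fit, and score.

    Both the fitted model and the ground truth are renormalized to the
    common scale anchor (geometric-mean kappa = 2) before comparison, so
    the score reflects genuine recovery rather than the arbitrary overall
    scale of the evidence space.  SvM curves are compared as functions of
    the relative likelihood L on ``curve_L_range``.
    """
    from .fitting import FittedModel, anchor_model, fit_grt_wind
    from .io import aggregate_counts
    from .svm import build_svm_curve, relative_likelihood

    trials, truth = generate_study(config)
    tables = aggregate_counts(trials, judgment=judgment)
    fitted = fit_grt_wind(tables, n_restarts=n_restarts, seed=fit_seed)

    true_group, true_parts = truth_to_model(truth)
    true_group, true_parts = anchor_model(true_group, true_parts)
    true_model = FittedModel(
        group=true_group,
        participants=true_parts,
        loglik=np.nan,
        n_restarts_used=0,
        restart_logliks=[],
        converged=[],
        judgment=judgment,
    )

    free_true = np.concatenate(
        [true_group.means[0], true_group.means[1]]
    )
    free_fit = np.concatenate(
        [fitted.group.means[0], fitted.group.means[1]]
    )
    mean_rmse = float(np.sqrt(np.mean((free_fit - free_true) ** 2)))
    rho_err = fitted.group.correlations - true_group.correlations

    curve_fit = build_svm_curve(
        fitted, n_points=curve_points, metad_starts=metad_starts
    )
    curve_true = build_svm_curve(
        true_model, n_points=curve_points, metad_starts=metad_starts
    )
    L_grid = np.geomspace(*curve_L_range, 51)
    md_fit = np.interp(L_grid, curve_fit.rel_likelihood, curve_fit.meta_d)
    md_true = np.interp(L_grid, curve_true.rel_likelihood, curve_true.meta_d)
    curve_err = np.abs(md_fit - md_true)

    return {
        "judgment": judgment,
        "group_mean_rmse": mean_rmse,
        "rho_errors": rho_err.tolist(),
        "rho_max_abs_error": float(np.max(np.abs(rho_err))),
        "curve_L_grid": L_grid.tolist(),
        "curve_abs_errors": curve_err.tolist(),
        "curve_max_abs_error": float(np.max(curve_err)),
        "curve_rmse": float(np.sqrt(np.mean(curve_err**2))),
        "pct_variance": fitted.pct_variance,
        "fitted": fitted,
        "true_model": true_model,
        "curve_fit": curve_fit,
        "curve_true": curve_true,
    }
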