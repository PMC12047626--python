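"""Type-2 sensitivity-versus-metacognition (SvM) analysis.

From a fitted group model this module derives, for every level ``y`` of
metacognitive evidence:

* the relative likelihood ``L(y)`` that a famous-condition trial (true
  TOT/FOK evidence) rather than a catch trial produced that evidence —
  the x-axis of the SvM curve;
* the conditional meta-d': the sensitivity of an equal-variance signal
  detection observer whose three-category confidence probabilities best
  match the model-implied conditional confidence probabilities at that
  evidence level — the y-axis of the curve;

together with the objective criterion ``y*`` where ``L(y*) = 1``, i.e.
the boundary an optimal observer would use to categorize their own
metacognitive states, and the positions of individual participants'
metacognitive criteria on the likelihood axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .fitting import FittedModel
from .model import GroupModel, ParticipantParams, StimulusCondition

__all__ = [
    "SDTFit",
    "SvMCurve",
    "relative_likelihood",
    "objective_criterion",
    "conditional_distribution",
    "conditional_category_probs",
    "fit_conditional_metad",
    "aggregate_reference_criteria",
    "build_svm_curve",
]

_FAMOUS = (StimulusCondition.CORRECT_NAME, StimulusCondition.INCORRECT_NAME)


@dataclass
class SDTFit:
    """Equal-variance SDT observer explaining conditional confidence data."""

    meta_d: float
    t1: float
    t2: float
    loss: float

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError("type-2 criteria must satisfy t1 < t2")
        if self.loss < 0:
            raise ValueError("loss must be non-negative")


@dataclass
class SvMCurve:
    """The SvM curve on a grid of metacognitive-evidence values."""

    y_grid: np.ndarray
    rel_likelihood: np.ndarray
    meta_d: np.ndarray
    y_star: float
    L_star: float
    participant_positions: np.ndarray
    judgment: str = "TOT"

    def __post_init__(self) -> None:
        self.y_grid = np.asarray(self.y_grid, dtype=float)
        self.rel_likelihood = np.asarray(self.rel_likelihood, dtype=float)
        self.meta_d = np.asarray(self.meta_d, dtype=float)
        self.participant_positions = np.asarray(
            self.participant_positions, dtype=float
        )
        if np.any(np.diff(self.y_grid) <= 0):
            raise ValueError("y_grid must be strictly increasing")
        if np.any(self.rel_likelihood <= 0):
            raise ValueError("relative likelihood must be strictly positive")
        if abs(self.L_star - 1.0) > 1e-8:
            raise ValueError("L at the objective criterion must equal 1")


def relative_likelihood(group: GroupModel, y) -> np.ndarray | float:
    """L(y): famous-condition metacognitive-evidence density over catch.

    The numerator is the equal-weight mixture of the correct-name and
    incorrect-name marginal densities on the metacognitive axis (both
    conditions are presented equally often); the denominator is the catch
    marginal.  Group-level unit variances throughout.
    """
    y_arr = np.asarray(y, dtype=float)
    mu_c = group.mean(StimulusCondition.CORRECT_NAME)[1]
    mu_i = group.mean(StimulusCondition.INCORRECT_NAME)[1]
    num = 0.5 * stats.norm.pdf(y_arr, mu_c, 1.0) + 0.5 * stats.norm.pdf(
        y_arr, mu_i, 1.0
    )
    out = num / stats.norm.pdf(y_arr, 0.0, 1.0)
    return float(out) if np.isscalar(y) else out


def objective_criterion(group: GroupModel) -> float:
    """The evidence level y* where L(y*) = 1.

    Located by bracketed root finding on a dense scan of
    [-10, max famous mu_y + 10].  When the famous metacognitive means
    differ, L(y) = 1 can in principle have several roots; the largest is
    returned (the operative low/high boundary in the right tail) with a
    warning.
    """
    mu_y = [group.mean(s)[1] for s in _FAMOUS]
    if max(mu_y) <= 0:
        raise ValueError(
            "no unique objective criterion: both famous metacognitive "
            "means are non-positive"
        )
    lo, hi = -10.0, max(mu_y) + 10.0
    ys = np.linspace(lo, hi, 4001)
    g = np.log(relative_likelihood(group, ys))
    sign_change = np.nonzero(np.diff(np.signbit(g)))[0]
    roots = []
    for i in sign_change:
        roots.append(
            optimize.brentq(
                lambda y: np.log(relative_likelihood(group, y)),
                ys[i],
                ys[i + 1],
                xtol=1e-10,
            )
        )
    # include exact grid hits
    roots.extend(ys[np.abs(g) < 1e-14])
    if not roots:
        raise ValueError("L(y) = 1 has no root in the search interval")
    roots = sorted(set(round(r, 12) for r in roots))
    if len(roots) > 1:
        warnings.warn(
            f"L(y)=1 has {len(roots)} roots; returning the largest",
            stacklevel=2,
        )
    return float(roots[-1])


def conditional_distribution(
    group: GroupModel, stimulus: StimulusCondition, y: float
) -> tuple[float, float]:
    """Mean and SD of recognition evidence x given metacognitive level y.

    Gaussian conditioning with unit marginal variances:
    mean = mu_x + rho * (y - mu_y), sd = sqrt(1 - rho^2).
    """
    mu = group.mean(stimulus)
    rho = group.correlation(stimulus)
    return mu[0] + rho * (y - mu[1]), float(np.sqrt(1.0 - rho * rho))


def conditional_category_probs(
    dist: tuple[float, float], c_x1: float, c_x2: float
) -> np.ndarray:
    """Three confidence-category probabilities for an N(mean, sd) slice."""
    if not c_x1 < c_x2:
        raise ValueError("confidence criteria must satisfy c_x1 < c_x2")
    m, s = dist
    if not s > 0:
        raise ValueError("sd must be positive")
    z1 = special.ndtr((c_x1 - m) / s)
    z2 = special.ndtr((c_x2 - m) / s)
    return np.array([z1, z2 - z1, 1.0 - z2])


# ---------------------------------------------------------------------------
# Conditional meta-d'
# ---------------------------------------------------------------------------

def _sdt_probs(d: float, t1: float, t2: float) -> np.ndarray:
    """6 category probabilities of the equal-variance SDT observer:
    rows (correct-name analog at +d/2, incorrect-name analog at -d/2)."""
    out = np.empty((2, 3))
    for row, m in enumerate((d / 2.0, -d / 2.0)):
        z1 = special.ndtr(t1 - m)
        z2 = special.ndtr(t2 - m)
        out[row] = (z1, z2 - z1, 1.0 - z2)
    return out


def _target_probs(group, ref_criteria, y):
    c1, c2 = ref_criteria
    return np.stack(
        [
            conditional_category_probs(
                conditional_distribution(group, s, y), c1, c2
            )
            for s in _FAMOUS
        ]
    )


def _moment_start(target: np.ndarray) -> np.ndarray:
    """Closed-form start from inverting the outer-category probabilities."""
    p = np.clip(target, 1e-9, 1 - 1e-9)
    z_hi = special.ndtri(1.0 - p[:, 2])  # t2 - m for each stimulus
    z_lo = special.ndtri(p[:, 0])  # t1 - m
    d0 = float(z_hi[1] - z_hi[0])
    t2 = float(np.mean([z_hi[0] + d0 / 2.0, z_hi[1] - d0 / 2.0]))
    t1 = float(np.mean([z_lo[0] + d0 / 2.0, z_lo[1] - d0 / 2.0]))
    if t2 - t1 < 1e-6:
        mid = 0.5 * (t1 + t2)
        t1, t2 = mid - 5e-7, mid + 5e-7
    return np.array([d0, t1, np.log(t2 - t1)])


def fit_conditional_metad(
    group: GroupModel,
    ref_criteria: tuple[float, float],
    y: float,
    n_starts: int = 10,
    seed: int = 0,
    loss: str = "lsq",
    extra_starts=None,
) -> SDTFit:
    """Conditional meta-d' at metacognitive evidence level ``y``.

    Finds the equal-variance SDT observer (stimulus means at +/- meta_d/2,
    unit SDs, free type-2 criteria t1 < t2) whose three-category
    confidence probabilities best match the model-implied conditional
    probabilities for the two famous conditions.  Discrepancy is
    unweighted least squares over the six probabilities by default
    (``loss="kl"`` uses the Kullback-Leibler divergence instead).  Local
    optimization from ``n_starts`` starting points (one moment-based, the
    rest randomized deterministically from ``seed``); best fit wins.

    meta_d is positive when confident-correct responses are more probable
    under the correct-name condition.
    """
    target = _target_probs(group, ref_criteria, y)

    if loss == "lsq":
        def residuals(v):
            d, t1, g = v
            return (_sdt_probs(d, t1, t1 + np.exp(g)) - target).ravel()
    elif loss == "kl":
        tgt = np.clip(target, 1e-12, 1.0)

        def residuals(v):
            d, t1, g = v
            q = np.clip(_sdt_probs(d, t1, t1 + np.exp(g)), 1e-12, 1.0)
            # per-cell sqrt of the KL integrand so least_squares minimizes KL
            return np.sqrt(np.maximum(tgt * np.log(tgt / q), 0.0)).ravel()
    else:
        raise ValueError(f"unknown loss {loss!r}")

    starts = [_moment_start(target)]
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        starts.append(
            np.array(
                [
                    rng.uniform(-4, 4),
                    rng.uniform(-3, 1),
                    np.log(rng.uniform(0.1, 4.0)),
                ]
            )
        )

    best = None
    for x0 in starts[:max(n_starts, len(starts))]:
        try:
            res = optimize.least_squares(
                residuals, x0, method="lm", xtol=1e-12, ftol=1e-14
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("conditional meta-d' optimization failed at all starts")
    d, t1, g = best.x
    return SDTFit(
        meta_d=float(d),
        t1=float(t1),
        t2=float(t1 + np.exp(g)),
        loss=float(np.sum(residuals(best.x) ** 2)),
    )


# ---------------------------------------------------------------------------
# Group-level reference criteria and the curve
# ---------------------------------------------------------------------------

def aggregate_reference_criteria(participants) -> tuple[float, float]:
    """Group-level confidence criteria: arithmetic mean of participants'
    criteria after rescaling each into unit-variance group coordinates
    (multiply x-criteria by sqrt(kappa * lambda))."""
    c1s, c2s = [], []
    for p in participants:
        s = np.sqrt(p.kappa * p.lam)
        c1s.append(p.c_x1 * s)
        c2s.append(p.c_x2 * s)
    return float(np.mean(c1s)), float(np.mean(c2s))


def participant_criterion_positions(
    group: GroupModel, participants
) -> np.ndarray:
    """Relative-likelihood coordinates of participants' metacognitive
    criteria (each c_y rescaled by sqrt(kappa * (1 - lambda)))."""
    ys = np.array(
        [p.c_y * np.sqrt(p.kappa * (1.0 - p.lam)) for p in participants]
    )
    return np.asarray(relative_likelihood(group, ys))


def build_svm_curve(
    fitted: FittedModel,
    n_points: int = 201,
    y_range: tuple[float, float] | None = None,
    metad_starts: int = 10,
    metad_seed: int = 0,
    loss: str = "lsq",
) -> SvMCurve:
    """Construct the type-2 SvM curve from a fitted model.

    The default grid spans [-3, max famous mu_y + 3] with 201 points,
    covering essentially all marginal evidence mass.  Each grid point's
    meta-d' fit reuses the previous point's solution as an extra warm
    start, which keeps the curve continuous in practice.
    """
    group = fitted.group
    if y_range is None:
        mu_y_max = max(group.mean(s)[1] for s in _FAMOUS)
        y_range = (-3.0, mu_y_max + 3.0)
    y_grid = np.linspace(y_range[0], y_range[1], n_points)

    y_star = objective_criterion(group)
    ref = aggregate_reference_criteria(fitted.participants)

    L = np.asarray(relative_likelihood(group, y_grid))
    meta_d = np.empty(n_points)
    prev = None
    for i, y in enumerate(y_grid):
        sdt = fit_conditional_metad(
            group,
            ref,
            y,
            n_starts=metad_starts,
            seed=metad_seed,
            loss=loss,
            extra_starts=None if prev is None else [prev],
        )
        meta_d[i] = sdt.meta_d
        prev = np.array([sdt.meta_d, sdt.t1, np.log(sdt.t2 - sdt.t1)])

    return SvMCurve(
        y_grid=y_grid,
        rel_likelihood=L,
        meta_d=meta_d,
        y_star=y_star,
        L_star=float(relative_likelihood(group, y_star)),
        participant_positions=participant_criterion_positions(
            group, fitted.participants
        ),
        judgment=fitted.judgment,
    )
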