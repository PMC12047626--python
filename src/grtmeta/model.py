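"""Core two-dimensional GRT decision space.

The model places one bivariate Gaussian per stimulus condition in a plane
whose x-axis carries recognition/confidence evidence and whose y-axis
carries metacognitive (TOT or FOK) evidence.  The catch condition anchors
the space at the origin and all marginal variances are fixed at one at the
group level; individual differences enter only through a per-participant
rescaling of the space (global attention ``kappa`` and dimensional share
``lambda``) and per-participant decision criteria.

Decisional separability is assumed on both axes, so the three criteria
(one horizontal metacognitive criterion, two vertical confidence criteria)
cut the plane into 2 x 3 axis-aligned rectangles; response probabilities
are therefore exact bivariate-normal rectangle probabilities, computed
here through Owen's T function rather than generic numerical integration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "StimulusCondition",
    "MetacogResponse",
    "ConfCategory",
    "JointResponse",
    "JOINT_RESPONSES",
    "GroupModel",
    "ParticipantParams",
    "CountTable",
    "participant_covariance",
    "bvn_cdf",
    "rectangle_probability",
    "cell_probabilities",
    "log_likelihood",
]

# Floor applied to cell probabilities before taking logs, keeping the
# objective finite when the optimizer wanders into regions where a cell
# with observed counts has vanishing probability.
PROB_FLOOR = 1e-300


class StimulusCondition(enum.IntEnum):
    """The three stimulus roles of the two-stage metamemory design."""

    CORRECT_NAME = 0
    INCORRECT_NAME = 1
    CATCH = 2


class MetacogResponse(enum.IntEnum):
    """Binary metacognitive report: TOT yes/no or FOK high/low."""

    ABSENT = 0
    PRESENT = 1


class ConfCategory(enum.IntEnum):
    """Three-way confidence-by-recognition category on the x-axis."""

    CONF_INCORRECT = 0  # confident that the recognition answer was wrong
    NOT_CONF = 1        # not confident, either recognition response
    CONF_CORRECT = 2    # confident that the recognition answer was right


@dataclass(frozen=True)
class JointResponse:
    metacog: MetacogResponse
    confcat: ConfCategory

    @property
    def index(self) -> int:
        """Position in the canonical 6-cell ordering."""
        return 3 * int(self.metacog) + int(self.confcat)


#: Canonical ordering of the six joint response cells: metacog-absent
#: cells first, confidence categories left to right within each half.
JOINT_RESPONSES: tuple[JointResponse, ...] = tuple(
    JointResponse(m, c) for m in MetacogResponse for c in ConfCategory
)

N_CELLS = len(JOINT_RESPONSES)
N_STIMULI = len(StimulusCondition)


@dataclass
class GroupModel:
    """Group-level stimulus distributions shared by all participants.

    Parameters
    ----------
    means : array-like, shape (3, 2)
        Per-stimulus (mu_x, mu_y), ordered CORRECT_NAME, INCORRECT_NAME,
        CATCH.  The catch mean must be exactly (0, 0).
    correlations : array-like, shape (3,)
        Per-stimulus correlation rho, each strictly inside (-1, 1).

    Marginal variances are identically 1 and are not parameters.
    """

    means: np.ndarray
    correlations: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if self.means.shape != (N_STIMULI, 2):
            raise ValueError(f"means must have shape (3, 2), got {self.means.shape}")
        if self.correlations.shape != (N_STIMULI,):
            raise ValueError(
                f"correlations must have shape (3,), got {self.correlations.shape}"
            )
        if not np.allclose(self.means[StimulusCondition.CATCH], 0.0, atol=1e-12):
            raise ValueError("catch-condition mean must be fixed at the origin")
        if np.any(np.abs(self.correlations) >= 1.0):
            raise ValueError("correlations must satisfy |rho| < 1")

    def mean(self, stimulus: StimulusCondition) -> np.ndarray:
        return self.means[int(stimulus)]

    def correlation(self, stimulus: StimulusCondition) -> float:
        return float(self.correlations[int(stimulus)])


@dataclass
class ParticipantParams:
    """Per-participant scaling and decision criteria.

    ``kappa`` scales overall evidence precision (larger = less noise),
    ``lam`` splits it between the two axes.  ``c_y`` is the metacognitive
    criterion (report PRESENT iff y > c_y); ``c_x1 < c_x2`` bound the
    not-confident band on the recognition axis.
    """

    participant_id: str
    kappa: float
    lam: float
    c_y: float
    c_x1: float
    c_x2: float

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"lam must lie in (0, 1), got {self.lam}")
        if not self.c_x1 < self.c_x2:
            raise ValueError(
                f"confidence criteria must satisfy c_x1 < c_x2, "
                f"got {self.c_x1} >= {self.c_x2}"
            )

    @property
    def sd_x(self) -> float:
        """Perceptual noise SD on the recognition axis, 1/sqrt(kappa*lam)."""
        return 1.0 / math.sqrt(self.kappa * self.lam)

    @property
    def sd_y(self) -> float:
        """Perceptual noise SD on the metacognitive axis."""
        return 1.0 / math.sqrt(self.kappa * (1.0 - self.lam))


@dataclass
class CountTable:
    """3 x 6 multinomial response counts for one participant.

    Rows follow :class:`StimulusCondition` order, columns the canonical
    :data:`JOINT_RESPONSES` order.
    """

    participant_id: str
    counts: np.ndarray
    judgment: str = "TOT"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_STIMULI, N_CELLS):
            raise ValueError(
                f"counts must have shape (3, 6), got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) == 0):
            raise ValueError(
                f"participant {self.participant_id}: every stimulus row "
                "needs at least one observation"
            )

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def participant_covariance(rho: float, kappa: float, lam: float) -> np.ndarray:
    """Perceptual covariance matrix a participant assigns to a stimulus.

    Var_x = 1/(kappa*lam), Var_y = 1/(kappa*(1-lam)), correlation rho.
    """
    if not kappa > 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lam must lie in (0, 1), got {lam}")
    if not abs(rho) < 1.0:
        raise ValueError(f"rho must satisfy |rho| < 1, got {rho}")
    var_x = 1.0 / (kappa * lam)
    var_y = 1.0 / (kappa * (1.0 - lam))
    cov = rho * math.sqrt(var_x * var_y)
    return np.array([[var_x, cov], [cov, var_y]])


# ---------------------------------------------------------------------------
# Bivariate normal CDF via Owen's T function
# ---------------------------------------------------------------------------

# Beyond this many standard deviations the univariate CDF is 0 or 1 to
# double precision; clipping lets callers pass +/-inf bounds.
_CLIP = 37.5
_EPS0 = 1e-13


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normals with correlation rho.

    Exact (to double precision) via Owen's T function; fully vectorized.
    """
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)

    # Exact zeros break the a_h/a_k ratios; nudging is loss-free because
    # the CDF is continuous and owens_t handles huge second arguments.
    h = np.where(np.abs(h) < _EPS0, _EPS0, h)
    k = np.where(np.abs(k) < _EPS0, _EPS0, k)

    denom = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    # correction term: 1/2 when h and k lie on opposite sides of zero
    # (exact zeros were nudged to +eps above, which matches the h+k sign
    # rule of the hk = 0 case)
    beta = np.where(h * k < 0, 0.5, 0.0)
    phi_h = special.ndtr(h)
    phi_k = special.ndtr(k)
    out = (
        0.5 * (phi_h + phi_k)
        - special.owens_t(h, a_h)
        - special.owens_t(k, a_k)
        - beta
    )
    return np.clip(out, 0.0, 1.0)


def rectangle_probability(
    mean, cov, x_lo: float, x_hi: float, y_lo: float, y_hi: float
) -> float:
    """Probability of an axis-aligned rectangle under a bivariate normal.

    Bounds may be infinite.  Absolute accuracy is far better than 1e-7
    (the Owen's T route is exact to roundoff).
    """
    if x_lo > x_hi or y_lo > y_hi:
        raise ValueError("rectangle bounds are inverted")
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric 2x2")
    var_x, var_y = cov[0, 0], cov[1, 1]
    det = var_x * var_y - cov[0, 1] ** 2
    if var_x <= 0 or var_y <= 0 or det <= 0:
        raise ValueError("covariance must be symmetric positive definite")
    sx, sy = math.sqrt(var_x), math.sqrt(var_y)
    rho = cov[0, 1] / (sx * sy)

    hx = np.array([(x_lo - mean[0]) / sx, (x_hi - mean[0]) / sx])
    hy = np.array([(y_lo - mean[1]) / sy, (y_hi - mean[1]) / sy])
    grid = bvn_cdf(hx[:, None], hy[None, :], rho)
    p = grid[1, 1] - grid[0, 1] - grid[1, 0] + grid[0, 0]
    return float(min(max(p, 0.0), 1.0))


def _standardized_edges(
    group: GroupModel, part: ParticipantParams
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized x- and y-criterion edges per stimulus.

    Returns (hx, hy) with shapes (3, 4) and (3, 3): confidence-category
    edges (-inf, c_x1, c_x2, inf) and metacognitive edges (-inf, c_y, inf),
    centred on each stimulus mean and scaled by the participant's noise.
    """
    sx, sy = part.sd_x, part.sd_y
    x_edges = np.array([-np.inf, part.c_x1, part.c_x2, np.inf])
    y_edges = np.array([-np.inf, part.c_y, np.inf])
    hx = (x_edges[None, :] - group.means[:, [0]]) / sx
    hy = (y_edges[None, :] - group.means[:, [1]]) / sy
    return hx, hy


def cell_probabilities(
    group: GroupModel, part: ParticipantParams, stimulus: StimulusCondition
) -> np.ndarray:
    """The six joint-response probabilities for one stimulus condition.

    Ordered as :data:`JOINT_RESPONSES`: (ABSENT, PRESENT) x
    (CONF_INCORRECT, NOT_CONF, CONF_CORRECT).  Sums to 1.
    """
    hx, hy = _standardized_edges(group, part)
    s = int(stimulus)
    rho = group.correlations[s]
    grid = bvn_cdf(hx[s][:, None], hy[s][None, :], rho)  # (4 x-edges, 3 y-edges)
    # rectangle prob for x-cell j, y-cell i
    rect = (
        grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    )  # (3 x-cells, 2 y-cells)
    probs = np.empty(N_CELLS)
    for jr in JOINT_RESPONSES:
        probs[jr.index] = rect[int(jr.confcat), int(jr.metacog)]
    return np.clip(probs, 0.0, 1.0)


def log_likelihood(
    group: GroupModel,
    parts,
    data,
) -> float:
    """Multinomial log-likelihood of count tables under the model.

    Sums n * log(p) over participants, stimuli and cells; the multinomial
    coefficient (constant in the parameters) is omitted.  Probabilities
    are floored at 1e-300 so a positive count on a numerically-zero cell
    yields a very large negative value rather than -inf.
    """
    parts = list(parts)
    data = list(data)
    if len(parts) != len(data):
        raise ValueError(
            f"{len(parts)} parameter sets for {len(data)} count tables"
        )
    by_id = {p.participant_id: p for p in parts}
    if len(by_id) != len(parts):
        raise ValueError("duplicate participant ids in parameter collection")
    total = 0.0
    for table in data:
        part = by_id.get(table.participant_id)
        if part is None:
            raise ValueError(
                f"no parameters for participant {table.participant_id!r}"
            )
        for stim in StimulusCondition:
            row = table.counts[int(stim)]
            if not row.any():
                continue
            p = np.maximum(cell_probabilities(group, part, stim), PROB_FLOOR)
            total += float(np.dot(row, np.log(p)))
    return total
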