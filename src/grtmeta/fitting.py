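"""Maximum-likelihood estimation of the group model and all participants.

The full parameter vector stacks 4 free group means (catch is pinned to
the origin), 3 stimulus correlations and 5 numbers per participant, all
mapped to an unconstrained scale (atanh for correlations, log for kappa,
logit for lambda, log-gap for the ordered confidence criteria).  The
likelihood is maximized by L-BFGS-B from many random starting points and
the best restart is kept.

Two identifiability conventions are applied to the returned model:

* the overall spatial scale — invisible to the likelihood because means,
  criteria and the kappa scalings can absorb a common stretch — is pinned
  by renormalizing so the geometric mean of the kappas equals 2 (the
  "neutral" value at which a lambda=0.5 participant has unit noise);
* the starting distribution places the correct-name mean on the positive
  x side, so fitted models follow that axis convention whenever the data
  support it.

The objective is evaluated in a batched form (many parameter vectors at
once) so that finite-difference gradients cost a single vectorized pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .model import (
    N_CELLS,
    N_STIMULI,
    PROB_FLOOR,
    CountTable,
    GroupModel,
    ParticipantParams,
    StimulusCondition,
)

__all__ = [
    "FittedModel",
    "FitError",
    "pack_parameters",
    "unpack_parameters",
    "random_start",
    "fit_grt_wind",
    "variance_accounted",
    "predicted_probabilities",
    "apply_scale",
    "apply_axis_scale",
    "anchor_model",
]

N_GROUP_PARAMS = 7  # 4 free means + 3 correlations
N_PER_PARTICIPANT = 5  # log kappa, logit lambda, c_y, c_x1, log gap

KAPPA_ANCHOR = 2.0


class FitError(RuntimeError):
    """Raised when no optimization restart converges."""


@dataclass
class FittedModel:
    """Result of a GRT-wIND fit: best model over all restarts."""

    group: GroupModel
    participants: list[ParticipantParams]
    loglik: float
    n_restarts_used: int
    restart_logliks: list[float]
    converged: list[bool]
    pct_variance: float | None = None
    judgment: str = "TOT"
    seed: int | None = None

    def params_for(self, participant_id: str) -> ParticipantParams:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "grtmeta-fitted-model",
            "version": 1,
            "judgment": self.judgment,
            "seed": self.seed,
            "group": {
                "means": self.group.means.tolist(),
                "correlations": self.group.correlations.tolist(),
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
                for p in self.participants
            ],
            "loglik": self.loglik,
            "n_restarts_used": self.n_restarts_used,
            "restart_logliks": self.restart_logliks,
            "converged": self.converged,
            "pct_variance": self.pct_variance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        group = GroupModel(
            means=np.array(d["group"]["means"]),
            correlations=np.array(d["group"]["correlations"]),
        )
        parts = [ParticipantParams(**p) for p in d["participants"]]
        return cls(
            group=group,
            participants=parts,
            loglik=d["loglik"],
            n_restarts_used=d["n_restarts_used"],
            restart_logliks=list(d["restart_logliks"]),
            converged=list(d["converged"]),
            pct_variance=d.get("pct_variance"),
            judgment=d.get("judgment", "TOT"),
            seed=d.get("seed"),
        )

    @classmethod
    def from_json(cls, source) -> "FittedModel":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------

def n_parameters(n_participants: int) -> int:
    return N_GROUP_PARAMS + N_PER_PARTICIPANT * n_participants


def pack_parameters(group: GroupModel, parts) -> np.ndarray:
    """Map a (group, participants) pair to the unconstrained vector."""
    parts = list(parts)
    theta = np.empty(n_parameters(len(parts)))
    mc = group.mean(StimulusCondition.CORRECT_NAME)
    mi = group.mean(StimulusCondition.INCORRECT_NAME)
    theta[0:4] = [mc[0], mc[1], mi[0], mi[1]]
    theta[4:7] = np.arctanh(group.correlations)
    for i, p in enumerate(parts):
        o = N_GROUP_PARAMS + N_PER_PARTICIPANT * i
        theta[o] = np.log(p.kappa)
        theta[o + 1] = special.logit(p.lam)
        theta[o + 2] = p.c_y
        theta[o + 3] = p.c_x1
        theta[o + 4] = np.log(p.c_x2 - p.c_x1)
    return theta


def unpack_parameters(
    theta: np.ndarray, n_participants: int, participant_ids=None
) -> tuple[GroupModel, list[ParticipantParams]]:
    """Inverse of :func:`pack_parameters`."""
    theta = np.asarray(theta, dtype=float)
    expected = n_parameters(n_participants)
    if theta.shape != (expected,):
        raise ValueError(
            f"parameter vector has length {theta.size}, expected {expected} "
            f"for {n_participants} participants"
        )
    if participant_ids is None:
        participant_ids = [f"p{i}" for i in range(n_participants)]
    means = np.zeros((N_STIMULI, 2))
    means[StimulusCondition.CORRECT_NAME] = theta[0:2]
    means[StimulusCondition.INCORRECT_NAME] = theta[2:4]
    group = GroupModel(means=means, correlations=np.tanh(theta[4:7]))
    parts = []
    for i, pid in enumerate(participant_ids):
        o = N_GROUP_PARAMS + N_PER_PARTICIPANT * i
        c_x1 = theta[o + 3]
        parts.append(
            ParticipantParams(
                participant_id=pid,
                kappa=float(np.exp(theta[o])),
                lam=float(special.expit(theta[o + 1])),
                c_y=float(theta[o + 2]),
                c_x1=float(c_x1),
                c_x2=float(c_x1 + np.exp(theta[o + 4])),
            )
        )
    return group, parts


# ---------------------------------------------------------------------------
# Batched negative log-likelihood
# ---------------------------------------------------------------------------

_CLIP = 37.5
_EPS0 = 1e-13


def _bvn_cdf_raw(h, k, rho):
    # same Owen's-T construction as model.bvn_cdf, without re-broadcasting
    h = np.clip(h, -_CLIP, _CLIP)
    k = np.clip(k, -_CLIP, _CLIP)
    h = np.where(np.abs(h) < _EPS0, _EPS0, h)
    k = np.where(np.abs(k) < _EPS0, _EPS0, k)
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    beta = np.where(h * k < 0, 0.5, 0.0)
    return (
        0.5 * (special.ndtr(h) + special.ndtr(k))
        - special.owens_t(h, a_h)
        - special.owens_t(k, a_k)
        - beta
    )


def _batched_cell_probs(theta: np.ndarray, n_p: int) -> np.ndarray:
    """Cell probabilities for a batch of parameter vectors.

    Parameters
    ----------
    theta : (B, D) array of unconstrained parameter vectors.

    Returns
    -------
    (B, n_p, 3, 6) probabilities in canonical cell order.
    """
    B = theta.shape[0]
    mu = np.zeros((B, N_STIMULI, 2))
    mu[:, 0, 0] = theta[:, 0]
    mu[:, 0, 1] = theta[:, 1]
    mu[:, 1, 0] = theta[:, 2]
    mu[:, 1, 1] = theta[:, 3]
    rho = np.tanh(theta[:, 4:7])  # (B, 3)

    # clip unconstrained coordinates so extreme optimizer excursions
    # saturate instead of overflowing to inf/nan
    pp = theta[:, N_GROUP_PARAMS:].reshape(B, n_p, N_PER_PARTICIPANT)
    kappa = np.exp(np.clip(pp[..., 0], -60.0, 60.0))
    lam = np.clip(special.expit(pp[..., 1]), 1e-12, 1.0 - 1e-12)
    c_y = pp[..., 2]
    c_x1 = pp[..., 3]
    c_x2 = c_x1 + np.exp(np.clip(pp[..., 4], -60.0, 60.0))
    sx = 1.0 / np.sqrt(kappa * lam)  # (B, n_p)
    sy = 1.0 / np.sqrt(kappa * (1.0 - lam))

    # standardized interior criterion positions per stimulus:
    # hx1, hx2 at the two confidence criteria, hy at the metacognitive one
    hx1 = (c_x1[:, :, None] - mu[:, None, :, 0]) / sx[:, :, None]
    hx2 = (c_x2[:, :, None] - mu[:, None, :, 0]) / sx[:, :, None]
    hy = (c_y[:, :, None] - mu[:, None, :, 1]) / sy[:, :, None]
    r = rho[:, None, :]

    # only the two interior grid nodes need the bivariate CDF; all other
    # rectangle corners involve an infinite edge and reduce to ndtr
    b11 = _bvn_cdf_raw(hx1, hy, r)  # F(c_x1, c_y)
    b21 = _bvn_cdf_raw(hx2, hy, r)  # F(c_x2, c_y)
    fx1 = special.ndtr(np.clip(hx1, -_CLIP, _CLIP))
    fx2 = special.ndtr(np.clip(hx2, -_CLIP, _CLIP))
    fy = special.ndtr(np.clip(hy, -_CLIP, _CLIP))

    probs = np.empty((B, n_p, N_STIMULI, N_CELLS))
    probs[..., 0] = b11                    # ABSENT, CONF_INCORRECT
    probs[..., 1] = b21 - b11              # ABSENT, NOT_CONF
    probs[..., 2] = fy - b21               # ABSENT, CONF_CORRECT
    probs[..., 3] = fx1 - b11              # PRESENT, CONF_INCORRECT
    probs[..., 4] = (fx2 - fx1) - (b21 - b11)  # PRESENT, NOT_CONF
    probs[..., 5] = 1.0 - fx2 - (fy - b21)     # PRESENT, CONF_CORRECT
    return np.clip(probs, 0.0, 1.0)


# Cell probabilities are differences of bivariate CDF values, so their
# absolute accuracy bottoms out near 1e-15; below that the computed value
# flickers between 0 and roundoff junk as parameters move.  An additive
# regularizer at that scale keeps log(p) smooth (essential for the
# quasi-Newton line search) and is far below any probability an observed
# count can attain at an optimum.
_PROB_REG = 1e-12


def _nll_batch(theta: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Negative log-likelihoods for a (B, D) batch given (n, 3, 6) counts."""
    n_p = counts.shape[0]
    with np.errstate(all="ignore"):
        probs = _batched_cell_probs(theta, n_p)
        probs = np.nan_to_num(probs, nan=0.0) + _PROB_REG
        nll = -np.einsum("sjk,bsjk->b", counts.astype(float), np.log(probs))
    return np.nan_to_num(nll, nan=1e300, posinf=1e300)


def _make_objective(counts: np.ndarray):
    """Objective returning (value, gradient) via one batched forward pass."""
    n_p = counts.shape[0]
    dim = n_parameters(n_p)
    steps_scale = np.cbrt(np.finfo(float).eps)  # central-difference optimum

    def fun_and_grad(x: np.ndarray):
        h = steps_scale * np.maximum(1.0, np.abs(x))
        batch = np.tile(x, (2 * dim + 1, 1))
        idx = np.arange(dim)
        batch[1 : dim + 1][idx, idx] += h
        batch[dim + 1 :][idx, idx] -= h
        vals = _nll_batch(batch, counts)
        grad = (vals[1 : dim + 1] - vals[dim + 1 :]) / (2.0 * h)
        return vals[0], grad

    return fun_and_grad


# ---------------------------------------------------------------------------
# Random starts and the fit driver
# ---------------------------------------------------------------------------

def _parameter_bounds(n_participants: int) -> list[tuple[float, float]]:
    """Generous box bounds on the unconstrained vector.

    The bounds sit far outside any plausible optimum (|mean| up to 20
    noise SDs, |rho| up to tanh(6) = 0.99998, kappa within e^{+/-12});
    they only keep the line search out of numerically degenerate
    territory.
    """
    bounds = [(-20.0, 20.0)] * 4 + [(-6.0, 6.0)] * 3
    per = [(-12.0, 12.0), (-12.0, 12.0), (-20.0, 20.0), (-20.0, 20.0), (-8.0, 8.0)]
    return bounds + per * n_participants


def random_start(seed: int, n_participants: int) -> np.ndarray:
    """Deterministic random starting vector honouring all type invariants.

    Group means are uniform on [-3, 3] with metacognitive means of the two
    famous conditions forced non-negative and x-means sign-assigned to the
    axis convention (correct-name positive).
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    mu_xc = abs(rng.uniform(-3, 3))
    mu_yc = abs(rng.uniform(-3, 3))
    mu_xi = -abs(rng.uniform(-3, 3))
    mu_yi = abs(rng.uniform(-3, 3))
    rho = rng.uniform(-0.8, 0.8, size=3)
    theta = [mu_xc, mu_yc, mu_xi, mu_yi, *np.arctanh(rho)]
    for _ in range(n_participants):
        kappa = np.exp(rng.uniform(np.log(0.5), np.log(8.0)))
        lam = rng.uniform(0.2, 0.8)
        c_y = rng.uniform(-2, 2)
        cx = np.sort(rng.uniform(-2, 2, size=2))
        if cx[1] - cx[0] < 1e-6:
            cx[1] = cx[0] + 1e-6
        theta.extend(
            [np.log(kappa), special.logit(lam), c_y, cx[0], np.log(cx[1] - cx[0])]
        )
    return np.asarray(theta)


def apply_axis_scale(
    group: GroupModel, parts, ax: float, ay: float
) -> tuple[GroupModel, list[ParticipantParams]]:
    """Stretch the x-axis by ``ax`` and the y-axis by ``ay``.

    Means and criteria scale with their axis; each participant's axis
    precisions kappa*lambda and kappa*(1-lambda) scale by 1/ax^2 and
    1/ay^2 (kappa and lambda are re-derived from them).  Every cell
    probability is unchanged: the likelihood only sees criteria and means
    in units of the per-axis noise SD.
    """
    if ax <= 0 or ay <= 0:
        raise ValueError("axis scale factors must be positive")
    new_group = GroupModel(
        means=group.means * np.array([ax, ay]),
        correlations=group.correlations.copy(),
    )
    new_parts = []
    for p in parts:
        px = p.kappa * p.lam / ax**2
        py = p.kappa * (1.0 - p.lam) / ay**2
        new_parts.append(
            ParticipantParams(
                participant_id=p.participant_id,
                kappa=px + py,
                lam=px / (px + py),
                c_y=p.c_y * ay,
                c_x1=p.c_x1 * ax,
                c_x2=p.c_x2 * ax,
            )
        )
    return new_group, new_parts


def apply_scale(
    group: GroupModel, parts, a: float
) -> tuple[GroupModel, list[ParticipantParams]]:
    """Uniform stretch of the decision space by ``a`` (both axes):
    means and criteria scale by a, each kappa by 1/a^2."""
    return apply_axis_scale(group, parts, a, a)


def anchor_model(
    group: GroupModel, parts
) -> tuple[GroupModel, list[ParticipantParams]]:
    """Pin the scale of both axes: renormalize so the geometric mean of
    the participants' axis precisions kappa*lambda and kappa*(1-lambda)
    is 1 on each axis (the "neutral" kappa=2, lambda=0.5 participant has
    unit noise).  Both axis scales are invisible to the likelihood, so
    this selects one representative per equivalence class."""
    log_px = [np.log(p.kappa * p.lam) for p in parts]
    log_py = [np.log(p.kappa * (1.0 - p.lam)) for p in parts]
    ax = float(np.sqrt(np.exp(np.mean(log_px))))
    ay = float(np.sqrt(np.exp(np.mean(log_py))))
    return apply_axis_scale(group, parts, ax, ay)


def fit_grt_wind(
    data,
    n_restarts: int = 100,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
    compute_pct_variance: bool = True,
) -> FittedModel:
    """Fit the group model and all participant parameters by MLE.

    Runs ``n_restarts`` independent L-BFGS-B maximizations from random
    starting configurations and keeps the best.  Deterministic given
    (data, seed, n_restarts); restart results do not depend on execution
    order because each restart draws from its own child seed.
    """
    data = list(data)
    if not data:
        raise ValueError("no count tables supplied")
    ids = [t.participant_id for t in data]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids in data")
    judgments = {t.judgment for t in data}
    judgment = judgments.pop() if len(judgments) == 1 else "mixed"
    counts = np.stack([t.counts for t in data])  # (n, 3, 6)
    n_p = len(data)

    child_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    objective = _make_objective(counts)
    bounds = _parameter_bounds(n_p)

    best_x = None
    best_nll = np.inf
    restart_logliks: list[float] = []
    converged: list[bool] = []
    for r in range(n_restarts):
        x0 = random_start(int(child_seeds[r]), n_p)
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
        )
        restart_logliks.append(-float(res.fun))
        converged.append(bool(res.success))
        if res.success and res.fun < best_nll:
            best_nll = float(res.fun)
            best_x = res.x
    if best_x is None:
        raise FitError(
            f"all {n_restarts} restarts failed to converge; "
            f"final objective values: {[-ll for ll in restart_logliks]}"
        )

    group, parts = unpack_parameters(best_x, n_p, participant_ids=ids)
    group, parts = anchor_model(group, parts)

    fitted = FittedModel(
        group=group,
        participants=parts,
        loglik=-best_nll,
        n_restarts_used=n_restarts,
        restart_logliks=restart_logliks,
        converged=converged,
        judgment=judgment,
        seed=seed,
    )
    if compute_pct_variance:
        fitted.pct_variance = variance_accounted(fitted, data)
    return fitted


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def predicted_probabilities(fitted: FittedModel, data) -> np.ndarray:
    """Model-predicted cell probabilities aligned with the data tables."""
    theta = pack_parameters(fitted.group, fitted.participants)
    order = {p.participant_id: i for i, p in enumerate(fitted.participants)}
    probs = _batched_cell_probs(theta[None, :], len(fitted.participants))[0]
    return np.stack([probs[order[t.participant_id]] for t in data])


def variance_accounted(fitted: FittedModel, data) -> float:
    """Percent of variability in observed cell proportions captured by the
    model: 100 times the squared Pearson correlation between observed
    proportions and predicted probabilities, pooled over all cells."""
    data = list(data)
    pred = predicted_probabilities(fitted, data).ravel()
    obs_rows = np.stack([t.counts for t in data]).astype(float)
    totals = obs_rows.sum(axis=2, keepdims=True)
    obs = (obs_rows / totals).ravel()
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("degenerate proportions: correlation undefined")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(100.0 * r * r)
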