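"""Parametric bootstrap bands for the SvM curve.

Datasets are simulated from the fitted model with the observed row
totals, refit, and each replicate's meta-d' curve is evaluated as a
function of the relative likelihood L on a shared logarithmic grid;
pointwise simple percentiles over replicates form the confidence band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fitting import FitError, FittedModel, fit_grt_wind, predicted_probabilities
from .model import CountTable, N_STIMULI
from .svm import build_svm_curve

__all__ = [
    "BootstrapBand",
    "simulate_counts",
    "bootstrap_svm_replicates",
    "band_from_replicates",
    "bootstrap_svm_band",
]

log = logging.getLogger(__name__)


@dataclass
class BootstrapBand:
    """Pointwise percentile band for meta-d' over the likelihood axis."""

    L_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_boot: int
    n_failed: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.L_grid = np.asarray(self.L_grid, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if np.any(self.lower > self.upper):
            raise ValueError("band bounds are crossed")


def simulate_counts(
    fitted: FittedModel, row_totals, seed: int
) -> list[CountTable]:
    """Simulate count tables from the fitted model.

    ``row_totals`` gives per-participant 3-vectors of trial counts per
    stimulus (typically the observed row totals), as an array of shape
    (n_participants, 3) aligned with ``fitted.participants``.
    """
    row_totals = np.asarray(row_totals, dtype=np.int64)
    n_p = len(fitted.participants)
    if row_totals.shape != (n_p, N_STIMULI):
        raise ValueError(
            f"row_totals must have shape ({n_p}, 3), got {row_totals.shape}"
        )
    if np.any(row_totals <= 0):
        raise ValueError("row totals must be positive")
    rng = np.random.default_rng(seed)
    dummy = [
        CountTable(p.participant_id, np.ones((3, 6), dtype=int))
        for p in fitted.participants
    ]
    probs = predicted_probabilities(fitted, dummy)  # (n, 3, 6)
    tables = []
    for i, part in enumerate(fitted.participants):
        counts = np.stack(
            [
                rng.multinomial(int(row_totals[i, s]), probs[i, s] / probs[i, s].sum())
                for s in range(N_STIMULI)
            ]
        )
        tables.append(
            CountTable(part.participant_id, counts, judgment=fitted.judgment)
        )
    return tables


def _replicate_curve_on_grid(refit, L_grid, curve_points, metad_starts):
    curve = build_svm_curve(
        refit, n_points=curve_points, metad_starts=metad_starts
    )
    L = curve.rel_likelihood
    if np.any(np.diff(L) <= 0):
        raise FitError("replicate likelihood axis is not strictly increasing")
    return np.interp(L_grid, L, curve.meta_d)


def bootstrap_svm_replicates(
    fitted: FittedModel,
    data,
    n_boot: int = 1000,
    seed: int = 0,
    restarts_per_refit: int = 10,
    L_grid: np.ndarray | None = None,
    curve_points: int = 61,
    metad_starts: int = 4,
    max_failure_fraction: float = 0.20,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Replicate meta-d' curves on a shared likelihood grid.

    Each replicate simulates counts with the observed row totals, refits
    the model with ``restarts_per_refit`` random restarts, builds its SvM
    curve, and interpolates meta-d' onto a shared log-spaced likelihood
    grid (default 0.1 to 20, 101 points).  Replicates whose refit fails
    are dropped and counted; more than ``max_failure_fraction`` failures
    abort the run.

    Child seeds derive from the master seed by a fixed counter scheme
    (SeedSequence state 2i for simulation, 2i+1 for the refit of
    replicate i), so results do not depend on execution order.

    Returns (L_grid, replicate matrix of shape (n_ok, len(L_grid)),
    n_failed).
    """
    data = list(data)
    order = {p.participant_id: i for i, p in enumerate(fitted.participants)}
    row_totals = np.zeros((len(fitted.participants), N_STIMULI), dtype=np.int64)
    for t in data:
        row_totals[order[t.participant_id]] = t.row_totals
    if L_grid is None:
        L_grid = np.geomspace(0.1, 20.0, 101)
    L_grid = np.asarray(L_grid, dtype=float)

    child = np.random.SeedSequence(seed).generate_state(2 * n_boot)
    rows = []
    n_failed = 0
    for b in range(n_boot):
        sim_seed, fit_seed = int(child[2 * b]), int(child[2 * b + 1])
        try:
            tables = simulate_counts(fitted, row_totals, sim_seed)
            refit = fit_grt_wind(
                tables,
                n_restarts=restarts_per_refit,
                seed=fit_seed,
                compute_pct_variance=False,
            )
            rows.append(
                _replicate_curve_on_grid(
                    refit, L_grid, curve_points, metad_starts
                )
            )
        except (FitError, ValueError) as exc:
            n_failed += 1
            log.debug("bootstrap replicate %d failed: %s", b, exc)
    if n_failed > max_failure_fraction * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap refits failed "
            f"(> {max_failure_fraction:.0%} allowed)"
        )
    return L_grid, np.stack(rows), n_failed


def band_from_replicates(
    L_grid: np.ndarray,
    replicates: np.ndarray,
    level: float = 0.99,
    n_failed: int = 0,
    seed: int | None = None,
) -> BootstrapBand:
    """Pointwise simple-percentile band over a replicate matrix.

    Percentiles use the 'lower'/'higher' methods so that both band
    endpoints are actual replicate values (no interpolation smoothing).
    """
    q_lo = 100.0 * (1.0 - level) / 2.0
    lower = np.percentile(replicates, q_lo, axis=0, method="lower")
    upper = np.percentile(replicates, 100.0 - q_lo, axis=0, method="higher")
    return BootstrapBand(
        L_grid=L_grid,
        lower=lower,
        upper=upper,
        level=level,
        n_boot=replicates.shape[0] + n_failed,
        n_failed=n_failed,
        seed=seed,
    )


def bootstrap_svm_band(
    fitted: FittedModel,
    data,
    n_boot: int = 1000,
    level: float = 0.99,
    seed: int = 0,
    restarts_per_refit: int = 10,
    L_grid: np.ndarray | None = None,
    curve_points: int = 61,
    metad_starts: int = 4,
    max_failure_fraction: float = 0.20,
) -> BootstrapBand:
    """Parametric-bootstrap percentile band for the SvM curve: simulate,
    refit and re-derive the curve ``n_boot`` times, then take pointwise
    simple percentiles at ``(1 - level)/2`` on each side."""
    grid, mat, n_failed = bootstrap_svm_replicates(
        fitted,
        data,
        n_boot=n_boot,
        seed=seed,
        restarts_per_refit=restarts_per_refit,
        L_grid=L_grid,
        curve_points=curve_points,
        metad_starts=metad_starts,
        max_failure_fraction=max_failure_fraction,
    )
    return band_from_replicates(grid, mat, level=level, n_failed=n_failed, seed=seed)
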