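"""End-to-end pipeline: read, exclude, aggregate, fit, curve, bootstrap,
descriptives, with a run manifest recording seeds and timings."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .bootstrap import bootstrap_svm_band
from .descriptives import apply_exclusions, descriptives_report
from .fitting import fit_grt_wind
from .io import aggregate_counts, read_trials, write_band, write_curve
from .svm import build_svm_curve

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    trials_path: str
    out_dir: str
    judgment: str = "TOT"
    seed: int = 0
    n_restarts: int = 100
    fit_tol: float = 1e-8
    fit_max_iter: int = 2000
    curve_points: int = 201
    metad_starts: int = 10
    n_boot: int = 1000
    boot_level: float = 0.99
    restarts_per_refit: int = 10
    boot_curve_points: int = 61
    boot_metad_starts: int = 4
    recall_max: float = 0.80
    recog_min: float = 0.51
    include_catch_in_descriptives: bool = True
    run_bootstrap: bool = True
    run_descriptives: bool = True

    def __post_init__(self) -> None:
        if self.judgment not in ("TOT", "FOK"):
            raise ValueError(f"judgment must be TOT or FOK, got {self.judgment!r}")
        for name in ("n_restarts", "curve_points", "n_boot", "restarts_per_refit"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.boot_level < 1.0:
            raise ValueError("boot_level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts into ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) with the
    config echo, seeds, per-stage timings and output paths.  Any stage
    failure propagates after the manifest is flushed with the stage
    marked incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"package": "grtmeta", "version": __version__},
        "config": asdict(config),
        "stages": {},
        "outputs": {},
        "complete": False,
    }

    def _flush():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def stage(name):
        class _Stage:
            def __enter__(self):
                log.info("stage %s: start", name)
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                elapsed = time.perf_counter() - self.t0
                manifest["stages"][name] = {
                    "seconds": round(elapsed, 3),
                    "ok": exc_type is None,
                }
                if exc_type is not None:
                    manifest["failed_stage"] = name
                    log.error("stage %s failed: %s", name, exc)
                else:
                    log.info("stage %s: done in %.2fs", name, elapsed)
                _flush()
                return False

        return _Stage()

    with stage("read"):
        trials = read_trials(config.trials_path)

    with stage("exclusions"):
        report = apply_exclusions(
            trials, recall_max=config.recall_max, recog_min=config.recog_min
        )
        kept = set(report.retained)
        trials = [t for t in trials if t.participant_id in kept]
        manifest["exclusions"] = {
            "retained": report.retained,
            "excluded": report.excluded,
        }

    with stage("aggregate"):
        tables = aggregate_counts(trials, judgment=config.judgment)

    with stage("fit"):
        fitted = fit_grt_wind(
            tables,
            n_restarts=config.n_restarts,
            seed=config.seed,
            max_iter=config.fit_max_iter,
            tol=config.fit_tol,
        )
        model_path = out / f"fitted_model_{config.judgment.lower()}.json"
        fitted.to_json(model_path)
        manifest["outputs"]["fitted_model"] = str(model_path)
        manifest["loglik"] = fitted.loglik
        manifest["pct_variance"] = fitted.pct_variance

    with stage("curve"):
        curve = build_svm_curve(
            fitted,
            n_points=config.curve_points,
            metad_starts=config.metad_starts,
        )
        curve_path = out / f"svm_curve_{config.judgment.lower()}.tsv"
        write_curve(curve, curve_path)
        manifest["outputs"]["svm_curve"] = str(curve_path)

    if config.run_bootstrap:
        with stage("bootstrap"):
            band = bootstrap_svm_band(
                fitted,
                tables,
                n_boot=config.n_boot,
                level=config.boot_level,
                seed=config.seed,
                restarts_per_refit=config.restarts_per_refit,
                curve_points=config.boot_curve_points,
                metad_starts=config.boot_metad_starts,
            )
            band_path = out / f"svm_band_{config.judgment.lower()}.tsv"
            write_band(band, band_path)
            manifest["outputs"]["svm_band"] = str(band_path)

    if config.run_descriptives:
        with stage("descriptives"):
            desc = descriptives_report(
                trials, include_catch=config.include_catch_in_descriptives
            )
            desc_path = out / "descriptives.json"
            summary = {
                j: {k: v for k, v in d.items() if k != "table"}
                for j, d in desc.items()
            }
            with open(desc_path, "w") as fh:
                json.dump(summary, fh, indent=2)
            for j, d in desc.items():
                d["table"].to_csv(out / f"state_confidence_{j.lower()}.tsv", sep="\t")
            manifest["outputs"]["descriptives"] = str(desc_path)

    manifest["complete"] = True
    _flush()
    return manifest
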