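"""End-to-end pipeline orchestration.

``run_pipeline`` composes the whole analysis: simulate (or load) a
longitudinal cohort, render an ILM profile for each non-excluded visit,
fit the DoG contour model, extract foveal metrics, fit the trajectory
mixed models, and write metrics CSV + model JSONs + a run report. Every
output embeds the configuration hash, package version and seed; per-image
failures are logged and skipped with a reason, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import FovealTrajectoryModel
from .dog import DoGFitConfig, DoGModel
from .errors import FoveometricsError
from .synthetic import CohortSpec, gen_cohort, gen_ilm_profile, truth_from_metrics

logger = logging.getLogger("foveometrics")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end run (YAML-serialisable)."""

    out_dir: str = "foveometrics_out"
    seed: int = 0
    cohort_csv: Optional[str] = None       # load instead of simulating
    cohort: CohortSpec = field(default_factory=CohortSpec)
    profile_noise_sd: float = 2.0          # um of ILM height noise per visit
    profile_n_points: int = 500
    dog: DoGFitConfig = field(default_factory=DoGFitConfig)
    responses: tuple = ("width_um",)
    adjustment: str = "ga"
    quadratic_pma: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        # identifies the analysis, not where it was written
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "cohort" in raw:
        raw["cohort"] = CohortSpec(**raw["cohort"])
    if "dog" in raw:
        raw["dog"] = DoGFitConfig(**raw["dog"])
    if "responses" in raw:
        raw["responses"] = tuple(raw["responses"])
    return PipelineConfig(**raw)


def run_pipeline(config: Optional[PipelineConfig] = None) -> dict:
    """Run the full analysis; returns the report dict (also written to disk).

    Per-visit stages: build a single-pit generating contour from the
    visit's cohort-level width/CFT/depth, sample a noisy ILM profile, fit
    the DoG model, extract metrics. Rows flagged ``poor_quality`` or
    ``cystic`` are excluded with a logged reason. Deterministic for a
    given config + seed.
    """
    cfg = config or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.cohort_csv:
        from .io import read_cohort_csv

        table = read_cohort_csv(cfg.cohort_csv)
        truth = None
    else:
        spec = cfg.cohort
        spec.seed = cfg.seed
        table, truth = gen_cohort(spec)

    exclusions = []
    metric_rows = []
    failures = []
    for i, row in table.iterrows():
        if bool(row.get("poor_quality", False)) or bool(row.get("cystic", False)):
            reason = "poor_quality" if row.get("poor_quality", False) else "cystic"
            exclusions.append({
                "infant_id": row["infant_id"], "eye": row["eye"],
                "pma_weeks": row["pma_weeks"], "reason": reason,
            })
            logger.info("excluded %s/%s @ %.1f wk: %s",
                        row["infant_id"], row["eye"], row["pma_weeks"], reason)
            continue
        try:
            pt = truth_from_metrics(
                width_um=float(row["width_um"]),
                cft_um=float(row["cft_um"]),
                depth_um=float(row["depth_um"]),
            )
            pt.noise_sd = cfg.profile_noise_sd
            pt.n_points = cfg.profile_n_points
            pt.seed = (cfg.seed * 1000003 + i) % (2**31 - 1)
            profile = gen_ilm_profile(pt, metadata={
                "infant_id": row["infant_id"], "eye": row["eye"],
                "pma_weeks": row["pma_weeks"],
            })
            res = DoGModel(profile, cfg.dog).fit()
            m = res.metrics()
        except FoveometricsError as exc:
            failures.append({
                "infant_id": row["infant_id"], "eye": row["eye"],
                "pma_weeks": row["pma_weeks"], "error": str(exc),
            })
            logger.warning("fit failed for %s/%s: %s", row["infant_id"], row["eye"], exc)
            continue
        metric_rows.append({
            "infant_id": row["infant_id"], "eye": row["eye"],
            "pma_weeks": row["pma_weeks"], "ga_weeks": row["ga_weeks"],
            "bw_g": row["bw_g"], "rop": row["rop"],
            "sex": row.get("sex"), "ethnicity": row.get("ethnicity"),
            "birth": row.get("birth"),
            "width_um": m.width, "depth_um": m.depth, "area_um2": m.area,
            "cft_um": m.cft,
            "slope_nasal": m.slope_nasal, "slope_temporal": m.slope_temporal,
            "prt_nasal_um": m.prt_nasal, "prt_temporal_um": m.prt_temporal,
            "parafovea_nasal": m.parafovea_nasal,
            "parafovea_temporal": m.parafovea_temporal,
        })

    metrics = pd.DataFrame(metric_rows)
    if metrics.empty:
        raise FoveometricsError("every visit failed or was excluded")

    stamp = {
        "config_hash": cfg.digest(),
        "version": __version__,
        "seed": cfg.seed,
    }
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.17g")

    model_results = {}
    for response in cfg.responses:
        try:
            res = FovealTrajectoryModel(
                metrics, response, adjustment=cfg.adjustment,
                quadratic_pma=cfg.quadratic_pma, validate=False,
            ).fit()
            payload = res.to_dict()
        except FoveometricsError as exc:
            payload = {"error": str(exc)}
        payload.update(stamp)
        model_results[response] = payload
        (out / f"model_{response}.json").write_text(
            json.dumps(payload, indent=2, default=float)
        )

    report = {
        **stamp,
        "n_cohort_rows": int(len(table)),
        "n_excluded": len(exclusions),
        "n_failed": len(failures),
        "n_metric_rows": int(len(metrics)),
        "exclusions": exclusions,
        "failures": failures,
        "models": sorted(model_results),
        "generating_truth": truth,
        "config": cfg.to_dict(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
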