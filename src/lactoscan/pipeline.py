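"""End-to-end pipeline: simulate -> calibrate -> mm -> classify -> build-ref -> evaluate.

Each stage reads and writes only the documented CSV/JSON artifacts inside a
run directory, logs row counts in/out, and stamps outputs with the config
hash so any chart or report can be traced to the exact configuration that
produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import evaluation, maturation, records, reference, sensor
from .errors import StageError, ValidationError

log = logging.getLogger("lactoscan")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible run needs; hashed into output provenance."""

    cohort: cohort_mod.CohortConfig = field(default_factory=cohort_mod.CohortConfig)
    sigma_colostrum: float = 6.0
    sigma_mature: float = 3.0
    shape: str = "linear"
    logistic_steepness: float = 6.0
    bin_edges: tuple | None = None  # None -> default daily + coarse bins
    smoothing_lower_offset: float = 1.0
    smoothing_upper_offset: float = 1.0
    min_n: int = 5
    percentile_level: int = 15
    eval_window: tuple = (6.0, 21.0)
    positive_class: str = "low_supply"
    reference_class: str = "normal"
    classification_window_hours: float = 24.0
    seed: int = 0

    def maturation_model(self) -> maturation.MaturationModel:
        return maturation.MaturationModel(
            sigma_colostrum=self.sigma_colostrum,
            sigma_mature=self.sigma_mature,
            shape=self.shape,
            logistic_steepness=self.logistic_steepness,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        seed = d.get("seed", 0)
        cc = d.pop("cohort", {})
        if isinstance(cc, dict):
            cc = dict(cc)
            for key in ("class_mix", "provider_visits", "self_scans", "day_range",
                        "temp_range", "device_gain_range", "device_offset_range"):
                if key in cc and isinstance(cc[key], list):
                    cc[key] = tuple(cc[key])
            cc.setdefault("seed", seed)
            cohort_cfg = cohort_mod.CohortConfig(**cc)
        else:
            cohort_cfg = cc
        for key in ("eval_window", "bin_edges"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(cohort=cohort_cfg, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)


def _bins(config: PipelineConfig):
    if config.bin_edges is None:
        return reference.default_bins()
    return reference.bins_from_edges(list(config.bin_edges))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline into ``out_dir``; returns the report dict.

    Stages: simulate (synthetic cohort), calibrate (per-device KCl fit),
    mm (readings -> conductivity at 25 degC -> MM%), classify, build-ref,
    flag + evaluate.  Any stage failure raises StageError naming the stage;
    partial outputs are left in place for debugging.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    report: dict = {"config_hash": cfg_hash, "stages": {}}

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        # -- simulate -----------------------------------------------------
        try:
            sim = cohort_mod.simulate_scans(config.cohort, out_dir=out)
            report["stages"]["simulate"] = {
                "n_readings": len(sim.readings),
                "n_scans": len(sim.scans),
                "n_mothers": config.cohort.n_mothers,
            }
            log.info("simulate: %d readings, %d scans", len(sim.readings), len(sim.scans))
        except ValidationError as exc:
            raise StageError("simulate", str(exc)) from exc

        # -- calibrate ----------------------------------------------------
        try:
            cals = sensor.fit_calibrations_from_csv(
                out / "calibration.csv", temp_coefficient=config.cohort.temp_coefficient
            )
            sensor.save_calibrations(cals, out / "calibrations.json")
            report["stages"]["calibrate"] = {"n_devices": len(cals)}
        except ValidationError as exc:
            raise StageError("calibrate", str(exc)) from exc

        # -- mm -----------------------------------------------------------
        try:
            model = config.maturation_model()
            readings = pd.read_csv(out / "readings.csv")
            rows = []
            for row in readings.itertuples(index=False):
                cal = cals[str(row.device_id)]
                sigma = sensor.temperature_correct(
                    sensor.apply_calibration(
                        float(row.conductance_mS) * cal.cell_constant, cal
                    ),
                    float(row.temperature_C),
                    cal.temp_coefficient,
                )
                non_physical = sigma <= 0
                mm = (
                    float(maturation.mm_array(np.array([sigma]), model)[0])
                    if not non_physical
                    else 0.0
                )
                rows.append(
                    {
                        "device_id": row.device_id,
                        "timestamp": row.timestamp,
                        "breast_side": row.breast_side,
                        "conductivity_25C": max(sigma, 0.0),
                        "mm_percent": mm,
                        "non_physical": non_physical,
                    }
                )
            mm_df = pd.DataFrame(rows)
            mm_df.to_csv(out / "mm.csv", index=False)
            report["stages"]["mm"] = {
                "n_in": len(readings),
                "n_out": len(mm_df),
                "n_non_physical": int(mm_df["non_physical"].sum()),
            }
        except ValidationError as exc:
            raise StageError("mm", str(exc)) from exc

        # -- classify -----------------------------------------------------
        try:
            recs, rejects = records.read_scan_records(out / "scans.csv")
            classes = records.classify_records(recs)
            df = records.records_to_frame(recs, classes)
            df.to_csv(out / "classified.csv", index=False)
            count_df, tag_df = records.classification_summary(recs, classes)
            report["stages"]["classify"] = {
                "n_in": len(recs) + len(rejects),
                "n_out": len(recs),
                "n_rejects": len(rejects),
                "class_counts": dict(zip(count_df["class_label"], count_df["n"].astype(int))),
            }
            (out / "rejects.json").write_text(json.dumps(rejects, indent=2))
        except ValidationError as exc:
            raise StageError("classify", str(exc)) from exc

        # -- build-ref ----------------------------------------------------
        try:
            normal = df[df["class_label"] == "normal"]
            chart = reference.build_reference(
                normal,
                bins=_bins(config),
                min_n=config.min_n,
                lower_offset=config.smoothing_lower_offset,
                upper_offset=config.smoothing_upper_offset,
                provenance={"config_hash": cfg_hash},
            )
            reference.save_chart(chart, out / "reference_chart.csv")
            report["stages"]["build_ref"] = {
                "n_in": len(normal),
                "n_bins": len(chart.bins),
                "n_usable_bins": int(np.isfinite(chart.values[:, 0]).sum()),
                "chart_hash": reference.chart_hash(chart),
            }
        except ValidationError as exc:
            raise StageError("build-ref", str(exc)) from exc

        # -- flag + evaluate ----------------------------------------------
        try:
            df["flag"] = reference.flag_frame(df, chart, level=config.percentile_level)
            df.to_csv(out / "flagged.csv", index=False)
            ev = evaluation.evaluate_threshold(
                df,
                chart,
                positive_class=config.positive_class,
                reference_class=config.reference_class,
                day_window=config.eval_window,
                level=config.percentile_level,
            )
            report["stages"]["evaluate"] = ev.to_dict()
        except ValidationError as exc:
            raise StageError("evaluate", str(exc)) from exc

        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
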