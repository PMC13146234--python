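"""End-to-end orchestration: simulate → preprocess → classify → calibrate → explore.

``run_pipeline`` executes every stage in order on a simulated day, logging
per-stage input/output counts to standard error and writing machine-readable
reports (funnel JSON, classified-episode CSV, day-estimate JSON, sensitivity
CSV, random-forest JSON).  Reruns with the same configuration and seed
produce byte-identical reports.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import classify as cls
from .calibrate import (
    CalibrationRatios,
    ValidationCounts,
    compute_ratios,
    count_day_devices,
    count_window_devices,
    estimate_day_totals,
    hourly_profile,
    sensitivity_analysis,
)
from .config import PipelineConfig
from .ingest import write_probe_log
from .preprocess import run_preprocess, write_episodes
from .rf_model import train_and_evaluate
from .simulate import generate_scenario, write_ground_truth

logger = logging.getLogger("smokesense")


class PipelineStageError(RuntimeError):
    """Wraps any stage failure with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _window_bounds(config: PipelineConfig):
    tz = dt.timezone(dt.timedelta(hours=config.scenario.utc_offset_hours))
    date = config.scenario.date
    return (
        pd.Timestamp(dt.datetime.combine(date, config.validation.start, tzinfo=tz)),
        pd.Timestamp(dt.datetime.combine(date, config.validation.end, tzinfo=tz)),
    )


def manual_counts_from_truth(
    truth: pd.DataFrame, window_start, window_end, radius_m: float
) -> Dict[str, int]:
    """Emulated observer tally: persons overlapping the window within the radius."""
    present = truth.loc[
        (truth["entry"] < window_end)
        & (truth["exit"] >= window_start)
        & (truth["min_distance_m"] <= radius_m)
    ]
    return {
        "smoker": int((present["class_label"] == "smoker").sum()),
        "passerby": int((present["class_label"] == "passerby").sum()),
    }


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full chain on one simulated day; returns the run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def stage(name: str):
        logger.info("stage %s", name)
        return name

    # --- simulate -------------------------------------------------------
    name = stage("simulate")
    try:
        log, truth = generate_scenario(config.scenario, config.seed)
        write_probe_log(log, out / "probe_log.csv", "csv")
        write_ground_truth(truth, out / "ground_truth.csv")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(name, exc) from exc
    report["stages"][name] = {"detections": len(log), "persons": len(truth)}
    logger.info("simulate: %d detections, %d persons", len(log), len(truth))

    # --- preprocess -----------------------------------------------------
    name = stage("preprocess")
    try:
        eligible, episodes, funnel, fixed_ouis = run_preprocess(
            log,
            business_hours=config.scenario.business_hours,
            gap_threshold_s=config.gap_threshold_s,
            max_dwell_min=config.max_dwell_min,
        )
        _dump_json(funnel.as_dict(), out / "funnel.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc
    report["stages"][name] = dict(
        funnel.as_dict()["counts"], fixed_ouis=sorted(fixed_ouis)
    )

    # --- classify -------------------------------------------------------
    name = stage("classify")
    try:
        classified = cls.classify_episodes(eligible, config.bands)
        write_episodes(classified, out / "classified_episodes.csv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc
    label_counts = classified["primary_label"].value_counts().to_dict() if len(classified) else {}
    report["stages"][name] = {k: int(v) for k, v in sorted(label_counts.items())}

    # --- calibrate + estimate ------------------------------------------
    name = stage("estimate")
    try:
        w0, w1 = _window_bounds(config)
        manual = manual_counts_from_truth(
            truth, w0, w1, config.scenario.assessment_radius_m
        )
        if config.manual_smokers is not None:
            manual["smoker"] = config.manual_smokers
        if config.manual_passersby is not None:
            manual["passerby"] = config.manual_passersby
        win_devices = count_window_devices(classified, w0, w1)
        ratios: CalibrationRatios = compute_ratios(
            ValidationCounts(
                manual_smokers=manual["smoker"],
                manual_passersby=manual["passerby"],
                smoker_devices=win_devices["smoker"],
                passerby_devices=win_devices["passerby"],
                window_start=w0,
                window_end=w1,
            )
        )
        estimate = estimate_day_totals(count_day_devices(classified), ratios)
        estimate.hourly = hourly_profile(classified, ratios)
        # window stay counts both before and after the dwell screen: whether
        # observed stays should be screened is a genuine modelling ambiguity
        window_stays = {
            "pre_dwell_screen": int(
                ((episodes["start"] >= w0) & (episodes["start"] < w1)).sum()
            ),
            "post_dwell_screen": int(
                ((eligible["start"] >= w0) & (eligible["start"] < w1)).sum()
            ),
        }
        _dump_json(
            {
                "manual_counts": manual,
                "window_stays": window_stays,
                "window_devices": win_devices,
                "ratios": ratios.as_dict(),
                "estimate": estimate.as_dict(),
            },
            out / "day_estimate.json",
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc
    report["stages"][name] = {
        "manual_counts": manual,
        "window_devices": win_devices,
        "smoker_persons": estimate.smoker_persons,
        "passerby_persons": estimate.passerby_persons,
    }

    # --- sensitivity ----------------------------------------------------
    name = stage("sensitivity")
    try:
        table = sensitivity_analysis(
            episodes,
            manual["smoker"],
            manual["passerby"],
            w0,
            w1,
            bands=config.bands,
            max_dwell_min=config.max_dwell_min,
            factors=config.sensitivity_factors,
        )
        table.to_csv(out / "sensitivity.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc
    report["stages"][name] = {"grid_points": len(table), "invalid": int((~table["valid"]).sum())}

    # --- exploratory random forest -------------------------------------
    name = stage("rf")
    try:
        labels = label_episodes_from_truth(eligible, truth)
        rf_report: Optional[dict] = None
        if labels is not None:
            feats, y = labels
            rf_report = train_and_evaluate(feats, y, config.rf).as_dict()
        _dump_json(rf_report or {"skipped": "fewer than two classes among labeled stays"}, out / "rf_report.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc
    report["stages"][name] = {"trained": rf_report is not None}

    _dump_json(report, out / "run_report.json")
    return report


def label_episodes_from_truth(episodes: pd.DataFrame, truth: pd.DataFrame):
    """Supervision labels for stays by tracing device ids to ground truth.

    Returns ``(features, labels)`` over episodes whose device traces to a
    simulated person, or ``None`` when fewer than two classes are present.
    """
    id_to_class = {
        row.device_id: row.class_label
        for row in truth.itertuples()
        if row.carried_device and row.device_id
    }
    mask = episodes["device_id"].isin(id_to_class)
    feats = episodes.loc[mask].reset_index(drop=True)
    y = [
        "smoker" if id_to_class[d] == "smoker" else "nonsmoker"
        for d in feats["device_id"]
    ]
    if len(set(y)) < 2:
        return None
    return feats, y
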