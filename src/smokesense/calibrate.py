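"""Device-to-person calibration and day-level estimation.

A brief manual observation window provides per-class person counts; the
concurrently classified device counts give class-specific capture ratios
(devices per person) and their reciprocals, the device-to-person
multipliers (persons per device).  Day totals are classified device counts
over business hours scaled by the multipliers.

Rounding convention: multipliers are rounded to one decimal BEFORE scaling
and person totals to the nearest integer AFTER.  With the observed window
counts (7 devices / 14 smokers, 28 devices / 207 passersby) this gives
multipliers 2.0 and 7.4.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Sequence

import pandas as pd

from . import classify as cls
from .config import RssiBands
from .preprocess import apply_dwell_screen


class CalibrationUndefinedError(ValueError):
    """Raised when a class has zero manual or classified counts in the window."""


def _round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ValidationCounts:
    """Manual and sensor-classified counts within the calibration window."""

    manual_smokers: int
    manual_passersby: int
    smoker_devices: int
    passerby_devices: int
    window_start: Optional[pd.Timestamp] = None
    window_end: Optional[pd.Timestamp] = None


@dataclass(frozen=True)
class ClassRatio:
    capture_ratio: float  # devices / persons, dimensionless
    multiplier: float  # persons / device, one decimal


@dataclass(frozen=True)
class CalibrationRatios:
    smoker: ClassRatio
    passerby: ClassRatio

    def as_dict(self) -> dict:
        return {
            "smoker": {
                "capture_ratio": self.smoker.capture_ratio,
                "multiplier": self.smoker.multiplier,
            },
            "passerby": {
                "capture_ratio": self.passerby.capture_ratio,
                "multiplier": self.passerby.multiplier,
            },
        }


@dataclass
class DayEstimate:
    """Business-hours device counts and calibrated person estimates per class."""

    smoker_devices: int
    passerby_devices: int
    smoker_persons: int
    passerby_persons: int
    hourly: Optional[pd.DataFrame] = field(default=None, repr=False)

    def as_dict(self) -> dict:
        d = {
            "smoker_devices": self.smoker_devices,
            "passerby_devices": self.passerby_devices,
            "smoker_persons": self.smoker_persons,
            "passerby_persons": self.passerby_persons,
        }
        if self.hourly is not None:
            d["hourly"] = self.hourly.to_dict(orient="list")
        return d


def compute_ratios(v: ValidationCounts) -> CalibrationRatios:
    """Class-specific capture ratios and device-to-person multipliers.

    Undefined (raises :class:`CalibrationUndefinedError`) when a class has
    zero manual persons or zero classified devices in the window.
    """
    out = {}
    for name, persons, devices in (
        ("smoker", v.manual_smokers, v.smoker_devices),
        ("passerby", v.manual_passersby, v.passerby_devices),
    ):
        if persons <= 0 or devices <= 0:
            raise CalibrationUndefinedError(
                f"calibration undefined for class {name!r}: "
                f"{persons} observed persons, {devices} classified devices"
            )
        out[name] = ClassRatio(
            capture_ratio=devices / persons,
            multiplier=_round_half_up(persons / devices, 1),
        )
    return CalibrationRatios(smoker=out["smoker"], passerby=out["passerby"])


def estimate_day_totals(
    day_devices: Dict[str, int], ratios: CalibrationRatios
) -> DayEstimate:
    """Scale classified device counts to person estimates per class."""
    if ratios is None:
        raise ValueError("calibration ratios are required")
    sd = int(day_devices.get(cls.SMOKER, 0))
    pdv = int(day_devices.get(cls.PASSERBY, 0))
    return DayEstimate(
        smoker_devices=sd,
        passerby_devices=pdv,
        smoker_persons=int(_round_half_up(sd * ratios.smoker.multiplier)),
        passerby_persons=int(_round_half_up(pdv * ratios.passerby.multiplier)),
    )


def count_window_devices(
    classified: pd.DataFrame, window_start, window_end
) -> Dict[str, int]:
    """Classified device counts with episode start inside [start, end)."""
    if len(classified) == 0:
        return {cls.SMOKER: 0, cls.PASSERBY: 0}
    in_win = classified.loc[
        (classified["start"] >= window_start) & (classified["start"] < window_end)
    ]
    return {
        cls.SMOKER: int((in_win["primary_label"] == cls.SMOKER).sum()),
        cls.PASSERBY: int((in_win["primary_label"] == cls.PASSERBY).sum()),
    }


def count_day_devices(classified: pd.DataFrame) -> Dict[str, int]:
    """Classified device counts over the full (already business-hours) table."""
    if len(classified) == 0:
        return {cls.SMOKER: 0, cls.PASSERBY: 0}
    return {
        cls.SMOKER: int((classified["primary_label"] == cls.SMOKER).sum()),
        cls.PASSERBY: int((classified["primary_label"] == cls.PASSERBY).sum()),
    }


def hourly_profile(classified: pd.DataFrame, ratios: CalibrationRatios) -> pd.DataFrame:
    """Per-hour person estimates per class (episode assigned to its start hour).

    Hourly values are kept proportional to hourly device counts and scaled so
    that each class sums exactly to its rounded day total: rounding is applied
    once, at the day level.
    """
    hours = pd.DataFrame({"hour": range(24)})
    counts = {c: [0] * 24 for c in (cls.SMOKER, cls.PASSERBY)}
    for _, row in classified.iterrows():
        label = row["primary_label"]
        if label in counts:
            counts[label][pd.Timestamp(row["start"]).hour] += 1
    hours["smoker_devices"] = counts[cls.SMOKER]
    hours["passerby_devices"] = counts[cls.PASSERBY]
    day = estimate_day_totals(
        {cls.SMOKER: sum(counts[cls.SMOKER]), cls.PASSERBY: sum(counts[cls.PASSERBY])},
        ratios,
    )
    for label, total, col in (
        (cls.SMOKER, day.smoker_persons, "smoker_persons"),
        (cls.PASSERBY, day.passerby_persons, "passerby_persons"),
    ):
        n_dev = sum(counts[label])
        hours[col] = [
            (total * c / n_dev) if n_dev else 0.0 for c in counts[label]
        ]
    return hours


def sensitivity_analysis(
    episodes: pd.DataFrame,
    manual_smokers: int,
    manual_passersby: int,
    window_start,
    window_end,
    bands: RssiBands = RssiBands(),
    max_dwell_min: float = 6.0,
    factors: Sequence[float] = (0.8, 0.9, 1.0, 1.1, 1.2),
) -> pd.DataFrame:
    """Re-run screen → classify → calibrate → estimate over a perturbation grid.

    ``episodes`` is the pre-dwell-screen episode table.  Each grid point
    multiplies the dwell screen and every RSSI band edge by a factor; a point
    whose perturbed bands overlap, or whose calibration is undefined, is kept
    in the output flagged invalid rather than silently dropped.
    """
    rows = []
    baseline: Optional[DayEstimate] = None
    grid = [(df_, rf_) for df_ in factors for rf_ in factors]
    if (1.0, 1.0) not in grid:
        grid.insert(0, (1.0, 1.0))
    for dwell_f, rssi_f in grid:
        row = {
            "dwell_factor": dwell_f,
            "rssi_factor": rssi_f,
            "max_dwell_min": max_dwell_min * dwell_f,
            "valid": True,
            "reason": "",
            "smoker_total": float("nan"),
            "passerby_total": float("nan"),
        }
        try:
            pert_bands = bands.scaled(rssi_f)
        except ValueError as exc:
            row["valid"], row["reason"] = False, f"band_overlap: {exc}"
            rows.append(row)
            continue
        eligible = apply_dwell_screen(episodes, max_dwell_min * dwell_f)
        classified = cls.classify_episodes(eligible, pert_bands)
        win = count_window_devices(classified, window_start, window_end)
        try:
            ratios = compute_ratios(
                ValidationCounts(
                    manual_smokers=manual_smokers,
                    manual_passersby=manual_passersby,
                    smoker_devices=win[cls.SMOKER],
                    passerby_devices=win[cls.PASSERBY],
                )
            )
        except CalibrationUndefinedError as exc:
            row["valid"], row["reason"] = False, f"calibration_undefined: {exc}"
            rows.append(row)
            continue
        est = estimate_day_totals(count_day_devices(classified), ratios)
        row["smoker_total"] = est.smoker_persons
        row["passerby_total"] = est.passerby_persons
        if dwell_f == 1.0 and rssi_f == 1.0 and baseline is None:
            baseline = est
        rows.append(row)
    table = pd.DataFrame(rows)
    if baseline is not None:
        for col, base in (
            ("smoker_total", baseline.smoker_persons),
            ("passerby_total", baseline.passerby_persons),
        ):
            table[col.replace("_total", "_pct_change")] = [
                100.0 * (v - base) / base if base and v == v else float("nan")
                for v in table[col]
            ]
    return table
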