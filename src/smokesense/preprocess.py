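"""Eligibility funnel: business hours, fixed-device exclusion, episodes, dwell screen.

The funnel mirrors how a raw day of probe traffic shrinks to eligible
presence episodes: (1) keep detections inside business hours, (2) drop every
OUI seen transmitting out of hours (stationary infrastructure keeps
broadcasting when the facility is closed, transient human devices do not),
(3) keep identifiers detected more than once, (4) group detections into
presence episodes and keep identifiers whose dwell is computable, (5) screen
episodes to short dwells typical of smoking or passing events.  Stage
percentages are always quoted against total day detections.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Set, Tuple

import numpy as np
import pandas as pd

EPISODE_COLUMNS = [
    "device_id",
    "start",
    "end",
    "dwell_min",
    "n_detections",
    "mean_rssi",
    "sd_rssi",
]


def filter_business_hours(
    records: pd.DataFrame, window: Tuple[int, int] = (10, 22)
) -> pd.DataFrame:
    """Keep detections whose local clock time falls in [start, end) hours.

    The interval is half-open so a detection at exactly closing time is
    excluded while one at exactly opening time is kept.
    """
    start, end = window
    if not start < end:
        raise ValueError("business-hours window start must precede end")
    if len(records) == 0:
        return records.copy()
    hours = records["timestamp"].map(lambda t: t.hour + t.minute / 60 + t.second / 3600)
    mask = (hours >= start) & (hours < end)
    return records.loc[mask].reset_index(drop=True)


def identify_fixed_ouis(
    records: pd.DataFrame, window: Tuple[int, int] = (10, 22)
) -> Set[str]:
    """OUIs with at least one detection outside business hours.

    Exclusion is applied at OUI granularity: a phone that happens to share a
    vendor prefix with a fixed device is collateral damage, which the
    simulator can measure but the rule does not prevent.
    """
    start, end = window
    if len(records) == 0:
        return set()
    hours = records["timestamp"].map(lambda t: t.hour + t.minute / 60 + t.second / 3600)
    outside = (hours < start) | (hours >= end)
    return set(records.loc[outside, "oui"].unique())


def exclude_ouis(records: pd.DataFrame, ouis: Set[str]) -> pd.DataFrame:
    """Drop all records bearing any of the given OUIs."""
    if not ouis or len(records) == 0:
        return records.copy()
    return records.loc[~records["oui"].isin(ouis)].reset_index(drop=True)


def build_episodes(records: pd.DataFrame, gap_threshold_s: float = 600.0) -> pd.DataFrame:
    """Group each device's detections into presence episodes.

    Consecutive detections of one device join an episode while the
    inter-detection gap stays within ``gap_threshold_s``; a larger gap starts
    a new episode.  Episodes need at least two detections — a single
    detection has no computable dwell and is discarded.  Dwell is last minus
    first detection time within the episode, in minutes.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    rows = []
    for device_id, grp in records.sort_values("timestamp", kind="stable").groupby(
        "device_id", sort=True
    ):
        ts = list(grp["timestamp"])
        sec = np.array([pd.Timestamp(t).timestamp() for t in ts])
        rssi = grp["rssi"].to_numpy(dtype=float)
        breaks = np.where(np.diff(sec) > gap_threshold_s)[0] + 1
        for chunk_idx in np.split(np.arange(len(ts)), breaks):
            if len(chunk_idx) < 2:
                continue
            i0, i1 = chunk_idx[0], chunk_idx[-1]
            vals = rssi[chunk_idx]
            rows.append(
                (
                    device_id,
                    pd.Timestamp(ts[i0]),
                    pd.Timestamp(ts[i1]),
                    (sec[i1] - sec[i0]) / 60.0,
                    len(chunk_idx),
                    float(np.mean(vals)),
                    float(np.std(vals, ddof=1)),
                )
            )
    episodes = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    if len(episodes):
        episodes = episodes.sort_values(
            ["start", "device_id"], kind="stable"
        ).reset_index(drop=True)
    return episodes


def apply_dwell_screen(episodes: pd.DataFrame, max_dwell_min: float = 6.0) -> pd.DataFrame:
    """Retain episodes with dwell of ``max_dwell_min`` minutes or less (inclusive)."""
    if len(episodes) == 0:
        return episodes.copy()
    return episodes.loc[episodes["dwell_min"] <= max_dwell_min].reset_index(drop=True)


def _pct(count: int, total: int) -> float:
    """Percentage of total to one decimal, rounded half-up; 0 when total is 0."""
    if total == 0:
        return 0.0
    q = Decimal(count) * 100 / Decimal(total)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PreprocessFunnel:
    """Counts surviving each preprocessing stage.

    Stages 1-2 count detections; stages 3-5 count identifiers or episodes.
    All percentages use total detections as the denominator.
    """

    total_detections: int
    in_business_hours: int
    multi_detection_ids: int
    dwell_computable_ids: int
    eligible_episodes: int

    def percentages(self) -> dict:
        total = self.total_detections
        return {
            "in_business_hours": _pct(self.in_business_hours, total),
            "multi_detection_ids": _pct(self.multi_detection_ids, total),
            "dwell_computable_ids": _pct(self.dwell_computable_ids, total),
            "eligible_episodes": _pct(self.eligible_episodes, total),
        }

    def as_dict(self) -> dict:
        return {
            "counts": {
                "total_detections": self.total_detections,
                "in_business_hours": self.in_business_hours,
                "multi_detection_ids": self.multi_detection_ids,
                "dwell_computable_ids": self.dwell_computable_ids,
                "eligible_episodes": self.eligible_episodes,
            },
            "pct_of_total_detections": self.percentages(),
        }


def compute_funnel(
    total_detections: int,
    in_business_hours: int,
    multi_detection_ids: int,
    dwell_computable_ids: int,
    eligible_episodes: int,
) -> PreprocessFunnel:
    """Assemble the funnel record from raw stage counts."""
    counts = (
        total_detections,
        in_business_hours,
        multi_detection_ids,
        dwell_computable_ids,
        eligible_episodes,
    )
    if any(c < 0 for c in counts):
        raise ValueError("funnel counts must be nonnegative")
    return PreprocessFunnel(*counts)


def write_episodes(episodes: pd.DataFrame, path) -> None:
    out = episodes.copy()
    for col in ("start", "end"):
        out[col] = out[col].map(lambda t: pd.Timestamp(t).isoformat())
    out.to_csv(path, index=False)


def read_episodes(path) -> pd.DataFrame:
    eps = pd.read_csv(path, dtype={"device_id": str})
    for col in ("start", "end"):
        eps[col] = eps[col].map(lambda s: pd.Timestamp(s))
    return eps


def run_preprocess(
    records: pd.DataFrame,
    business_hours: Tuple[int, int] = (10, 22),
    gap_threshold_s: float = 600.0,
    max_dwell_min: float = 6.0,
):
    """Full funnel on a raw day of canonical records.

    Returns ``(eligible, episodes, funnel, fixed_ouis)`` where ``episodes``
    is the pre-screen episode table (needed by sensitivity analyses) and
    ``eligible`` the post-screen subset.
    """
    total = len(records)
    in_hours = filter_business_hours(records, business_hours)
    fixed_ouis = identify_fixed_ouis(records, business_hours)
    human = exclude_ouis(in_hours, fixed_ouis)
    id_counts = human["device_id"].value_counts() if len(human) else pd.Series(dtype=int)
    multi_ids = int((id_counts > 1).sum())
    episodes = build_episodes(human, gap_threshold_s)
    dwell_ids = int(episodes["device_id"].nunique()) if len(episodes) else 0
    eligible = apply_dwell_screen(episodes, max_dwell_min)
    funnel = compute_funnel(total, len(in_hours), multi_ids, dwell_ids, len(eligible))
    return eligible, episodes, funnel, fixed_ouis
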