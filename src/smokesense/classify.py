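"""Episode classification by RSSI band and by the exploratory threshold rule.

The primary rule maps the mean RSSI of an eligible episode to a behavioral
class: a strong band for likely smokers lingering near the sensor, a weak
band for likely passersby crossing the corridor, and ``unclassified`` for
means outside both bands (very strong or very weak signals).  The bands are
applied to the episode mean because an episode's member detections fluctuate
by several dB of shadowing while the person's behaviour does not.

The exploratory rule is a simple conjunction — mean RSSI above -80 dBm and a
stay shorter than 10 minutes — useful as a transparent baseline next to the
random-forest model.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import RssiBands

SMOKER = "smoker"
PASSERBY = "passerby"
UNCLASSIFIED = "unclassified"
NONSMOKER = "nonsmoker"

FEATURE_COLUMNS = ["dwell_min", "mean_rssi", "sd_rssi", "n_detections"]


@dataclass(frozen=True)
class EpisodeFeatures:
    """Summary features of one presence episode."""

    dwell_min: float
    mean_rssi: float
    sd_rssi: float
    n_detections: int


def summarize_episode(episode) -> EpisodeFeatures:
    """Features from an episode row (needs >= 2 member detections)."""
    n = int(episode["n_detections"])
    if n < 2:
        raise ValueError("episode must have at least 2 detections")
    return EpisodeFeatures(
        dwell_min=float(episode["dwell_min"]),
        mean_rssi=float(episode["mean_rssi"]),
        sd_rssi=float(episode["sd_rssi"]),
        n_detections=n,
    )


def classify_primary(features: EpisodeFeatures, bands: RssiBands = RssiBands()) -> str:
    """Band rule on mean RSSI: smoker, passerby, or unclassified (inclusive bounds)."""
    m = features.mean_rssi
    if bands.smoker_lower <= m <= bands.smoker_upper:
        return SMOKER
    if bands.passerby_lower <= m <= bands.passerby_upper:
        return PASSERBY
    return UNCLASSIFIED


def classify_exploratory(
    features: EpisodeFeatures, rssi_floor: float = -80.0, max_dwell_min: float = 10.0
) -> str:
    """Threshold rule: smoker iff mean RSSI > -80 dBm and dwell < 10 min."""
    if features.mean_rssi > rssi_floor and features.dwell_min < max_dwell_min:
        return SMOKER
    return NONSMOKER


def classify_episodes(episodes: pd.DataFrame, bands: RssiBands = RssiBands()) -> pd.DataFrame:
    """Add ``primary_label`` and ``exploratory_label`` columns to an episode table."""
    out = episodes.copy()
    if len(out) == 0:
        out["primary_label"] = pd.Series(dtype=str)
        out["exploratory_label"] = pd.Series(dtype=str)
        return out
    m = out["mean_rssi"]
    primary = pd.Series(UNCLASSIFIED, index=out.index, dtype=object)
    primary[(m >= bands.smoker_lower) & (m <= bands.smoker_upper)] = SMOKER
    primary[(m >= bands.passerby_lower) & (m <= bands.passerby_upper)] = PASSERBY
    out["primary_label"] = primary
    out["exploratory_label"] = NONSMOKER
    out.loc[(m > -80.0) & (out["dwell_min"] < 10.0), "exploratory_label"] = SMOKER
    return out
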