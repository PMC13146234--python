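"""Synthetic probe-request scenario generator with known ground truth.

The study's raw sensor logs are not public, so end-to-end validation runs on
simulated data that reproduces the statistical structure the analysis
assumes: two behavioral classes (smokers dwelling near the smoking area,
passersby crossing an adjacent corridor), Poisson arrivals with hourly
rates, heterogeneous device carriage, bursty probe emission, log-distance
path loss with shadowing, and fixed infrastructure devices that transmit
around the clock.  Every emitted probe record traces to exactly one
ground-truth person or one fixed-roster device.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .config import PathLossParams, ScenarioConfig
from .ingest import PROBE_COLUMNS, anonymize_identifier

TRUTH_COLUMNS = [
    "person_id",
    "class_label",
    "entry",
    "exit",
    "carried_device",
    "device_id",
    "min_distance_m",
]

SMOKER = "smoker"
PASSERBY = "passerby"


def rssi_at(distance_m, params: PathLossParams, noise_db=0.0):
    """Received power (dBm) at a horizontal distance under log-distance path loss.

    RSSI = p0 - 10 * exponent * log10(distance / d0) + noise.  Accepts scalars
    or arrays; raises ``ValueError`` for nonpositive distances.
    """
    d = np.asarray(distance_m, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance_m must be positive")
    out = params.p0_dbm - 10.0 * params.exponent * np.log10(d / params.d0_m) + noise_db
    if np.isscalar(distance_m) and np.isscalar(noise_db):
        return float(out)
    return out


@dataclass
class _Trajectory:
    """Closed-form position over a person's presence span (seconds)."""

    span_s: float
    kind: str
    # smoker: anchor point inside the dwell zone; passerby: lateral path
    x0: float = 0.0
    y0: float = 0.0
    vx: float = 0.0

    def position_at(self, t_s: float) -> Tuple[float, float]:
        if self.kind == SMOKER:
            return self.x0, self.y0
        return self.x0 + self.vx * t_s, self.y0


def _draw_smoker_trajectory(config: ScenarioConfig, rng: np.random.Generator) -> _Trajectory:
    stay_s = (
        config.smoker_stay.median_min
        * 60.0
        * math.exp(config.smoker_stay.sigma * rng.standard_normal())
    )
    # uniform anchor in the dwell zone disc around the smoking-area centre
    r = config.dwell_zone_radius_m * math.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    cx, cy = config.smoking_area_xy
    return _Trajectory(span_s=stay_s, kind=SMOKER, x0=cx + r * math.cos(theta), y0=cy + r * math.sin(theta))


def _draw_passerby_trajectory(config: ScenarioConfig, rng: np.random.Generator) -> _Trajectory:
    half = config.corridor_length_m / 2.0
    y = config.corridor_offset_m + rng.uniform(-0.5, 0.5) * config.corridor_width_m
    direction = 1.0 if rng.uniform() < 0.5 else -1.0
    span = config.corridor_length_m / config.walking_speed_mps
    return _Trajectory(
        span_s=span,
        kind=PASSERBY,
        x0=-direction * half,
        y0=y,
        vx=direction * config.walking_speed_mps,
    )


def simulate_trajectory(person_class: str, config: ScenarioConfig, seed: int) -> pd.DataFrame:
    """Sample one person's position at 1-second resolution.

    Smokers hold an anchor inside the dwell zone for a log-normal stay;
    passersby traverse the corridor laterally at walking speed.
    """
    if person_class not in (SMOKER, PASSERBY):
        raise ValueError(f"unknown person class: {person_class!r}")
    rng = np.random.default_rng(seed)
    traj = (
        _draw_smoker_trajectory(config, rng)
        if person_class == SMOKER
        else _draw_passerby_trajectory(config, rng)
    )
    times = np.arange(0.0, traj.span_s + 1e-9, 1.0)
    pos = np.array([traj.position_at(t) for t in times])
    return pd.DataFrame({"t_s": times, "x_m": pos[:, 0], "y_m": pos[:, 1]})


def _min_distance(traj: _Trajectory, sensor: Tuple[float, float]) -> float:
    sx, sy = sensor
    if traj.kind == SMOKER:
        return math.hypot(traj.x0 - sx, traj.y0 - sy)
    x_end = traj.x0 + traj.vx * traj.span_s
    lo, hi = min(traj.x0, x_end), max(traj.x0, x_end)
    nearest_x = min(max(sx, lo), hi)
    return math.hypot(nearest_x - sx, traj.y0 - sy)


def _random_mac(rng: np.random.Generator, oui: str) -> str:
    tail = "".join(f"{rng.integers(0, 256):02x}" for _ in range(3))
    return oui.lower() + tail


def _emit_bursts(
    traj: _Trajectory,
    entry_s: float,
    config: ScenarioConfig,
    rng: np.random.Generator,
    out_times: List[float],
    out_rssi: List[int],
) -> None:
    """Append burst probe times/RSSI for one device over its presence span."""
    em = config.emission
    pl = config.path_loss
    sx, sy = config.sensor_xy
    t = rng.exponential(em.mean_interburst_s)
    while t < traj.span_s:
        x, y = traj.position_at(t)
        d = math.hypot(x - sx, y - sy)
        n_probes = int(rng.integers(em.probes_per_burst_min, em.probes_per_burst_max + 1))
        base = pl.p0_dbm - 10.0 * pl.exponent * math.log10(max(d, 1e-6) / pl.d0_m)
        for _ in range(n_probes):
            rssi = base + rng.normal(0.0, pl.shadowing_sd_db)
            out_times.append(entry_s + t)
            out_rssi.append(int(np.clip(round(rssi), -100, 0)))
        t += rng.exponential(em.mean_interburst_s)


def generate_scenario(config: ScenarioConfig, seed: int) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one day of probe traffic plus its ground truth.

    Returns ``(log, truth)``: a time-sorted probe log with the canonical
    columns and a per-person truth table.  Deterministic given
    ``(config, seed)``; arrivals per class per hour follow a Poisson process
    with the configured rates, and fixed devices emit across all 24 hours.
    """
    root = np.random.SeedSequence(seed)
    arrival_rng = np.random.default_rng(root.spawn(1)[0])
    tz = dt.timezone(dt.timedelta(hours=config.utc_offset_hours))
    midnight = dt.datetime.combine(config.date, dt.time(0, 0), tzinfo=tz)

    times: List[float] = []
    rssis: List[int] = []
    dev_ids: List[str] = []
    ouis: List[str] = []
    truth_rows: List[dict] = []
    used_macs: set = set()

    person_specs = []  # (class, entry seconds)
    for cls, rates in ((SMOKER, config.smoker_rate_per_hour), (PASSERBY, config.passerby_rate_per_hour)):
        for hour, rate in enumerate(rates):
            if rate <= 0:
                continue
            n = arrival_rng.poisson(rate)
            offsets = np.sort(arrival_rng.uniform(0.0, 3600.0, size=n))
            for off in offsets:
                person_specs.append((cls, hour * 3600.0 + float(off)))
    person_specs.sort(key=lambda p: p[1])

    person_streams = root.spawn(len(person_specs) + len(config.fixed_devices))
    counters = {SMOKER: 0, PASSERBY: 0}
    for i, (cls, entry_s) in enumerate(person_specs):
        rng = np.random.default_rng(person_streams[i])
        traj = (
            _draw_smoker_trajectory(config, rng)
            if cls == SMOKER
            else _draw_passerby_trajectory(config, rng)
        )
        counters[cls] += 1
        pid = f"{'S' if cls == SMOKER else 'P'}{counters[cls]:05d}"
        carriage = config.smoker_carriage_p if cls == SMOKER else config.passerby_carriage_p
        carried = bool(rng.uniform() < carriage)
        device_id = ""
        if carried:
            oui = str(rng.choice(np.asarray(config.human_oui_pool)))
            mac = _random_mac(rng, oui)
            while mac in used_macs:
                mac = _random_mac(rng, oui)
            used_macs.add(mac)
            device_id = anonymize_identifier(mac, config.hash_salt.encode())
            n_before = len(times)
            _emit_bursts(traj, entry_s, config, rng, times, rssis)
            n_new = len(times) - n_before
            dev_ids.extend([device_id] * n_new)
            ouis.extend([oui] * n_new)
        truth_rows.append(
            {
                "person_id": pid,
                "class_label": cls,
                "entry": midnight + dt.timedelta(seconds=math.floor(entry_s)),
                "exit": midnight + dt.timedelta(seconds=math.floor(entry_s + traj.span_s)),
                "carried_device": carried,
                "device_id": device_id,
                "min_distance_m": _min_distance(traj, config.sensor_xy),
            }
        )

    # stationary infrastructure: emits all day from a fixed position
    for j, fixed in enumerate(config.fixed_devices):
        rng = np.random.default_rng(person_streams[len(person_specs) + j])
        mac = _random_mac(rng, fixed.oui)
        device_id = anonymize_identifier(mac, config.hash_salt.encode())
        traj = _Trajectory(span_s=86400.0, kind=SMOKER, x0=fixed.x_m, y0=fixed.y_m)
        n_before = len(times)
        _emit_bursts(traj, 0.0, config, rng, times, rssis)
        n_new = len(times) - n_before
        dev_ids.extend([device_id] * n_new)
        ouis.extend([fixed.oui] * n_new)

    log = pd.DataFrame(
        {
            "timestamp": [midnight + dt.timedelta(seconds=math.floor(t)) for t in times],
            "device_id": dev_ids,
            "oui": ouis,
            "rssi": pd.array(rssis, dtype="int64"),
        },
        columns=PROBE_COLUMNS,
    )
    log = log.sort_values("timestamp", kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return log, truth


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    for col in ("entry", "exit"):
        out[col] = out[col].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, keep_default_na=False, dtype={"device_id": str})
    for col in ("entry", "exit"):
        truth[col] = pd.to_datetime(truth[col])
    truth["carried_device"] = truth["carried_device"].astype(str).str.lower().isin(("true", "1"))
    truth["min_distance_m"] = truth["min_distance_m"].astype(float)
    return truth
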