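"""Reading, validation, and anonymization of probe-request logs.

Canonical record stream: a time-sorted DataFrame with columns
``timestamp`` (tz-aware local wall clock), ``device_id`` (salted one-way
hash of the MAC address, 16 lowercase hex characters), ``oui`` (vendor
prefix, 6 upper-case hex characters) and ``rssi`` (integer dBm in
[-100, 0]).  Malformed rows are counted and excluded, never fatal, so a
partially corrupted sensor export still yields its valid records.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Tuple

import pandas as pd

PROBE_COLUMNS = ["timestamp", "device_id", "oui", "rssi"]

#: hex length of the truncated salted SHA-256 digest used as device_id
DIGEST_LEN = 16

_OUI_RE = re.compile(r"^[0-9A-F]{6}$")
_HEX_RE = re.compile(r"^[0-9a-f]+$")
_MAC_RE = re.compile(r"^[0-9a-f]{12}$")


@dataclass
class IngestReport:
    """Bookkeeping for one log read: read = kept + dropped."""

    read: int = 0
    kept: int = 0
    dropped: int = 0
    drop_reasons: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "read": self.read,
            "kept": self.kept,
            "dropped": self.dropped,
            "drop_reasons": dict(sorted(self.drop_reasons.items())),
        }


def anonymize_identifier(mac: str, salt: bytes) -> str:
    """One-way hash of a MAC address: salted SHA-256 truncated to 16 hex chars.

    Deterministic for a fixed (mac, salt) pair; different salts give
    unrelated digests, and the digest reveals no MAC bytes.  Separators
    (``:``, ``-``, ``.``) and case in the MAC are normalized away first.
    """
    if not salt:
        raise ValueError("salt must be nonempty")
    norm = re.sub(r"[:\-.]", "", mac).lower()
    if not _MAC_RE.match(norm):
        raise ValueError(f"malformed MAC address: {mac!r}")
    return hashlib.sha256(salt + norm.encode("ascii")).hexdigest()[:DIGEST_LEN]


def _parse_timestamp(value: str):
    try:
        ts = dt.datetime.fromisoformat(str(value))
    except (ValueError, TypeError):
        return None
    if ts.tzinfo is None:
        return None
    return ts


def read_probe_log(source, format: str = "csv") -> Tuple[pd.DataFrame, IngestReport]:
    """Read a raw probe log into the canonical record stream.

    ``source`` is a path or open text handle; ``format`` is ``csv`` or
    ``jsonl``.  Rows with an unparseable or offset-free timestamp, RSSI
    outside [-100, 0], a bad OUI, or a non-hex device id are dropped with a
    per-reason count in the report.  Output is sorted by timestamp.
    """
    if format == "csv":
        raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    elif format == "jsonl":
        raw = pd.read_json(source, lines=True, dtype=str, convert_dates=False)
        raw = raw.astype(str)
    else:
        raise ValueError(f"unknown probe-log format: {format!r} (expected csv or jsonl)")

    report = IngestReport(read=len(raw))
    if len(raw) == 0:
        empty = pd.DataFrame(columns=PROBE_COLUMNS)
        empty["timestamp"] = pd.to_datetime(empty["timestamp"])
        return empty, report

    missing = [c for c in PROBE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"probe log missing columns: {missing}")

    rows = []
    for tup in raw.itertuples(index=False):
        ts = _parse_timestamp(getattr(tup, "timestamp"))
        if ts is None:
            report.drop_reasons["bad_timestamp"] += 1
            continue
        try:
            rssi = int(str(getattr(tup, "rssi")))
        except ValueError:
            report.drop_reasons["rssi_out_of_range"] += 1
            continue
        if not (-100 <= rssi <= 0):
            report.drop_reasons["rssi_out_of_range"] += 1
            continue
        oui = str(getattr(tup, "oui")).upper()
        if not _OUI_RE.match(oui):
            report.drop_reasons["bad_oui"] += 1
            continue
        device_id = str(getattr(tup, "device_id")).lower()
        if not _HEX_RE.match(device_id):
            report.drop_reasons["bad_device_id"] += 1
            continue
        rows.append((ts, device_id, oui, rssi))

    report.dropped = sum(report.drop_reasons.values())
    report.kept = len(rows)
    records = pd.DataFrame(rows, columns=PROBE_COLUMNS)
    if len(records):
        records = records.sort_values("timestamp", kind="stable").reset_index(drop=True)
        records["rssi"] = records["rssi"].astype("int64")
    return records, report


def write_probe_log(records: pd.DataFrame, sink, format: str = "csv") -> None:
    """Write canonical records as CSV or JSON-lines; round-trips bit-exact."""
    out = records.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    if format == "csv":
        out.to_csv(sink, index=False)
    elif format == "jsonl":
        text = out.to_json(orient="records", lines=True)
        if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
            with open(sink, "w") as fh:
                fh.write(text)
        else:
            sink.write(text)
    else:
        raise ValueError(f"unknown probe-log format: {format!r} (expected csv or jsonl)")
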