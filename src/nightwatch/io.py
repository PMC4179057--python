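"""File formats and configuration loading.

Line-oriented, diff-able formats throughout: JSONL for event logs, CSV
for load-cell streams and feature datasets, DOT for graphs, JSON for
thresholds and metrics.  Timestamps are ISO-8601 UTC; a night is
identified by the calendar date of its 10 p.m. boundary.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import ALPHABET, SensorEvent


class EventLogError(ValueError):
    pass


class ConfigKeyError(ValueError):
    pass


def write_event_log(events, path) -> None:
    """One JSON object per line: ts, symbol, night_id, source."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps({
                "ts": e.ts.isoformat(), "symbol": e.symbol,
                "night_id": e.night_id, "source": e.source,
            }) + "\n")


def read_event_log(path) -> list[SensorEvent]:
    """Parse and validate a JSONL event log.

    Malformed lines and unknown symbols are reported with their line
    numbers; timestamps must be nondecreasing within each night, and a
    violation reports both offending timestamps.
    """
    events: list[SensorEvent] = []
    problems: list[str] = []
    last_ts: dict[str, pd.Timestamp] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                ts = pd.Timestamp(rec["ts"])
                symbol = rec["symbol"]
                night_id = rec.get("night_id", "")
                source = rec.get("source", "")
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                problems.append(f"line {lineno}: malformed record ({exc})")
                continue
            if symbol not in ALPHABET:
                problems.append(f"line {lineno}: unknown symbol {symbol!r}")
                continue
            prev = last_ts.get(night_id)
            if prev is not None and ts < prev:
                problems.append(
                    f"line {lineno}: out-of-order timestamp {ts.isoformat()} "
                    f"after {prev.isoformat()} in night {night_id!r}"
                )
                continue
            last_ts[night_id] = ts
            events.append(SensorEvent(ts=ts, symbol=symbol,
                                      night_id=night_id, source=source))
    if problems:
        raise EventLogError(
            f"{path}: {len(problems)} invalid line(s):\n" + "\n".join(problems)
        )
    return events


def write_loadcell_csv(adc: np.ndarray, night_start: pd.Timestamp,
                       sampling_hz: float, path) -> None:
    """CSV with columns ts (ISO-8601 UTC), adc_out."""
    idx = np.arange(1, len(adc) + 1)
    ts = night_start + pd.to_timedelta(idx / sampling_hz, unit="s")
    pd.DataFrame({"ts": ts.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
                  "adc_out": adc}).to_csv(path, index=False)


def read_loadcell_csv(path) -> tuple[np.ndarray, pd.Timestamp, float]:
    """Returns (adc array, night_start, sampling_hz inferred from spacing)."""
    df = pd.read_csv(path)
    missing = {"ts", "adc_out"} - set(df.columns)
    if missing:
        raise EventLogError(f"{path}: missing columns {sorted(missing)}")
    ts = pd.to_datetime(df["ts"])
    if len(ts) < 2:
        raise EventLogError(f"{path}: need at least two samples")
    dt = (ts.iloc[1] - ts.iloc[0]).total_seconds()
    hz = 1.0 / dt
    night_start = ts.iloc[0] - pd.to_timedelta(dt, unit="s")
    return df["adc_out"].to_numpy(np.int64), night_start, hz


def load_config(path) -> dict:
    """TOML or YAML by extension."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh)
    raise ConfigKeyError(f"unsupported config format {path.suffix!r} (use .toml/.yaml)")


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
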