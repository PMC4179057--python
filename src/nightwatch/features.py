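"""Sliding-window feature extraction for early-night behavior modeling.

Each observation summarizes a 20-minute window of the event stream with
15 features:

* the symbols of the last four events in the window, newest first
  (``ev_t`` .. ``ev_t3``), with the value ``N`` when fewer events exist;
* the elapsed time in seconds from the newest event back to each of the
  three preceding ones, ``Et(t, t-k)`` for k = 1..3 (``et_1`` .. ``et_3``);
  missing lags are coded with a sentinel equal to the window width;
* the count of each of the 8 event types in the window.

Windows are labeled TPI when they start in the early-night period
(10 p.m. to midnight) and !TPI otherwise (midnight to 6 a.m.).  With the
default non-overlapping 20-minute grid a night of 8 hours yields 24
observations, of which 6 are TPI, and no window straddles midnight.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right

import pandas as pd

from .events import ALPHABET, SensorEvent

DEFAULT_WIDTH_MIN = 20.0
NO_EVENT = "N"
LABEL_EARLY = "TPI"
LABEL_LATE = "!TPI"

CATEGORICAL_FEATURES = ["ev_t", "ev_t1", "ev_t2", "ev_t3"]
NUMERIC_FEATURES = ["et_1", "et_2", "et_3"] + [f"n_{s}" for s in ALPHABET]
FEATURE_COLUMNS = CATEGORICAL_FEATURES + NUMERIC_FEATURES   # 4 + 3 + 8 = 15


def extract_features(
    events: list[SensorEvent],
    window_start: pd.Timestamp,
    width_min: float = DEFAULT_WIDTH_MIN,
) -> dict:
    """Feature dict for the window ``[window_start, window_start + width)``.

    ``events`` must be sorted by timestamp; an empty window yields
    all-``N`` slots, sentinel times and zero counts.
    """
    window_end = window_start + pd.to_timedelta(width_min, unit="m")
    ts_list = [e.ts for e in events]
    lo = bisect_left(ts_list, window_start)
    hi = bisect_right(ts_list, window_end)
    # half-open window: drop events exactly at window_end
    while hi > lo and ts_list[hi - 1] >= window_end:
        hi -= 1
    in_window = events[lo:hi]

    sentinel = width_min * 60.0
    fv: dict = {}
    last4 = in_window[-4:][::-1]   # newest first
    for k, name in enumerate(CATEGORICAL_FEATURES):
        fv[name] = last4[k].symbol if k < len(last4) else NO_EVENT
    for k in (1, 2, 3):
        if len(last4) > k:
            fv[f"et_{k}"] = (last4[0].ts - last4[k].ts).total_seconds()
        else:
            fv[f"et_{k}"] = sentinel
    for s in ALPHABET:
        fv[f"n_{s}"] = sum(1 for e in in_window if e.symbol == s)
    return fv


def build_dataset(
    events_by_night: dict[str, list[SensorEvent]],
    night_starts: dict[str, pd.Timestamp],
    width_min: float = DEFAULT_WIDTH_MIN,
    step_min: float | None = None,
    night_hours: float = 8.0,
    early_hours: float = 2.0,
) -> pd.DataFrame:
    """Labeled observation table over all nights.

    Window starts are laid on a grid from each night's start (10 p.m.)
    with the given step (default: the width, i.e. non-overlapping); a
    window is kept while its start lies inside the active span.  The
    label is TPI iff the window starts before ``night_start +
    early_hours`` (midnight).

    Returns a DataFrame with the 15 feature columns, ``label``,
    ``night_id`` and ``window_start``.
    """
    step = width_min if step_min is None else step_min
    rows = []
    for night_id in sorted(events_by_night):
        events = sorted(events_by_night[night_id], key=lambda e: e.ts)
        start = night_starts[night_id]
        midnight = start + pd.to_timedelta(early_hours, unit="h")
        night_end = start + pd.to_timedelta(night_hours, unit="h")
        w = start
        while w < night_end:
            fv = extract_features(events, w, width_min=width_min)
            fv["label"] = LABEL_EARLY if w < midnight else LABEL_LATE
            fv["night_id"] = night_id
            fv["window_start"] = w
            rows.append(fv)
            w = w + pd.to_timedelta(step, unit="m")
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["label", "night_id", "window_start"])
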