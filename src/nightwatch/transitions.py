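"""Online first-order event-transition mining.

Processes a night's event stream one event at a time — the way an active
rule would see inserts arriving — and maintains, per ordered event pair
(e_i, e_j):

* a transition count, from which the conditional probability
  P_ij = P(e_j | e_i) = counts_ij / sum_j counts_ij is derived, and
* streaming (Welford) statistics of the inter-event time: n, mean mu_t
  and standard deviation sigma_t in seconds.

Nights are independent: the first event of a night has no predecessor and
contributes no transition.  Consecutive identical symbols within a
configurable debounce gap (PIR retriggering) are merged into one event;
an absorbed repeat refreshes the remembered timestamp so a retrigger
chain counts once, timed from its last firing.

The learned matrix exports as a DOT graph keeping only edges whose
confidence P_ij reaches a threshold (default 0.2), each labeled with p,
mu_t and sigma_t.
"""

from __future__ import annotations

import math
from io import StringIO

import numpy as np
import pandas as pd

from .events import ALPHABET, SYMBOL_INDEX, SensorEvent

DEFAULT_DEBOUNCE_GAP_S = 30.0
DEFAULT_CONFIDENCE_THRESHOLD = 0.2


class OutOfOrderError(ValueError):
    pass


class UndefinedRowError(KeyError):
    pass


class TransitionModel:
    """Count matrix plus per-pair online inter-event-time accumulators."""

    def __init__(self, debounce_gap_s: float = DEFAULT_DEBOUNCE_GAP_S) -> None:
        k = len(ALPHABET)
        self.debounce_gap_s = debounce_gap_s
        self.counts = np.zeros((k, k), dtype=np.int64)
        # Welford accumulators per ordered pair
        self._n = np.zeros((k, k), dtype=np.int64)
        self._mean = np.zeros((k, k), dtype=float)
        self._m2 = np.zeros((k, k), dtype=float)
        self._last: dict[str, SensorEvent] = {}   # per-night last event

    # -- online updates --------------------------------------------------

    def observe(self, event: SensorEvent) -> "TransitionModel":
        """Fold one event into the model (events in ts order per night)."""
        prev = self._last.get(event.night_id)
        if prev is not None:
            dt = (event.ts - prev.ts).total_seconds()
            if dt < 0:
                raise OutOfOrderError(
                    f"event at {event.ts} precedes previous event at {prev.ts} "
                    f"in night {event.night_id!r}"
                )
            if event.symbol == prev.symbol and dt <= self.debounce_gap_s:
                self._last[event.night_id] = event   # absorbed retrigger
                return self
            i = SYMBOL_INDEX[prev.symbol]
            j = SYMBOL_INDEX[event.symbol]
            self.counts[i, j] += 1
            n = self._n[i, j] + 1
            self._n[i, j] = n
            delta = dt - self._mean[i, j]
            self._mean[i, j] += delta / n
            self._m2[i, j] += delta * (dt - self._mean[i, j])
        self._last[event.night_id] = event
        return self

    def observe_all(self, events) -> "TransitionModel":
        for e in events:
            self.observe(e)
        return self

    # -- queries ---------------------------------------------------------

    def row_total(self, e_i: str) -> int:
        return int(self.counts[SYMBOL_INDEX[e_i]].sum())

    def probability(self, e_i: str, e_j: str) -> float:
        total = self.row_total(e_i)
        if total == 0:
            raise UndefinedRowError(f"no observed transitions out of {e_i!r}")
        return float(self.counts[SYMBOL_INDEX[e_i], SYMBOL_INDEX[e_j]]) / total

    def pair_stats(self, e_i: str, e_j: str) -> tuple[float | None, float | None, int]:
        """(mu_t, sigma_t, n) for the pair; sigma_t uses n-1 and is None
        for n < 2, mu_t None for n = 0."""
        i, j = SYMBOL_INDEX[e_i], SYMBOL_INDEX[e_j]
        n = int(self._n[i, j])
        if n == 0:
            return None, None, 0
        mu = float(self._mean[i, j])
        sigma = math.sqrt(self._m2[i, j] / (n - 1)) if n >= 2 else None
        return mu, sigma, n

    def probability_matrix(self) -> np.ndarray:
        """Row-normalized matrix; unobserved rows are NaN."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / totals
        p[totals.ravel() == 0, :] = np.nan
        return p

    # -- exports ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format dump: one row per observed pair with count, p, mu_t, sigma_t."""
        records = []
        for a in ALPHABET:
            if self.row_total(a) == 0:
                continue
            for b in ALPHABET:
                c = int(self.counts[SYMBOL_INDEX[a], SYMBOL_INDEX[b]])
                if c == 0:
                    continue
                mu, sigma, n = self.pair_stats(a, b)
                records.append(
                    {"from": a, "to": b, "count": c,
                     "p": self.probability(a, b), "mu_t_s": mu,
                     "sigma_t_s": sigma, "n": n}
                )
        return pd.DataFrame(
            records, columns=["from", "to", "count", "p", "mu_t_s", "sigma_t_s", "n"]
        )

    def export_graph(
        self, confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    ) -> str:
        """DOT digraph of edges with P_ij >= threshold, deterministic order."""
        buf = StringIO()
        buf.write("digraph transitions {\n")
        edges = []
        for a in ALPHABET:
            if self.row_total(a) == 0:
                continue
            for b in ALPHABET:
                if self.counts[SYMBOL_INDEX[a], SYMBOL_INDEX[b]] == 0:
                    continue
                p = self.probability(a, b)
                if p >= confidence_threshold:
                    edges.append((a, b, p))
        nodes = sorted(
            {a for a, _b, _p in edges} | {b for _a, b, _p in edges},
            key=lambda s: SYMBOL_INDEX[s],
        )
        for node in nodes:
            buf.write(f'  "{node}";\n')
        for a, b, p in edges:
            mu, sigma, _n = self.pair_stats(a, b)
            label = f"p={p:.2f}"
            if mu is not None:
                label += f", mu_t={mu:.1f}s"
            if sigma is not None:
                label += f", sigma_t={sigma:.1f}s"
            buf.write(f'  "{a}" -> "{b}" [label="{label}"];\n')
        buf.write("}\n")
        return buf.getvalue()
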