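"""The shared event currency of all services.

A :class:`SensorEvent` is one timestamped symbol from the nighttime
alphabet: PIR motion in the bathroom (Ba), kitchen (K), hallway (H) or
living room (L); wearable-inertial inactivity (I); a door opening (D);
and bed entrance / exit (Bin / Bout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Fixed event alphabet, in canonical order.
ALPHABET: tuple[str, ...] = ("Ba", "K", "H", "L", "I", "D", "Bin", "Bout")

SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}


class UnknownSymbolError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class SensorEvent:
    ts: pd.Timestamp
    symbol: str = field(compare=False)
    night_id: str = field(default="", compare=False)
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.symbol not in SYMBOL_INDEX:
            raise UnknownSymbolError(
                f"unknown event symbol {self.symbol!r}; expected one of {ALPHABET}"
            )
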