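"""In-process active-database substrate.

An :class:`Engine` holds named tables, AFTER-INSERT row triggers with
``WHEN``-style conditions, and publish/subscribe notification channels —
the event-condition-action (ECA) machinery of an active DBMS, re-created
as a small synchronous in-memory component so the monitoring services can
be wired together and tested deterministically.

Tables may be FIFO-bounded: a table created with ``fifo_capacity=c`` keeps
only the ``c`` most recent rows, and its engine-assigned ``sample_id``
wraps around ``1..c``.  A trigger whose condition is
``row["sample_id"] == c`` therefore fires exactly once per full window of
``c`` inserts — the cadence used by the bed-presence service.

Semantics are single-threaded and synchronous: triggers run inline in
registration order during :meth:`Engine.insert`, and ``notify`` delivers
payloads to subscribers immediately, in subscription order.  A failing
trigger action does not undo the insert; remaining triggers still run and
the first exception is re-raised afterwards.  Subscriber callback failures
are isolated (logged, never propagated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

logger = logging.getLogger(__name__)

Row = dict
Condition = Callable[[Row], bool]
Action = Callable[[Row], None]


class EngineError(Exception):
    """Base class for engine contract violations."""


class DuplicateTableError(EngineError):
    pass


class UnknownTableError(EngineError):
    pass


class SchemaError(EngineError):
    pass


@dataclass
class Table:
    """An append-ordered table, optionally FIFO-bounded.

    ``columns`` is an ordered list of ``(name, semantic_type)`` pairs;
    only the column names are enforced on insert (the engine stores plain
    dict rows).  ``sample_id`` is engine-assigned: it cycles ``1..capacity``
    for FIFO tables and counts monotonically otherwise.
    """

    name: str
    columns: list[tuple[str, str]]
    fifo_capacity: int | None = None
    rows: list[Row] = field(default_factory=list)
    _inserted: int = 0

    @property
    def column_names(self) -> list[str]:
        return [c[0] for c in self.columns]

    def next_sample_id(self) -> int:
        if self.fifo_capacity is not None:
            return (self._inserted % self.fifo_capacity) + 1
        return self._inserted + 1


@dataclass
class TriggerRule:
    """AFTER-INSERT ECA rule: fire ``action(new_row)`` when ``condition(new_row)``."""

    table: str
    condition: Condition
    action: Action
    timing: str = "AFTER_INSERT"
    name: str = ""


class Engine:
    """Tables + triggers + notification channels under one roof."""

    def __init__(self) -> None:
        self._tables: dict[str, Table] = {}
        self._triggers: dict[str, list[tuple[int, TriggerRule]]] = {}
        self._next_trigger_id = 1
        self._channels: dict[str, list[Callable[[str], None]]] = {}

    # -- tables ----------------------------------------------------------

    def create_table(
        self,
        name: str,
        columns: Sequence[tuple[str, str]],
        fifo_capacity: int | None = None,
    ) -> Table:
        if name in self._tables:
            raise DuplicateTableError(f"table {name!r} already exists")
        if fifo_capacity is not None and fifo_capacity < 1:
            raise EngineError(f"fifo_capacity must be >= 1, got {fifo_capacity}")
        table = Table(name=name, columns=list(columns), fifo_capacity=fifo_capacity)
        self._tables[name] = table
        self._triggers[name] = []
        return table

    def table(self, name: str) -> Table:
        try:
            return self._tables[name]
        except KeyError:
            raise UnknownTableError(f"no table named {name!r}") from None

    def insert(self, table_name: str, row: Mapping[str, Any]) -> Row:
        """Append a row, apply FIFO eviction, then evaluate triggers.

        Returns the stored row including the assigned ``sample_id``.
        Triggers run in registration order; if an action raises, the
        remaining triggers still run and the first exception is re-raised.
        """
        table = self.table(table_name)
        expected = set(table.column_names)
        got = set(row)
        if got != expected:
            raise SchemaError(
                f"row columns {sorted(got)} do not match schema "
                f"{sorted(expected)} of table {table_name!r}"
            )
        stored = dict(row)
        stored["sample_id"] = table.next_sample_id()
        table.rows.append(stored)
        table._inserted += 1
        if table.fifo_capacity is not None and len(table.rows) > table.fifo_capacity:
            del table.rows[0]

        first_exc: BaseException | None = None
        for _tid, rule in self._triggers[table_name]:
            try:
                if rule.condition(stored):
                    rule.action(stored)
            except BaseException as exc:  # noqa: BLE001 - re-raised below
                if first_exc is None:
                    first_exc = exc
        if first_exc is not None:
            raise first_exc
        return stored

    # -- triggers --------------------------------------------------------

    def register_trigger(self, rule: TriggerRule) -> int:
        if rule.table not in self._tables:
            raise UnknownTableError(f"no table named {rule.table!r}")
        if rule.timing != "AFTER_INSERT":
            raise EngineError(f"unsupported trigger timing {rule.timing!r}")
        tid = self._next_trigger_id
        self._next_trigger_id += 1
        self._triggers[rule.table].append((tid, rule))
        return tid

    def deregister_trigger(self, trigger_id: int) -> None:
        for rules in self._triggers.values():
            for i, (tid, _rule) in enumerate(rules):
                if tid == trigger_id:
                    del rules[i]
                    return
        raise EngineError(f"no trigger with id {trigger_id}")

    # -- channels --------------------------------------------------------

    def listen(self, channel: str, callback: Callable[[str], None]) -> None:
        subs = self._channels.setdefault(channel, [])
        if callback not in subs:
            subs.append(callback)

    def unlisten(self, channel: str, callback: Callable[[str], None]) -> None:
        subs = self._channels.get(channel, [])
        if callback in subs:
            subs.remove(callback)

    def notify(self, channel: str, payload: str) -> int:
        """Deliver ``payload`` once to each current subscriber, in
        subscription order.  Returns the number of deliveries; callback
        exceptions are logged and swallowed."""
        delivered = 0
        for callback in list(self._channels.get(channel, [])):
            try:
                callback(payload)
                delivered += 1
            except Exception:  # noqa: BLE001 - isolation contract
                logger.exception("subscriber on channel %r failed", channel)
        return delivered
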