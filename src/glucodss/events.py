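"""Dosing / meal diary: the event log the calculator and titrator consume.

Timestamps are minutes since the (naive, local) Unix epoch; the I/O layer
converts to and from ISO-8601 strings.  The log is append-only except for a
30-minute deletion window after entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from typing import Iterable, Iterator

from .core import InvalidArgument

EPOCH = datetime(1970, 1, 1)

DELETE_WINDOW_MIN = 30.0


class EventKind(str, Enum):
    meal_bolus = "meal_bolus"
    correction_bolus = "correction_bolus"
    basal = "basal"


class TrendArrow(str, Enum):
    rising_fast = "rising_fast"
    rising = "rising"
    stable = "stable"
    falling = "falling"
    falling_fast = "falling_fast"


class OverrideReason(str, Enum):
    dose_higher_than_usual = "dose_higher_than_usual"
    exercise = "exercise"
    sick = "sick"
    stress = "stress"
    menstrual_cycle = "menstrual_cycle"
    alcohol = "alcohol"
    none = "none"


def minutes_to_datetime(minutes: float) -> datetime:
    return EPOCH + timedelta(minutes=float(minutes))


def datetime_to_minutes(dt: datetime) -> float:
    return (dt - EPOCH).total_seconds() / 60.0


@dataclass
class DoseEvent:
    """One diary entry: a rapid-acting bolus or a basal log.

    ``overridden`` records that the user delivered something other than the
    recommendation; the ``override_reason`` is a note only and never enters
    any dose computation.
    """

    timestamp: float  # minutes since epoch
    kind: EventKind
    delivered: float  # units
    carbs: float | None = None  # grams
    glucose: float | None = None  # sensor mmol/L at entry
    arrow: TrendArrow | None = None
    recommended: float | None = None
    overridden: bool = False
    override_reason: OverrideReason = OverrideReason.none
    meal_type: str | None = None
    event_id: int | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)
        if self.arrow is not None:
            self.arrow = TrendArrow(self.arrow)
        self.override_reason = OverrideReason(self.override_reason)
        if self.delivered < 0:
            raise InvalidArgument("delivered dose must be >= 0")
        if self.recommended is not None:
            self.overridden = bool(abs(self.delivered - self.recommended) > 1e-9)


class NotFound(KeyError):
    """Raised when an event id does not exist in the log."""


class EventLog:
    """Time-sorted collection of :class:`DoseEvent` with stable ids."""

    def __init__(self, events: Iterable[DoseEvent] = ()) -> None:
        self._events: list[DoseEvent] = []
        self._next_id = 0
        for ev in events:
            self.append(ev)

    def append(self, event: DoseEvent) -> DoseEvent:
        if event.event_id is None:
            event.event_id = self._next_id
        self._next_id = max(self._next_id, event.event_id) + 1
        self._events.append(event)
        self._events.sort(key=lambda e: (e.timestamp, e.event_id))
        return event

    def __iter__(self) -> Iterator[DoseEvent]:
        return iter(self._events)

    def __len__(self) -> int:
        return len(self._events)

    def between(self, start: float, end: float) -> list[DoseEvent]:
        """Events with ``start <= timestamp < end``."""
        return [e for e in self._events if start <= e.timestamp < end]

    def of_kind(self, *kinds: EventKind) -> list[DoseEvent]:
        kinds_ = {EventKind(k) for k in kinds}
        return [e for e in self._events if e.kind in kinds_]

    def delete_entry(self, event_id: int, now: float) -> bool:
        """Remove an entry if still inside the 30-minute deletion window.

        Returns True when removed; False (log unchanged) when the window has
        expired.  Unknown ids raise :class:`NotFound`.
        """
        for i, ev in enumerate(self._events):
            if ev.event_id == event_id:
                if now - ev.timestamp <= DELETE_WINDOW_MIN:
                    del self._events[i]
                    return True
                return False
        raise NotFound(event_id)
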