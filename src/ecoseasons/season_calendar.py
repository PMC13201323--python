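"""Seasonal space-use calendars on a circular 365-day ordinal year.

A :class:`SeasonCalendar` is the pipeline's headline output: an ordered set
of space-use states whose day windows tile the ordinal year (day 1 through
day 365, wrapping at the year boundary), with one transition date per
adjacent state pair.  A transition date is the first ordinal day of the new
state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

DAYS_PER_YEAR = 365


def circular_day(day: int) -> int:
    """Wrap an integer day onto 1..365."""
    return (int(day) - 1) % DAYS_PER_YEAR + 1


def circular_span(start: int, end: int) -> int:
    """Number of days in the inclusive circular window start..end."""
    return (end - start) % DAYS_PER_YEAR + 1


def circular_diff(day_a: int, day_b: int) -> int:
    """Signed shortest-arc difference ``day_a - day_b`` in days.

    Positive means ``day_a`` falls later than ``day_b`` along the shorter
    arc of the circular year; the result lies in [-182, 182].
    """
    d = (int(day_a) - int(day_b)) % DAYS_PER_YEAR
    if d > DAYS_PER_YEAR / 2:
        d -= DAYS_PER_YEAR
    return d


def circular_midpoint(day_a: int, day_b: int) -> int:
    """Midpoint of two ordinal days along the shorter arc, rounded half-up."""
    d = circular_diff(day_b, day_a)
    # round half-up: floor(x + 0.5) handles the .5 midpoints deterministically
    import math

    mid = int(day_a) + math.floor(d / 2 + 0.5)
    return circular_day(mid)


@dataclass
class SeasonState:
    """One space-use state: an inclusive circular window of ordinal days."""

    label: str
    start_day: int
    end_day: int

    def contains(self, day: int) -> bool:
        day = circular_day(day)
        if self.start_day <= self.end_day:
            return self.start_day <= day <= self.end_day
        return day >= self.start_day or day <= self.end_day

    @property
    def n_days(self) -> int:
        return circular_span(self.start_day, self.end_day)


@dataclass
class SeasonCalendar:
    """Ordered space-use states tiling the 365-day circle."""

    states: list[SeasonState]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.states) >= 2:
            total = sum(s.n_days for s in self.states)
            if total != DAYS_PER_YEAR:
                raise ValueError(
                    f"state windows cover {total} days, expected {DAYS_PER_YEAR}"
                )
            for prev, cur in zip(self.states, self.states[1:] + self.states[:1]):
                if circular_day(prev.end_day + 1) != cur.start_day:
                    raise ValueError(
                        f"gap between state {prev.label!r} (ends {prev.end_day}) "
                        f"and {cur.label!r} (starts {cur.start_day})"
                    )
        elif len(self.states) == 1:
            s = self.states[0]
            if s.n_days != DAYS_PER_YEAR:
                raise ValueError("a single state must cover the full year")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def state_of(self, day: int) -> str:
        day = circular_day(day)
        for s in self.states:
            if s.contains(day):
                return s.label
        raise ValueError(f"day {day} not covered")  # unreachable if tiled

    def transitions(self) -> list[dict]:
        """One transition per adjacent state pair (none for a single state).

        Each entry gives the outgoing state, the incoming state, and the
        transition date = the incoming state's first ordinal day.
        """
        if len(self.states) < 2:
            return []
        out = []
        for prev, cur in zip(self.states, self.states[1:] + self.states[:1]):
            out.append(
                {"from": prev.label, "to": cur.label, "day": cur.start_day}
            )
        return out

    def day_labels(self):
        """Label per ordinal day 1..365 as a list of length 365."""
        return [self.state_of(d) for d in range(1, DAYS_PER_YEAR + 1)]

    def to_dict(self) -> dict:
        return {
            "states": [
                {"label": s.label, "start_day": s.start_day, "end_day": s.end_day}
                for s in self.states
            ],
            "transitions": self.transitions(),
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "SeasonCalendar":
        states = [
            SeasonState(s["label"], int(s["start_day"]), int(s["end_day"]))
            for s in d["states"]
        ]
        return cls(states=states, provenance=d.get("provenance", {}))

    @classmethod
    def from_json(cls, path: str | Path) -> "SeasonCalendar":
        return cls.from_dict(json.loads(Path(path).read_text()))
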