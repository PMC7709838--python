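"""The positional testing schedule.

The protocol this package models administers a cognitive battery while the
subject is moved through body positions: a seated baseline, a block of
head-down (Trendelenburg, 17 degrees) tilt with the battery repeated at a
fixed interval, a supine recovery hour with one mid-recovery sitting of the
battery, and a final sitting immediately after the subject sits up.  Under
the default parameters (30-minute interval, 3 h head-down, 1 h supine) this
yields nine testing occasions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .exceptions import ConfigurationError

POSITIONS = ("sitting", "trendelenburg", "supine")


@dataclass(frozen=True)
class Occasion:
    """One administration of the full battery."""

    index: int
    label: str
    position: str
    minutes_from_start: float

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ConfigurationError(
                f"unknown position {self.position!r}; expected one of {POSITIONS}"
            )
        if self.minutes_from_start < 0:
            raise ConfigurationError("minutes_from_start must be non-negative")


@dataclass(frozen=True)
class TimepointSchedule:
    """Ordered testing occasions over the positional protocol.

    Invariants: indices start at 1 and increase by 1, minutes strictly
    increase, the first occasion is the seated baseline at minute 0, at least
    one head-down occasion follows, then exactly one supine occasion and a
    final sitting occasion.
    """

    occasions: tuple[Occasion, ...]

    def __post_init__(self) -> None:
        occ = self.occasions
        if len(occ) < 4:
            raise ConfigurationError("schedule needs baseline, head-down, supine and sitting occasions")
        if [o.index for o in occ] != list(range(1, len(occ) + 1)):
            raise ConfigurationError("occasion indices must be 1..n without gaps")
        minutes = [o.minutes_from_start for o in occ]
        if any(b <= a for a, b in zip(minutes, minutes[1:])):
            raise ConfigurationError("minutes_from_start must be strictly increasing")
        pattern = [o.position for o in occ]
        if pattern[0] != "sitting" or occ[0].minutes_from_start != 0:
            raise ConfigurationError("occasion 1 must be the seated baseline at minute 0")
        if pattern[-1] != "sitting" or pattern[-2] != "supine":
            raise ConfigurationError("schedule must end with one supine then one sitting occasion")
        if any(p != "trendelenburg" for p in pattern[1:-2]):
            raise ConfigurationError("occasions between baseline and recovery must be trendelenburg")

    def __len__(self) -> int:
        return len(self.occasions)

    def __iter__(self) -> Iterator[Occasion]:
        return iter(self.occasions)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(o.index for o in self.occasions)

    def label_of(self, index: int) -> str:
        for o in self.occasions:
            if o.index == index:
                return o.label
        raise KeyError(index)


def _fmt_minutes(m: float) -> str:
    return f"{m:g}"


def make_schedule(
    interval_minutes: float = 30,
    trendelenburg_hours: float = 3,
    supine_hours: float = 1,
) -> TimepointSchedule:
    """Build the positional testing schedule.

    The battery runs at baseline (sitting, minute 0), every ``interval_minutes``
    of head-down tilt — the last of these immediately after moving supine,
    labelled accordingly — then once mid-way through the supine period and once
    on sitting up at its end.

    Parameters
    ----------
    interval_minutes
        Testing interval during the head-down block; must divide the block
        duration evenly.
    trendelenburg_hours, supine_hours
        Durations of the head-down and supine blocks.

    Raises
    ------
    ConfigurationError
        If the interval does not divide the head-down duration.
    """
    if interval_minutes <= 0 or trendelenburg_hours <= 0 or supine_hours <= 0:
        raise ConfigurationError("interval and durations must be positive")
    trend_min = trendelenburg_hours * 60.0
    supine_min = supine_hours * 60.0
    n_steps = trend_min / interval_minutes
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigurationError(
            f"interval {interval_minutes:g} min does not divide the "
            f"{trend_min:g}-minute head-down period evenly"
        )
    n_steps = int(round(n_steps))

    occasions = [Occasion(1, "Baseline (sitting)", "sitting", 0.0)]
    for k in range(1, n_steps + 1):
        m = k * interval_minutes
        if k < n_steps:
            label = f"{_fmt_minutes(m)} minutes after Trendelenburg positioning"
        else:
            label = (
                f"Supine (after {_fmt_minutes(trend_min)} minutes in the "
                "Trendelenburg position)"
            )
        occasions.append(Occasion(1 + k, label, "trendelenburg", m))
    mid = supine_min / 2.0
    occasions.append(
        Occasion(
            2 + n_steps,
            f"{_fmt_minutes(mid)} minutes after supine positioning",
            "supine",
            trend_min + mid,
        )
    )
    occasions.append(
        Occasion(
            3 + n_steps,
            f"Sitting up ({_fmt_minutes(supine_min)} minutes after supine positioning)",
            "sitting",
            trend_min + supine_min,
        )
    )
    return TimepointSchedule(tuple(occasions))
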