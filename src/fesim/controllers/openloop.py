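"""Open-loop stimulation schedules.

The open-loop case applies a precomputed effort schedule with no
feedback: either a constant effort from an onset time (the step case,
with the constant found offline so the steady-state displacement hits
the desired amplitude) or an arbitrary (t, effort) table interpolated
with zero-order hold.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

__all__ = ["OpenLoopSchedule", "openloop_update"]


@dataclass
class OpenLoopSchedule:
    """Fixed effort schedule.

    ``effort`` is applied from ``onset`` onward; if ``table`` is given
    (list of (time, effort) pairs, sorted) it takes precedence and is
    sampled with zero-order hold.
    """

    effort: float = 0.0
    onset: float = 0.0
    table: list[tuple[float, float]] | None = None
    _times: list[float] = field(init=False, default_factory=list)

    def __post_init__(self) -> None:
        if self.table is not None:
            if not self.table:
                raise ValueError("schedule table must be nonempty")
            self._times = [t for t, _ in self.table]
            if self._times != sorted(self._times):
                raise ValueError("schedule table times must be sorted")


def openloop_update(t: float, spec: OpenLoopSchedule) -> float:
    """Effort at time ``t``; independent of any plant feedback."""
    if spec.table is not None:
        i = bisect.bisect_right(spec._times, t) - 1
        if i < 0:
            return 0.0
        return spec.table[i][1]
    return spec.effort if t >= spec.onset else 0.0
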