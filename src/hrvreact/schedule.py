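"""Stress-relaxation measurement protocol schedule.

The protocol alternates relaxation and cognitive stress (mental arithmetic)
in five contiguous four-minute phases:

    relax1 | stress1 | relax2 | stress2 | relax3

for a total of 20 minutes.  HRV is summarised over six analysis windows:
a 30-s baseline at the very start of the recording, and a 3-min sample
per phase starting 20 s after phase onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PHASE_LABELS = ("relax1", "stress1", "relax2", "stress2", "relax3")
#: Baseline + the five phases, in protocol order.
WINDOW_LABELS = ("baseline",) + PHASE_LABELS
STRESS_PHASES = ("stress1", "stress2")

DEFAULT_PHASE_DURATION_S = 240.0
DEFAULT_BASELINE_DURATION_S = 30.0
DEFAULT_WINDOW_OFFSET_S = 20.0
DEFAULT_WINDOW_DURATION_S = 180.0


@dataclass(frozen=True)
class Phase:
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PhaseSchedule:
    """Contiguous protocol phases plus per-label analysis windows.

    ``windows`` maps a window label (``baseline`` or a phase label) to
    ``(start_s, duration_s)``; windows are half-open ``[start, start+dur)``.
    """

    phases: tuple[Phase, ...]
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.phases, self.phases[1:]):
            if abs(prev.end_s - cur.start_s) > 1e-9:
                raise ValueError(
                    f"phases must be contiguous: {prev.label} ends at "
                    f"{prev.end_s}, {cur.label} starts at {cur.start_s}"
                )
        for label, (start, dur) in self.windows.items():
            if dur <= 0:
                raise ValueError(f"window {label!r} has non-positive duration")
            if start < self.start_s - 1e-9 or start + dur > self.end_s + 1e-9:
                raise ValueError(f"window {label!r} lies outside the recording")

    @property
    def start_s(self) -> float:
        return self.phases[0].start_s

    @property
    def end_s(self) -> float:
        return self.phases[-1].end_s

    @property
    def total_duration_s(self) -> float:
        return self.end_s - self.start_s

    def phase(self, label: str) -> Phase:
        for p in self.phases:
            if p.label == label:
                return p
        raise KeyError(label)

    def window(self, label: str) -> tuple[float, float]:
        return self.windows[label]

    @property
    def window_labels(self) -> tuple[str, ...]:
        return tuple(self.windows)


def build_default_schedule(
    phase_duration_s: float = DEFAULT_PHASE_DURATION_S,
    baseline_duration_s: float = DEFAULT_BASELINE_DURATION_S,
    window_offset_s: float = DEFAULT_WINDOW_OFFSET_S,
    window_duration_s: float = DEFAULT_WINDOW_DURATION_S,
) -> PhaseSchedule:
    """Build the default 20-min protocol schedule.

    Five contiguous ``phase_duration_s`` phases starting at t=0; the
    baseline window is ``[0, baseline_duration_s)`` (the recording opens
    with relax1, so baseline sits inside relax1's span but before its
    analysis window); each phase's analysis window is
    ``[start+window_offset_s, start+window_offset_s+window_duration_s)``.
    """
    if window_offset_s + window_duration_s > phase_duration_s:
        raise ValueError("analysis window does not fit inside a phase")
    phases = tuple(
        Phase(label, i * phase_duration_s, (i + 1) * phase_duration_s)
        for i, label in enumerate(PHASE_LABELS)
    )
    windows: dict[str, tuple[float, float]] = {
        "baseline": (0.0, baseline_duration_s)
    }
    for p in phases:
        windows[p.label] = (p.start_s + window_offset_s, window_duration_s)
    return PhaseSchedule(phases=phases, windows=windows)
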