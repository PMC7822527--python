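"""Proposal-locked analysis windows and the complementary segmentation.

Each proposal contributes a window from 1 s before its end to 4 s after it
(the recipient can often anticipate the proposal's content before it is
finished, and SCRs lag their stimulus by seconds). Windows are half-open
``[t0, t1)`` and are kept per-event for rate analysis; for synchrony they
are merged into disjoint proposal segments whose complement within the task
span is the non-proposal segmentation. The two partitions tile the task
span exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


from .errors import ParameterError
from .io_formats import ProposalEvent

DEFAULT_PRE = 1.0
DEFAULT_POST = 4.0


@dataclass(frozen=True)
class Window:
    """Half-open interval [t0, t1) locked to one proposal's end."""

    event_id: str
    t0: float
    t1: float
    clipped: bool = False

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


@dataclass
class Segmentation:
    """Disjoint proposal segments and their complement within the task span."""

    proposal_segments: list[tuple[float, float]]
    nonproposal_segments: list[tuple[float, float]]
    task_start: float
    task_end: float

    def total_duration(self, kind: str) -> float:
        segs = (self.proposal_segments if kind == "proposal"
                else self.nonproposal_segments)
        return float(sum(b - a for a, b in segs))


def build_proposal_windows(
    events: list[ProposalEvent],
    pre: float = DEFAULT_PRE,
    post: float = DEFAULT_POST,
    recording_start: float | None = None,
    recording_end: float | None = None,
) -> list[Window]:
    """One window [t_end - pre, t_end + post) per event.

    Windows of nearby events may overlap and are all retained: each is a
    separate observation for the rate analysis. Windows running past the
    recording edge (if bounds are given) are clipped and flagged.
    """
    if pre < 0 or post < 0:
        raise ParameterError(f"pre/post must be non-negative, got {pre}, {post}")
    windows = []
    for e in events:
        t0, t1 = e.t_end - pre, e.t_end + post
        clipped = False
        if recording_start is not None and t0 < recording_start:
            t0, clipped = recording_start, True
        if recording_end is not None and t1 > recording_end:
            t1, clipped = recording_end, True
        if clipped:
            warnings.warn(
                f"window for event {e.event_id} clipped to [{t0}, {t1})"
            )
        if t1 > t0:
            windows.append(Window(event_id=e.event_id, t0=t0, t1=t1,
                                  clipped=clipped))
    return windows


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of half-open intervals as a sorted disjoint list."""
    ivs = sorted((a, b) for a, b in intervals if b > a)
    merged: list[list[float]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def segment_task(
    windows: list[Window], task_start: float, task_end: float
) -> Segmentation:
    """Partition [task_start, task_end) into proposal and non-proposal time.

    Proposal segments are the merged union of the windows clipped to the
    task span; non-proposal segments are the exact set complement, so the
    two lists tile the span with no gap or overlap.
    """
    if task_end <= task_start:
        raise ParameterError(
            f"task_end {task_end} must exceed task_start {task_start}"
        )
    raw = []
    for w in windows:
        a, b = max(w.t0, task_start), min(w.t1, task_end)
        if (w.t0 < task_start or w.t1 > task_end) and b > a:
            warnings.warn(
                f"window for event {w.event_id} extends outside the task span; clipped"
            )
        if b > a:
            raw.append((a, b))
        elif w.t1 <= task_start or w.t0 >= task_end:
            warnings.warn(f"window for event {w.event_id} lies outside the task span; dropped")
    proposal = merge_intervals(raw)
    nonproposal = []
    cursor = task_start
    for a, b in proposal:
        if a > cursor:
            nonproposal.append((cursor, a))
        cursor = b
    if cursor < task_end:
        nonproposal.append((cursor, task_end))
    return Segmentation(proposal_segments=proposal,
                        nonproposal_segments=nonproposal,
                        task_start=task_start, task_end=task_end)


def infer_task_span(events: list[ProposalEvent],
                    pre: float = DEFAULT_PRE,
                    post: float = DEFAULT_POST) -> tuple[float, float]:
    """Default task span: first annotation start (minus pre) to last end plus post."""
    if not events:
        raise ParameterError("cannot infer a task span from zero events")
    return (min(e.t_start for e in events) - pre,
            max(e.t_end for e in events) + post)
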