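"""Brain-state labels and segment bookkeeping.

The study design steps isoflurane anesthesia from the deepest level (2%)
down to wakefulness; every recording concatenates the six states in that
fixed order. All modules index states by the canonical tuple below.
"""

from __future__ import annotations

from typing import NamedTuple

#: Canonical state order, deepest anesthesia first, awake last.
STATES: tuple[str, ...] = ("iso2.0", "iso1.75", "iso1.5", "iso1.0", "iso0.5", "awake")

DEEPEST: str = STATES[0]
AWAKE: str = STATES[-1]


class Segment(NamedTuple):
    """Half-open frame range [start, end) of one brain state inside a session."""

    state: str
    start: int
    end: int


def state_index(state: str) -> int:
    """Position of ``state`` in the deepest-to-awake order."""
    try:
        return STATES.index(state)
    except ValueError:
        raise ValueError(f"unknown state label {state!r}; expected one of {STATES}") from None


def validate_segments(segments: list[Segment], n_frames: int | None = None) -> None:
    """Check segments are disjoint, in deepest-to-awake order, inside [0, T)."""
    if not segments:
        raise ValueError("empty segment list")
    prev_end = 0
    prev_idx = -1
    for seg in segments:
        idx = state_index(seg.state)
        if idx <= prev_idx:
            raise ValueError("segments out of deepest-to-awake order")
        if seg.start < prev_end or seg.end <= seg.start:
            raise ValueError(f"segment {seg} overlaps or is empty")
        if n_frames is not None and seg.end > n_frames:
            raise ValueError(f"segment {seg} exceeds movie length {n_frames}")
        prev_end = seg.end
        prev_idx = idx


def segment_for(segments: list[Segment], state: str) -> Segment:
    for seg in segments:
        if seg.state == state:
            return seg
    raise KeyError(f"no segment for state {state!r}")
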