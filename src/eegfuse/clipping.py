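"""Multi-scale clipping (MSC): windowing plus C-fold translation augmentation.

A record of N samples is cut into non-overlapping windows of X samples
(the tail shorter than X is discarded).  MSC augments this grid C-fold by
repeating it at C shifted origins ("parts"): part k (1-based) starts at
offset ``(k - 1) * round_half_up(X / C)`` samples.  AU-N denotes the
unaugmented grid (C = 1); AU-2/AU-4/AU-8 denote C = 2/4/8.  With X = 2100:

    C = 2 -> part offsets 0, 1050
    C = 4 -> part offsets 0, 525, 1050, 1575
    C = 8 -> X/C = 262.5 rounds half-up to 263 -> offsets 0, 263, 526, ... 1841

Part 1 of any AU-C is therefore identical to AU-N, and within one part
consecutive windows are disjoint and contiguous (stride exactly X).  All
indices are 1-based inclusive, matching the field's sample-numbering
convention for these constructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from eegfuse.types import MultichannelRecord


@dataclass(frozen=True)
class ClipConfig:
    """Window length X (samples) and augmentation factor C (C=1 means AU-N)."""

    window_length: int = 2100
    factor: int = 1

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError(f"window_length must be >= 2, got {self.window_length}")
        if self.factor < 1:
            raise ValueError(f"factor must be >= 1, got {self.factor}")


@dataclass(frozen=True)
class Segment:
    """One fixed-length window of a record (1-based inclusive indices).

    ``end - start + 1`` equals the window length; ``part`` identifies which
    shifted grid (1..C) the window belongs to.
    """

    record_ref: str
    start: int
    end: int
    part: int
    label: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid segment range [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def slice(self, record: MultichannelRecord):
        """Extract this window's data from ``record`` (channels x X)."""
        return record.data[:, self.start - 1 : self.end]


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero upward (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def part_offset(window_length: int, factor: int, part: int) -> int:
    """Start offset (samples) of part ``part``'s window grid.

    Part k's grid is the AU-N grid shifted right by
    ``(k - 1) * round_half_up(X / C)`` samples; part 1 is unshifted.
    """
    if not 1 <= part <= factor:
        raise ValueError(f"part must be in 1..{factor}, got {part}")
    return (part - 1) * round_half_up(window_length / factor)


def _grid_starts(n_samples: int, window_length: int, offset: int) -> list[int]:
    """1-based start indices of full windows at stride X from ``offset``."""
    count = max(0, (n_samples - offset) // window_length)
    return [offset + m * window_length + 1 for m in range(count)]


def segment_windows(record: MultichannelRecord, window_length: int) -> list[Segment]:
    """Non-overlapping AU-N windowing: (1..X), (X+1..2X), ...; tail discarded."""
    return [
        Segment(record.subject_id, s, s + window_length - 1, part=1, label=record.label)
        for s in _grid_starts(record.n_samples, window_length, 0)
    ]


def msc_augment(record: MultichannelRecord, config: ClipConfig) -> list[Segment]:
    """All windows of all C parts, ordered by part then start.

    Each part contributes its own contiguous stride-X grid; windows that
    would overrun the record are discarded per part.  ``factor=1`` reduces
    exactly to :func:`segment_windows`.
    """
    X, C = config.window_length, config.factor
    segments = []
    for part in range(1, C + 1):
        off = part_offset(X, C, part)
        segments.extend(
            Segment(record.subject_id, s, s + X - 1, part=part, label=record.label)
            for s in _grid_starts(record.n_samples, X, off)
        )
    return segments


def expected_sample_count(n_samples: int, window_length: int, factor: int) -> int:
    """Exact realized window count of MSC: sum over parts of each grid's count.

    Equals ``sum_k floor((N - offset_k) / X)``; at most ``C * floor(N/X)`` and,
    for records much longer than X, close to C times the unaugmented count.
    """
    if window_length < 1 or factor < 1:
        raise ValueError("window_length and factor must be >= 1")
    return sum(
        max(0, (n_samples - part_offset(window_length, factor, k)) // window_length)
        for k in range(1, factor + 1)
    )
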