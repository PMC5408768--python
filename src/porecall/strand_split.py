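"""Strand separation by abasic-hairpin detection.

The hairpin adapter joining the template and complement strands contains
abasic DNA, which produces anomalously high current: regular DNA sits
around 50-90 pA while abasic stretches exceed 100 pA.  Because the exact
levels are distorted by the unknown per-read shift/scale, the abasic
threshold is estimated per read as the 99th-percentile event level plus
5 pA.  Runs of 5 or more consecutive above-threshold events form islands;
nearby islands (separated by fewer than 50 events) are merged; the island
closest to the middle of the read splits it into template and complement,
provided its midpoint falls within the middle third of the event sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pore_model import EventSequence

__all__ = ["SplitResult", "abasic_threshold", "find_islands", "split_read"]

MIN_ISLAND_EVENTS = 5
MERGE_GAP_EVENTS = 50
THRESHOLD_MARGIN_PA = 5.0


@dataclass
class SplitResult:
    """Event-index ranges (half-open) of the strands and the hairpin.

    When no acceptable hairpin island is found, ``template_range`` covers
    the whole read and both ``hairpin_island`` and ``complement_range`` are
    absent.
    """

    template_range: tuple[int, int]
    complement_range: tuple[int, int] | None
    hairpin_island: tuple[int, int] | None
    threshold: float

    @property
    def is_split(self) -> bool:
        return self.complement_range is not None


def abasic_threshold(events: EventSequence) -> float:
    """Abasic current threshold: nearest-rank 99th percentile of event
    means, plus 5 pA."""
    n = len(events)
    if n == 0:
        raise ValueError("cannot estimate abasic threshold of an empty read")
    rank = max(1, math.ceil(0.99 * n))  # nearest-rank percentile
    level = np.sort(events.mean)[rank - 1]
    return float(level) + THRESHOLD_MARGIN_PA


def find_islands(events: EventSequence, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of >=5 consecutive events above threshold, with runs
    separated by fewer than 50 events merged transitively."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    above = events.mean > threshold
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= MIN_ISLAND_EVENTS:
                runs.append((i, j))
            i = j
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < MERGE_GAP_EVENTS:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return merged


def split_read(events: EventSequence) -> SplitResult:
    """Split a read into template and complement at the hairpin island.

    The island whose midpoint is nearest the middle of the event sequence
    is the candidate (ties resolve to the earlier island); it splits the
    read only if its midpoint lies in the middle third of the indices,
    [floor(n/3), floor(2n/3)).  Island events belong to neither strand.
    """
    n = len(events)
    threshold = abasic_threshold(events)
    islands = find_islands(events, threshold)
    no_split = SplitResult((0, n), None, None, threshold)
    if not islands:
        return no_split
    centre = n / 2.0
    best = min(islands, key=lambda r: abs((r[0] + r[1]) / 2.0 - centre))
    mid = (best[0] + best[1]) / 2.0
    if not (n // 3 <= mid < (2 * n) // 3):
        return no_split
    return SplitResult(
        template_range=(0, best[0]),
        complement_range=(best[1], n),
        hairpin_island=best,
        threshold=threshold,
    )
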