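"""Per-read filters: quality/N filter, error-tolerant polyX filter, bubble filter.

Bad reads are annotated (the failing filter's name is appended to the read
name) and streamed to the bad output. For paired-end data, if either mate
fails, both mates are routed to the bad stream so pairing is preserved in the
good output. The pass/fail partition does not depend on the order the filters
run; the reported reason is fixed by the order quality -> n_count -> polyX ->
bubble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

from .fastq_io import PHRED_OFFSET, FlowcellCoord, SequenceRead

FILTER_REASONS = ("quality", "n_count", "polyX", "bubble",
                  "too_short_after_trim", "overlap_indel")

BAD_ANNOTATION = "fail:"

DEFAULT_LOW_QUAL = 15
DEFAULT_MAX_LOW_QUAL_FRACTION = 0.40
DEFAULT_MAX_N = 5
DEFAULT_MIN_MEAN_QUAL = 20.0


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.passed != (self.reason == ""):
            raise ValueError("passed verdicts carry no reason; failed ones must")


PASS = FilterVerdict(passed=True)


@dataclass(frozen=True)
class PolyXParams:
    """polyX detection: a stretch of at least P bases of one base X with at
    most L non-X bases tolerated inside it."""

    P: int = 35
    L: int = 2

    def __post_init__(self) -> None:
        if self.P < 1 or self.L < 0 or self.L >= self.P:
            raise ValueError(f"invalid polyX params P={self.P}, L={self.L}")


def detect_polyx(seq: str, params: PolyXParams = PolyXParams()
                 ) -> Tuple[bool, Optional[str], Optional[Tuple[int, int]]]:
    """Error-tolerant polyX detection.

    A read is flagged when for some X in A,C,G,T there is a window [i, i+P)
    with at most L positions differing from X, anchored on X at both ends
    (seq[i] == seq[i+P-1] == X, so tolerated non-X bases cannot dangle at the
    run edges). N counts as non-X. Returns (found, base, (start, end)) with
    the leftmost qualifying span of the first qualifying X in A,C,G,T order.
    """
    P, L = params.P, params.L
    n = len(seq)
    if n < P:
        return False, None, None
    for x in "ACGT":
        # prefix[i] = number of non-x bases in seq[:i]
        prefix = [0] * (n + 1)
        for i, b in enumerate(seq):
            prefix[i + 1] = prefix[i] + (b != x)
        for i in range(n - P + 1):
            if seq[i] != x or seq[i + P - 1] != x:
                continue
            if prefix[i + P] - prefix[i] <= L:
                return True, x, (i, i + P)
    return False, None, None


def quality_filter(read: SequenceRead,
                   low_qual_threshold: int = DEFAULT_LOW_QUAL,
                   max_low_qual: Optional[int] = None,
                   max_n: int = DEFAULT_MAX_N,
                   min_mean_qual: float = DEFAULT_MIN_MEAN_QUAL) -> FilterVerdict:
    """Count low-quality bases and Ns and check the read's mean quality.

    Fails with reason "n_count" when #N > max_n; with reason "quality" when
    more than max_low_qual bases are below low_qual_threshold or the mean
    Phred score is below min_mean_qual. max_low_qual defaults to 40% of the
    read length.
    """
    if max_low_qual is None:
        max_low_qual = math.floor(DEFAULT_MAX_LOW_QUAL_FRACTION * len(read.bases))
    n_count = read.bases.count("N")
    if n_count > max_n:
        return FilterVerdict(passed=False, reason="n_count")
    phred = read.phred()
    if not phred:
        return PASS
    low = sum(1 for q in phred if q < low_qual_threshold)
    if low > max_low_qual or sum(phred) / len(phred) < min_mean_qual:
        return FilterVerdict(passed=False, reason="quality")
    return PASS


def bubble_filter(coord: Optional[FlowcellCoord],
                  circles: Sequence["BubbleCircle"]) -> FilterVerdict:  # noqa: F821
    """Fail reads whose flowcell coordinate lies strictly inside a detected
    bubble circle of their lane+tile; reads without a coordinate pass."""
    if coord is None:
        return PASS
    for circle in circles:
        if circle.lane != coord.lane or circle.tile != coord.tile:
            continue
        dx = coord.x - circle.center_x
        dy = coord.y - circle.center_y
        if dx * dx + dy * dy < circle.radius * circle.radius:
            return FilterVerdict(passed=False, reason="bubble")
    return PASS


def annotate_bad(read: SequenceRead, reason: str) -> SequenceRead:
    """Append the failing filter's name to the read name (original name kept).

    Not idempotent: annotating twice appends twice — callers annotate once.
    """
    if not reason:
        raise ValueError("reason must be non-empty")
    return replace(read, name=f"{read.name} {BAD_ANNOTATION}{reason}")
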