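"""Global automatic trimming.

A single (front, tail) trim is decided once per file from the pre-filtering
cycle profile and applied to every read identically, so duplicated reads stay
identical after trimming (per-read local trimming breaks mapping-position
based de-duplication). The decision starts from the central cycle, assumed
good, and expands the good region outward cycle by cycle until a side hits an
abnormal cycle or the read end.

A cycle is abnormal when any of these holds:

1. a single base's content is above 40% or below 15% (N exempt);
2. a base's content changes by more than 10 percentage points versus the
   neighbouring cycle toward the centre;
3. GC content is above 70% or below 30%;
4. mean quality is below Q20.

All comparisons are strict. The front side applies only criteria 3 and 4:
unflat base content at the read start usually reflects the fragmentation
method rather than a sequencing artefact and is kept; the tail applies all
four. Trimming is capped at 10% of cycles in front and 5% in tail (floor),
so even a fully chaotic profile cannot discard most of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Tuple

from .fastq_io import SequenceRead
from .qc_profiler import CycleProfile

FRONT_MAX_PERCENT = 10.0
TAIL_MAX_PERCENT = 5.0

# abnormality thresholds (fractions / Phred)
_CONTENT_HIGH = 0.40
_CONTENT_LOW = 0.15
_CONTENT_JUMP = 0.10
_GC_HIGH = 0.70
_GC_LOW = 0.30
_MIN_MEAN_QUAL = 20.0

# cycles supported by fewer than this fraction of the max per-cycle coverage
# are sparse tails of variable-length input and are never called abnormal
_MIN_SUPPORT_FRACTION = 0.10

Side = Literal["front", "tail"]


@dataclass(frozen=True)
class TrimDecision:
    front: int
    tail: int


def is_abnormal_cycle(profile: CycleProfile, cycle: int, side: Side) -> Tuple[bool, str]:
    """Classify one cycle as abnormal for the given side; returns (flag, reason)."""
    n = profile.n_cycles
    if not 0 <= cycle < n:
        raise IndexError(f"cycle {cycle} out of range [0, {n})")
    if side not in ("front", "tail"):
        raise ValueError(f"side must be 'front' or 'tail', got {side!r}")
    max_total = int(profile.totals.max()) if n else 0
    if profile.totals[cycle] < _MIN_SUPPORT_FRACTION * max_total or profile.totals[cycle] == 0:
        return False, ""

    if side == "tail":
        for base in "ACGT":
            frac = profile.base_fraction(cycle, base)
            if frac > _CONTENT_HIGH:
                return True, f"base content {base} {frac:.1%} > {_CONTENT_HIGH:.0%}"
            if frac < _CONTENT_LOW:
                return True, f"base content {base} {frac:.1%} < {_CONTENT_LOW:.0%}"
        centre = n // 2
        neighbour = cycle - 1 if cycle > centre else cycle + 1
        if 0 <= neighbour < n and profile.totals[neighbour] >= _MIN_SUPPORT_FRACTION * max_total:
            for base in "ACGT":
                jump = abs(profile.base_fraction(cycle, base)
                           - profile.base_fraction(neighbour, base))
                if jump > _CONTENT_JUMP:
                    return True, f"base content {base} jumps {jump:.1%} vs neighbour"

    gc = profile.gc_fraction(cycle)
    if gc > _GC_HIGH:
        return True, f"GC {gc:.1%} > {_GC_HIGH:.0%}"
    if gc < _GC_LOW:
        return True, f"GC {gc:.1%} < {_GC_LOW:.0%}"
    mq = float(profile.mean_qual[cycle])
    if mq < _MIN_MEAN_QUAL:
        return True, f"mean quality {mq:.1f} < Q{_MIN_MEAN_QUAL:.0f}"
    return False, ""


def compute_trim(profile: CycleProfile,
                 front_max_percent: float = FRONT_MAX_PERCENT,
                 tail_max_percent: float = TAIL_MAX_PERCENT) -> TrimDecision:
    """Expand a good region outward from the central cycle; trim the rest.

    The centre cycle floor(n/2) is good unconditionally. Each side grows one
    cycle at a time and stops at its first abnormal cycle. The resulting
    front/tail trims are clamped to floor(front_max_percent% / tail_max_percent%
    of n_cycles).
    """
    n = profile.n_cycles
    if n == 0:
        return TrimDecision(front=0, tail=0)
    centre = n // 2
    lo = hi = centre
    while lo > 0:
        flag, _ = is_abnormal_cycle(profile, lo - 1, "front")
        if flag:
            break
        lo -= 1
    while hi < n - 1:
        flag, _ = is_abnormal_cycle(profile, hi + 1, "tail")
        if flag:
            break
        hi += 1
    front = min(lo, int(front_max_percent / 100.0 * n))
    tail = min(n - 1 - hi, int(tail_max_percent / 100.0 * n))
    return TrimDecision(front=front, tail=tail)


def apply_trim(read: SequenceRead, decision: TrimDecision) -> Optional[SequenceRead]:
    """Slice bases and quals to [front, len - tail); name unchanged.

    Returns None when the read is shorter than front + tail + 1 — the caller
    routes such reads to the bad stream (reason "too_short_after_trim")
    instead of raising.
    """
    front, tail = decision.front, decision.tail
    if front + tail >= len(read.bases):
        return None
    if front == 0 and tail == 0:
        return read
    end = len(read.bases) - tail
    return replace(read, bases=read.bases[front:end], quals=read.quals[front:end])
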