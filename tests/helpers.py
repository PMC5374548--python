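"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (full DP tables, exhaustive window and
offset scans, O(n^3) circle search) and shares no code with the package paths
it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Optional, Tuple

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def dp_edit_distance(a: str, b: str) -> int:
    """Full Wagner-Fischer DP table."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def exhaustive_overlap(r1: str, r2: str, min_overlap: int,
                       max_ed_fraction: float
                       ) -> Tuple[int, int, int, bool]:
    """Scan every offset, score with the DP oracle, apply the documented
    tie-break (min ed, max length, min |offset|, positive first).
    Returns (offset, overlap_len, edit_dist, overlapped)."""
    c = revcomp(r2)
    len1, len2 = len(r1), len(r2)
    span = len1 - min_overlap
    best_key = None
    best = None
    for offset in range(-span, span + 1):
        s1 = max(offset, 0)
        e1 = min(len1, offset + len2)
        length = e1 - s1
        if length <= 0:
            continue
        sc = s1 - offset
        ed = dp_edit_distance(r1[s1:e1], c[sc : sc + length])
        key = (ed, -length, abs(offset), 0 if offset >= 0 else 1)
        if best_key is None or key < best_key:
            best_key = key
            best = (offset, length, ed)
    if best is None:
        return 0, 0, 0, False
    offset, length, ed = best
    overlapped = (length >= min_overlap
                  and ed <= max(0, math.floor(max_ed_fraction * length)))
    return offset, length, ed, overlapped


def brute_polyx(seq: str, P: int, L: int) -> bool:
    """All-windows polyX scan: any length-P window with <= L non-X bases,
    anchored on X at both ends, for any X."""
    for x in "ACGT":
        for i in range(len(seq) - P + 1):
            window = seq[i : i + P]
            if window[0] == x and window[-1] == x and \
                    sum(1 for b in window if b != x) <= L:
                return True
    return False


def brute_min_enclosing_circle(points: List[Tuple[float, float]]
                               ) -> Tuple[float, float, float]:
    """O(n^3) search over all 1-, 2- and 3-point support circles."""

    def covers(cx: float, cy: float, r: float) -> bool:
        return all(math.hypot(x - cx, y - cy) <= r + 1e-9 for x, y in points)

    if len(points) == 1:
        return points[0][0], points[0][1], 0.0
    best: Optional[Tuple[float, float, float]] = None
    for (x1, y1), (x2, y2) in itertools.combinations(points, 2):
        cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
        r = math.hypot(x1 - x2, y1 - y2) / 2
        if covers(cx, cy, r) and (best is None or r < best[2]):
            best = (cx, cy, r)
    for (ax, ay), (bx, by), (cx_, cy_) in itertools.combinations(points, 3):
        d = 2 * (ax * (by - cy_) + bx * (cy_ - ay) + cx_ * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = ((ax ** 2 + ay ** 2) * (by - cy_) + (bx ** 2 + by ** 2) * (cy_ - ay)
              + (cx_ ** 2 + cy_ ** 2) * (ay - by)) / d
        uy = ((ax ** 2 + ay ** 2) * (cx_ - bx) + (bx ** 2 + by ** 2) * (ax - cx_)
              + (cx_ ** 2 + cy_ ** 2) * (bx - ax)) / d
        r = math.hypot(ax - ux, ay - uy)
        if covers(ux, uy, r) and (best is None or r < best[2]):
            best = (ux, uy, r)
    assert best is not None
    return best
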