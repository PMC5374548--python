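"""Paired-end overlap analysis: offset search, adapter cutting, base
correction, error-rate profiling and pair merging.

For a DNA template of length T sequenced from both ends at read length S, the
mates overlap by 2S - T when S < T < 2S, overlap completely when T <= S, and
do not overlap when 2S <= T. The engine reverse-complements R2 and slides it
under R1, choosing the offset O that minimises the edit distance of the
vertically aligned subsequences. A negative optimal offset means the template
is shorter than the read length, so the bases beyond the template on the 3'
end of both mates are adapter sequence and are cut — no adapter sequence
input is needed.

Every base in the overlap region was sequenced twice, so mismatches there are
dominated by sequencing errors. When the overlapped slices differ only by
substitutions (Hamming distance equals edit distance), a mismatch where one
base is high quality (>= Q30) and the other very low quality (< Q15) is
resolved by overwriting the low-quality base with its high-quality mate. The
same asymmetric mismatches feed the 12-category base-transform error profile
(how often a true T is read as C, etc.), and mismatch/total over long
overlaps estimates the per-base sequencing error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import edlib

from .fastq_io import PHRED_OFFSET, ReadPair, SequenceRead
from .qc_profiler import reverse_complement

DEFAULT_MIN_OVERLAP = 30
DEFAULT_MAX_ED_FRACTION = 0.05
DEFAULT_HIGH_Q = 30
DEFAULT_LOW_Q = 15
DEFAULT_MIN_PROFILE_OVERLAP = 50

#: the 12 ordered substitution categories (true base -> observed base)
TRANSFORMS: Tuple[str, ...] = tuple(
    f"{a}->{b}" for a in "ACGT" for b in "ACGT" if a != b
)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost substitution/insertion/deletion)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(frozen=True)
class OverlapResult:
    """Best overlap of a read pair.

    ``offset`` is the displacement of reverse-complement(R2) under R1
    (negative: template shorter than the read, adapter present).
    ``mismatch_positions`` holds (pos_in_r1, r1_base, r1_qual, r2_base,
    r2_qual) per positional mismatch, with r2_base/r2_qual the raw R2 base
    (not complemented) and its quality. ``hamming_dist`` equals ``edit_dist``
    iff the overlapped slices differ only by substitutions.
    """

    offset: int
    overlap_len: int
    edit_dist: int
    hamming_dist: Optional[int]
    mismatch_positions: Tuple[Tuple[int, str, int, str, int], ...]
    overlapped: bool


def _slices(len1: int, len2: int, offset: int) -> Tuple[int, int, int]:
    """(start in r1, start in C, common length) of the aligned region at offset."""
    s1 = max(offset, 0)
    e1 = min(len1, offset + len2)
    return s1, s1 - offset, max(0, e1 - s1)


def find_overlap(pair: ReadPair,
                 min_overlap: int = DEFAULT_MIN_OVERLAP,
                 max_ed_fraction: float = DEFAULT_MAX_ED_FRACTION) -> OverlapResult:
    """Exhaustive offset search minimising the edit distance of the aligned
    subsequences.

    Candidate offsets run over [-(len(r1) - min_overlap), len(r1) - min_overlap].
    Ties are broken toward larger overlap length, then smaller |offset|, then
    positive offset (the least destructive interpretation: no adapter cut on
    ties). The pair counts as overlapped when the overlap length reaches
    min_overlap and the edit distance is at most
    floor(max_ed_fraction * overlap_len).
    """
    r1, r2 = pair.r1.bases, pair.r2.bases
    if not r1 or not r2:
        raise ValueError("find_overlap requires non-empty reads")
    c = reverse_complement(r2)
    len1, len2 = len(r1), len(r2)
    span = len1 - min_overlap
    best: Optional[Tuple[int, int, int, int, int]] = None  # sort key
    best_offset = 0
    for offset in range(-span, span + 1):
        s1, sc, length = _slices(len1, len2, offset)
        if length <= 0:
            continue
        ed = edit_distance(r1[s1 : s1 + length], c[sc : sc + length])
        key = (ed, -length, abs(offset), 0 if offset >= 0 else 1)
        if best is None or key < best:
            best = key
            best_offset = offset
    if best is None:
        return OverlapResult(offset=0, overlap_len=0, edit_dist=0,
                             hamming_dist=None, mismatch_positions=(),
                             overlapped=False)
    offset = best_offset
    s1, sc, length = _slices(len1, len2, offset)
    a = r1[s1 : s1 + length]
    b = c[sc : sc + length]
    ed = best[0]
    mismatches: List[Tuple[int, str, int, str, int]] = []
    hamming = 0
    for i in range(length):
        if a[i] != b[i]:
            hamming += 1
            p1 = s1 + i
            p2 = len2 - 1 - (sc + i)  # position of this base in raw R2
            mismatches.append((p1, r1[p1], ord(pair.r1.quals[p1]) - PHRED_OFFSET,
                               r2[p2], ord(pair.r2.quals[p2]) - PHRED_OFFSET))
    overlapped = (length >= min_overlap
                  and ed <= max(0, math.floor(max_ed_fraction * length)))
    return OverlapResult(offset=offset, overlap_len=length, edit_dist=ed,
                         hamming_dist=hamming,
                         mismatch_positions=tuple(mismatches),
                         overlapped=overlapped)


def cut_adapters(pair: ReadPair, result: OverlapResult) -> ReadPair:
    """Cut adapter bases beyond the template from the 3' end of both mates.

    A negative offset means the template length is offset + len(r2) (= offset
    + len(r1) for equal-length mates): both mates keep their template-length
    prefix; everything past it is read-through into the adapter.
    """
    if not result.overlapped or result.offset >= 0:
        raise ValueError("cut_adapters requires an overlapped pair with negative offset")
    template_len = result.offset + len(pair.r2.bases)
    r1 = replace(pair.r1, bases=pair.r1.bases[:template_len],
                 quals=pair.r1.quals[:template_len])
    r2 = replace(pair.r2, bases=pair.r2.bases[:template_len],
                 quals=pair.r2.quals[:template_len])
    return ReadPair(r1=r1, r2=r2)


def correct_pair(pair: ReadPair, result: OverlapResult,
                 high_q: int = DEFAULT_HIGH_Q,
                 low_q: int = DEFAULT_LOW_Q
                 ) -> Tuple[ReadPair, int, bool]:
    """Correct quality-asymmetric mismatches in the overlap.

    Correction is gated on the overlapped slices differing only by
    substitutions (Hamming distance == edit distance); indel-bearing overlaps
    are uncorrectable and the pair is returned unchanged. A mismatch where
    one base has quality >= high_q and the other < low_q is fixed by copying
    the high-quality base (reverse-complement aware) and its quality onto the
    low-quality mate. Returns (pair, number corrected, uncorrectable flag);
    uncorrectable is True when any mismatch remains unfixed.
    """
    if not result.overlapped:
        raise ValueError("correct_pair requires an overlapped pair")
    if result.edit_dist == 0:
        raise ValueError("correct_pair requires edit_dist > 0")
    if result.hamming_dist is None or result.hamming_dist != result.edit_dist:
        return pair, 0, True

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    b1 = list(pair.r1.bases)
    q1 = list(pair.r1.quals)
    b2 = list(pair.r2.bases)
    q2 = list(pair.r2.quals)
    len2 = len(b2)
    corrected = 0
    remaining = 0
    for p1, base1, qual1, base2, qual2 in result.mismatch_positions:
        p2 = len2 - 1 - (p1 - result.offset)
        if qual1 >= high_q and qual2 < low_q:
            b2[p2] = comp[base1]
            q2[p2] = pair.r1.quals[p1]
            corrected += 1
        elif qual2 >= high_q and qual1 < low_q:
            b1[p1] = comp[base2]
            q1[p1] = pair.r2.quals[p2]
            corrected += 1
        else:
            remaining += 1
    new_pair = ReadPair(
        r1=replace(pair.r1, bases="".join(b1), quals="".join(q1)),
        r2=replace(pair.r2, bases="".join(b2), quals="".join(q2)),
    )
    return new_pair, corrected, remaining > 0


@dataclass
class ErrorStats:
    """Sequencing-error profile accumulated over long overlaps.

    mismatch/total over all counted overlap regions estimates the per-base
    sequencing error rate; transform_counts attribute each quality-asymmetric
    mismatch to one of the 12 true->observed substitution categories (bases
    in R1 orientation); balanced-quality mismatches cannot be attributed and
    are tallied as unprofiled.
    """

    total_overlapped_bases: int = 0
    mismatched_bases: int = 0
    transform_counts: Dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in TRANSFORMS})
    unprofiled_mismatches: int = 0

    @property
    def error_rate(self) -> float:
        if self.total_overlapped_bases == 0:
            return 0.0
        return self.mismatched_bases / self.total_overlapped_bases

    def to_dict(self) -> dict:
        return {
            "total": self.total_overlapped_bases,
            "mismatched": self.mismatched_bases,
            "rate": self.error_rate,
            "transforms": dict(self.transform_counts),
            "unprofiled": self.unprofiled_mismatches,
        }


def accumulate_error_stats(result: OverlapResult, stats: ErrorStats,
                           min_profile_overlap: int = DEFAULT_MIN_PROFILE_OVERLAP,
                           high_q: int = DEFAULT_HIGH_Q,
                           low_q: int = DEFAULT_LOW_Q) -> ErrorStats:
    """Add one pair's overlap to the error profile.

    Only substitution-only overlaps longer than min_profile_overlap are
    counted (short overlaps admit spurious minimum-edit-distance alignments).
    The low-quality base of an asymmetric mismatch is taken as the sequencing
    error; both bases are expressed in R1 orientation for the transform key.
    """
    if not result.overlapped:
        raise ValueError("accumulate_error_stats requires an overlapped pair")
    if result.overlap_len <= min_profile_overlap:
        raise ValueError(
            f"overlap_len {result.overlap_len} <= min_profile_overlap {min_profile_overlap}")
    if result.hamming_dist is None:
        raise ValueError("accumulate_error_stats requires a Hamming distance")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    stats.total_overlapped_bases += result.overlap_len
    stats.mismatched_bases += result.hamming_dist
    for _p1, base1, qual1, base2, qual2 in result.mismatch_positions:
        base2_r1 = comp[base2]  # R2's base expressed in R1 orientation
        if qual1 >= high_q and qual2 < low_q:
            true_b, obs_b = base1, base2_r1
        elif qual2 >= high_q and qual1 < low_q:
            true_b, obs_b = base2_r1, base1
        else:
            stats.unprofiled_mismatches += 1
            continue
        key = f"{true_b}->{obs_b}"
        if key in stats.transform_counts:
            stats.transform_counts[key] += 1
        else:  # N-containing mismatch: attributable to no category
            stats.unprofiled_mismatches += 1
    return stats


def merge_overlap(pair: ReadPair, result: OverlapResult) -> SequenceRead:
    """Collapse a (corrected) pair to its double-sequenced overlap region.

    The merged read is the overlap in R1 orientation; each position takes the
    higher-quality mate's base (after correction the mates agree except at
    uncorrectable positions, where R1's base is kept) and the max of the two
    qualities. This converts paired-end data into high-quality single-end
    data, since every retained base was sequenced twice.
    """
    if not result.overlapped:
        raise ValueError("merge_overlap requires an overlapped pair")
    r1, r2 = pair.r1, pair.r2
    c_bases = reverse_complement(r2.bases)
    c_quals = r2.quals[::-1]
    s1, sc, length = _slices(len(r1.bases), len(r2.bases), result.offset)
    bases = []
    quals = []
    for i in range(length):
        base1, qual1 = r1.bases[s1 + i], r1.quals[s1 + i]
        base2, qual2 = c_bases[sc + i], c_quals[sc + i]
        if base1 == base2:
            bases.append(base1)
        else:
            bases.append(base1)  # uncorrectable disagreement: keep R1's call
        quals.append(max(qual1, qual2))
    return SequenceRead(name=f"{r1.name} merged",
                        bases="".join(bases), quals="".join(quals))
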