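"""Per-cycle QC profiles, discontinuity curves and k-mer strand-bias counts.

Three diagnostics are computed here:

* the classic per-cycle base content / mean quality profile (``CycleProfile``),
  which also drives the global trimming decision;
* per-cycle *discontinuity* — the mean number of adjacent differing bases in a
  short window of cycles. A healthy run has a flat discontinuity curve; a
  cycle-by-cycle drop points at per-cycle chemistry problems (e.g. washing);
* k-mer strand-bias counts: with unbiased amplification and sequencing, a
  k-mer and its reverse complement should occur about equally often, so the
  (forward, reverse-complement) count table diagnoses strand bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .fastq_io import PHRED_OFFSET, SequenceRead

BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CycleProfile:
    """Per-cycle base counts, total coverage and mean quality.

    ``counts`` has shape (n_cycles, 5) ordered A,C,G,T,N; ``totals[c]`` is the
    number of reads covering cycle c; ``mean_qual[c]`` is the arithmetic mean
    Phred score at cycle c.
    """

    n_cycles: int
    counts: np.ndarray  # (n_cycles, 5) int64
    totals: np.ndarray  # (n_cycles,) int64
    qual_sums: np.ndarray  # (n_cycles,) int64

    @property
    def mean_qual(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.totals > 0, self.qual_sums / np.maximum(self.totals, 1), 0.0)

    def base_fraction(self, cycle: int, base: str) -> float:
        """Content fraction of one base at a cycle (denominator: all bases incl. N)."""
        total = self.totals[cycle]
        if total == 0:
            return 0.0
        return self.counts[cycle, _BASE_INDEX[base]] / total

    def gc_fraction(self, cycle: int) -> float:
        """GC fraction at a cycle; N is excluded from the denominator."""
        a, c, g, t, _ = self.counts[cycle]
        acgt = a + c + g + t
        if acgt == 0:
            return 0.0
        return (g + c) / acgt

    def to_dict(self) -> dict:
        return {
            "n_cycles": int(self.n_cycles),
            "counts": {b: self.counts[:, i].tolist() for i, b in enumerate(BASES)},
            "totals": self.totals.tolist(),
            "mean_qual": [round(float(q), 4) for q in self.mean_qual],
        }


def profile_cycles(reads: Iterable[SequenceRead]) -> CycleProfile:
    """Count every base and quality of every read at its 0-based cycle."""
    counts: List[np.ndarray] = []
    totals: List[int] = []
    qual_sums: List[int] = []

    def _grow(n: int) -> None:
        while len(totals) < n:
            counts.append(np.zeros(5, dtype=np.int64))
            totals.append(0)
            qual_sums.append(0)

    n_grown = 0
    for read in reads:
        L = len(read.bases)
        if L > n_grown:
            _grow(L)
            n_grown = L
        for c, (b, q) in enumerate(zip(read.bases, read.quals)):
            counts[c][_BASE_INDEX[b]] += 1
            totals[c] += 1
            qual_sums[c] += ord(q) - PHRED_OFFSET
    n = len(totals)
    return CycleProfile(
        n_cycles=n,
        counts=np.array(counts, dtype=np.int64).reshape(n, 5),
        totals=np.array(totals, dtype=np.int64),
        qual_sums=np.array(qual_sums, dtype=np.int64),
    )


def discontinued_count(seq: str) -> int:
    """Number of adjacent positions where the base changes.

    "ATCGA" -> 4 (every neighbour differs); "AAAAA" -> 0. Empty or length-1
    sequences have no adjacent pairs, hence 0.
    """
    return sum(1 for i in range(len(seq) - 1) if seq[i] != seq[i + 1])


def discontinuity_curve(reads: Sequence[SequenceRead], window: int = 5) -> List[float]:
    """Mean discontinued-base count per window of cycles.

    Entry w is the mean over reads of discontinued_count(bases[w : w+window]);
    reads shorter than w+window are skipped for that window.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    max_len = max((len(r.bases) for r in reads), default=0)
    n_windows = max(0, max_len - window + 1)
    sums = [0] * n_windows
    ns = [0] * n_windows
    for read in reads:
        seq = read.bases
        for w in range(0, len(seq) - window + 1):
            sums[w] += discontinued_count(seq[w : w + window])
            ns[w] += 1
    return [s / n if n else 0.0 for s, n in zip(sums, ns)]


@dataclass
class StrandBiasTable:
    """Forward / reverse-complement occurrence counts per canonical k-mer.

    The canonical form of a k-mer is the lexicographically smaller of itself
    and its reverse complement; a window whose canonical form is itself counts
    as forward, otherwise as reverse. k must be even so no k-mer is its own
    reverse complement.
    """

    k: int
    entries: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def total(self) -> int:
        return sum(f + r for f, r in self.entries.values())

    def to_list(self) -> list:
        return [[kmer, f, r] for kmer, (f, r) in sorted(self.entries.items())]


def kmer_strand_counts(reads: Iterable[SequenceRead], k: int = 8,
                       max_reads: int = 100_000) -> StrandBiasTable:
    """Slide a width-k window over the first max_reads reads; k-mers containing
    N are excluded. k must be even (odd k admits palindromic k-mers that are
    their own reverse complement, making the forward/reverse split ambiguous)."""
    if k < 2 or k % 2 != 0:
        raise ValueError(f"k must be even and >= 2, got {k}")
    if max_reads <= 0:
        raise ValueError("max_reads must be positive")
    entries: Dict[str, List[int]] = {}
    for i, read in enumerate(reads):
        if i >= max_reads:
            break
        seq = read.bases
        for j in range(len(seq) - k + 1):
            kmer = seq[j : j + k]
            if "N" in kmer:
                continue
            rc = reverse_complement(kmer)
            if kmer <= rc:
                canon, slot = kmer, 0
            else:
                canon, slot = rc, 1
            counts = entries.setdefault(canon, [0, 0])
            counts[slot] += 1
    return StrandBiasTable(k=k, entries={km: (c[0], c[1]) for km, c in entries.items()})


def bias_summary(table: StrandBiasTable) -> float:
    """Count-weighted mean of |forward - reverse| / (forward + reverse).

    0 means perfect strand balance; 1 means every k-mer was seen on one
    strand only.
    """
    if not table.entries:
        raise ValueError("strand-bias table is empty")
    num = 0.0
    den = 0
    for f, r in table.entries.values():
        n = f + r
        if n == 0:
            continue
        num += abs(f - r)
        den += n
    if den == 0:
        raise ValueError("strand-bias table has no counts")
    return num / den
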