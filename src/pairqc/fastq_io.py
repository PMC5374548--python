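"""FASTQ input/output and batch-folder plumbing.

Reads and writes 4-line FASTQ records (plain or gzip, chosen by the ``.gz``
suffix), discovers R1/R2 file pairs in a folder, and parses Illumina-style
colon-delimited read names into flowcell coordinates (lane, tile, x, y) used
by the spatial bubble detector.

Quality encoding is fixed to Phred+33. Phred+64 input is rejected rather than
auto-detected: any quality character below ``'!'`` is impossible in Phred+33
and raises.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

PHRED_OFFSET = 33
MAX_PHRED = 60

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRead:
    """One FASTQ record: full header (without '@'), bases over {A,C,G,T,N},
    and a Phred+33 quality string of the same length."""

    name: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.name!r}: bases ({len(self.bases)}) and qualities "
                f"({len(self.quals)}) differ in length"
            )

    def phred(self) -> list[int]:
        """Decoded per-base Phred scores."""
        return [ord(c) - PHRED_OFFSET for c in self.quals]

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadPair:
    """A pair of mates R1/R2; lengths may differ after trimming."""

    r1: SequenceRead
    r2: SequenceRead


@dataclass(frozen=True)
class FlowcellCoord:
    lane: int
    tile: int
    x: int
    y: int


def _open(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream records from a plain or gzip FASTQ file.

    Yields records in file order with constant memory. A malformed record
    (missing '+' separator, truncated record, length mismatch, invalid base,
    quality character outside the Phred+33 [0, 60] range) raises ValueError
    naming the 0-based record index.
    """
    with _open(path, "r") as fh:
        index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"record {index}: header does not start with '@'")
            bases = fh.readline().rstrip("\n")
            plus = fh.readline()
            quals = fh.readline().rstrip("\n")
            if not plus or not quals:
                raise ValueError(f"record {index}: truncated record")
            if not plus.startswith("+"):
                raise ValueError(f"record {index}: missing '+' separator line")
            if len(bases) != len(quals):
                raise ValueError(
                    f"record {index}: sequence length {len(bases)} != "
                    f"quality length {len(quals)}"
                )
            bad = set(bases) - _VALID_BASES
            if bad:
                raise ValueError(f"record {index}: invalid base(s) {sorted(bad)}")
            for c in quals:
                q = ord(c) - PHRED_OFFSET
                if q < 0:
                    raise ValueError(
                        f"record {index}: quality char {c!r} below '!' "
                        "(Phred+64 input is not supported)"
                    )
                if q > MAX_PHRED:
                    raise ValueError(
                        f"record {index}: quality {q} above {MAX_PHRED}"
                    )
            yield SequenceRead(name=header[1:], bases=bases, quals=quals)
            index += 1


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    """Write records as 4-line FASTQ (gzip if path ends in .gz); returns count."""
    n = 0
    with _open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.bases}\n+\n{read.quals}\n")
            n += 1
    return n


# R1/R2 tokens accepted when pairing files: "R1"/"R2" anywhere, or "_1"/"_2"
# immediately before the FASTQ extension.
_FASTQ_EXT = re.compile(r"\.(fastq|fq)(\.gz)?$")
_R1_TOKENS = [(re.compile(r"R1"), "R2"), (re.compile(r"_1(?=\.(?:fastq|fq)(?:\.gz)?$)"), "_2")]


def pair_files(folder: str | Path) -> list[tuple[Path, Optional[Path]]]:
    """Discover FASTQ files in a folder and match them into R1/R2 pairs.

    Two files pair when their names differ only by an R1/R2 token ("R1"/"R2",
    or "_1"/"_2" before the extension). Unmatched files are returned as
    single-end units. The result is a partition of the folder's FASTQ files,
    in lexicographic order of the R1 (or only) file.
    """
    folder = Path(folder)
    files = sorted(p for p in folder.iterdir() if p.is_file() and _FASTQ_EXT.search(p.name))
    names = {p.name: p for p in files}
    used: set[str] = set()
    units: list[tuple[Path, Optional[Path]]] = []
    for p in files:
        if p.name in used:
            continue
        mate: Optional[Path] = None
        for token_re, repl in _R1_TOKENS:
            m = token_re.search(p.name)
            if m is None:
                continue
            candidate = p.name[: m.start()] + repl + p.name[m.end():]
            if candidate in names and candidate not in used and candidate != p.name:
                mate = names[candidate]
                break
        if mate is not None:
            used.add(p.name)
            used.add(mate.name)
            units.append((p, mate))
        else:
            # mate files (R2/_2) wait for their R1 partner; everything else is
            # single-end. A lone R2 with no R1 partner falls through as single-end.
            is_r2 = False
            for token_re, repl in [(re.compile("R2"), "R1"),
                                   (re.compile(r"_2(?=\.(?:fastq|fq)(?:\.gz)?$)"), "_1")]:
                m = token_re.search(p.name)
                if m is not None:
                    candidate = p.name[: m.start()] + repl + p.name[m.end():]
                    if candidate in names:
                        is_r2 = True
                        break
            if not is_r2:
                used.add(p.name)
                units.append((p, None))
    # lone R2 files (partner never claimed them — cannot happen with the
    # symmetric rule above, but keep the partition property airtight)
    for p in files:
        if p.name not in used:
            used.add(p.name)
            units.append((p, None))
    units.sort(key=lambda u: u[0].name)
    return units


def parse_coord(name: str) -> Optional[FlowcellCoord]:
    """Parse lane/tile/x/y from an Illumina colon-delimited read name.

    Dialect: ``instrument:run:flowcell:lane:tile:x:y[ ...]``; fields 4-7 must
    be non-negative integers (lane and tile >= 1). Returns None (not an error)
    for names that do not match.
    """
    head = name.split()[0] if name.strip() else ""
    fields = head.split(":")
    if len(fields) < 7:
        return None
    try:
        lane, tile, x, y = (int(fields[i]) for i in (3, 4, 5, 6))
    except ValueError:
        return None
    if lane < 1 or tile < 1 or x < 0 or y < 0:
        return None
    return FlowcellCoord(lane=lane, tile=tile, x=x, y=y)


def format_coord(coord: FlowcellCoord, instrument: str = "SIM",
                 run: int = 1, flowcell: str = "FC") -> str:
    """Render a coordinate as an Illumina-style read name (parse_coord inverse)."""
    return f"{instrument}:{run}:{flowcell}:{coord.lane}:{coord.tile}:{coord.x}:{coord.y}"


def count_records(path: str | Path) -> int:
    n = 0
    for _ in read_fastq(path):
        n += 1
    return n


def with_name(read: SequenceRead, name: str) -> SequenceRead:
    return replace(read, name=name)
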