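"""Synthetic paired-end FASTQ generator with full ground truth.

Every pair is drawn from a random DNA template of length T read from both
ends at read length S, reproducing the three overlap regimes: full overlap
(T <= S, read-through into adapter), partial overlap of 2S - T bases
(S < T < 2S) and no overlap (2S <= T). Substitution errors are planted per
base at a configurable rate and written at a distinct (low) quality so the
quality-asymmetry correction rule is exactly testable; setting error_qual =
base_qual instead produces balanced-quality (uncorrectable) errors. Optional
extras plant whole-read polyG artifacts, single-base insertions (to exercise
the indel-discard path) and flowcell-bubble polyG clouds with known circle
geometry.

Template lengths default to normal(167, 20): cell-free DNA fragments centre
around 167 bp, which is the regime where overlap analysis is most useful.
Ground truth (templates, planted errors, adapter boundaries, coordinates,
bubble circles) is returned alongside the reads so every downstream module
can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .fastq_io import PHRED_OFFSET, FlowcellCoord, SequenceRead, format_coord
from .qc_profiler import reverse_complement

# Illumina TruSeq universal adapter prefix — read-through adapter content
DEFAULT_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
DEFAULT_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class BubbleSpec:
    """Planted bubble: polyG reads uniform in a disc plus uniform background."""

    lane: int = 1
    tile: int = 1101
    cx: float = 1000.0
    cy: float = 1000.0
    r: float = 300.0
    n_rim_reads: int = 200
    background_mean: float = 100.0  # Poisson mean of tile-wide polyG noise
    tile_width: float = 2000.0
    read_len: int = 50


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_pairs: int = 1000
    read_len: int = 100
    template_len: Union[int, Tuple[float, float], Sequence[int]] = (167.0, 20.0)
    adapter_r1: str = DEFAULT_ADAPTER_R1
    adapter_r2: str = DEFAULT_ADAPTER_R2
    error_rate: float = 0.001
    error_on: str = "both"  # "both", "r1" or "r2"
    error_qual: int = 8
    base_qual: int = 36
    polyx_fraction: float = 0.0
    indel_fraction: float = 0.0
    tile: int = 1101
    lane: int = 1
    tile_width: float = 2000.0

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 1):
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.read_len < 20:
            raise ValueError(f"read_len must be >= 20, got {self.read_len}")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.error_on not in ("both", "r1", "r2"):
            raise ValueError(f"error_on must be both/r1/r2, got {self.error_on!r}")


def expected_mismatch_fraction(error_rate: float, error_on: str = "both") -> float:
    """Expected positional-mismatch fraction over overlapped bases.

    With errors on one mate only the fraction is the planted rate e. With
    errors on both mates each base errs independently per mate and a mismatch
    shows unless both err to the same base (probability 1/3 given both err):
    2e(1-e) + (2/3)e^2.
    """
    e = error_rate
    if error_on in ("r1", "r2"):
        return e
    return 2 * e * (1 - e) + (2.0 / 3.0) * e * e


def _draw_template_lengths(config: SimulationConfig, rng: np.random.Generator
                           ) -> np.ndarray:
    spec = config.template_len
    if isinstance(spec, int):
        return np.full(config.n_pairs, spec, dtype=int)
    if (isinstance(spec, tuple) and len(spec) == 2
            and all(isinstance(v, (int, float)) for v in spec)):
        mean, sd = spec
        draws = rng.normal(mean, sd, size=config.n_pairs)
        return np.clip(np.round(draws), 20, None).astype(int)
    lengths = np.asarray(list(spec), dtype=int)
    if len(lengths) != config.n_pairs:
        raise ValueError("template length list must have n_pairs entries")
    return lengths


def _fill_to_length(insert: str, adapter: str, length: int,
                    rng: np.random.Generator) -> str:
    """Extend a short insert with adapter then random bases up to read length."""
    out = insert + adapter
    if len(out) < length:
        out += "".join(rng.choice(_BASES, size=length - len(out)))
    return out[:length]


def simulate_pairs(config: SimulationConfig
                   ) -> Tuple[List[SequenceRead], List[SequenceRead], dict]:
    """Generate R1/R2 records plus a ground-truth record.

    Ground truth per pair: template, template length T, true offset T - S,
    adapter read-through lengths, planted errors as (mate, position,
    true_base, observed_base), flowcell coordinate, polyX/indel flags.
    Deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    S = config.read_len
    lengths = _draw_template_lengths(config, rng)
    r1_records: List[SequenceRead] = []
    r2_records: List[SequenceRead] = []
    truth_pairs: List[dict] = []
    base_q_char = chr(config.base_qual + PHRED_OFFSET)
    err_q_char = chr(config.error_qual + PHRED_OFFSET)

    for i in range(config.n_pairs):
        T = int(lengths[i])
        template = "".join(rng.choice(_BASES, size=T))
        x = int(rng.integers(0, int(config.tile_width)))
        y = int(rng.integers(0, int(config.tile_width)))
        name = format_coord(FlowcellCoord(config.lane, config.tile, x, y),
                            instrument="SIM", run=i)

        is_polyx = bool(rng.random() < config.polyx_fraction)
        if is_polyx:
            r1_b = "G" * S
            r2_b = "G" * S
            adapter1_len = adapter2_len = 0
            errors: List[Tuple[str, int, str, str]] = []
            has_indel = False
        else:
            r1_b = _fill_to_length(template[:S] if T >= S else template,
                                   config.adapter_r1 if T < S else "", S, rng)
            rc = reverse_complement(template)
            r2_b = _fill_to_length(rc[:S] if T >= S else rc,
                                   config.adapter_r2 if T < S else "", S, rng)
            adapter1_len = adapter2_len = max(0, S - T)

            errors = []
            r1_list = list(r1_b)
            r2_list = list(r2_b)
            for mate, blist in (("r1", r1_list), ("r2", r2_list)):
                if config.error_on != "both" and mate != config.error_on:
                    continue
                err_mask = rng.random(S) < config.error_rate
                for pos in np.flatnonzero(err_mask):
                    true_b = blist[pos]
                    choices = [b for b in "ACGT" if b != true_b]
                    obs = choices[int(rng.integers(0, 3))]
                    blist[pos] = obs
                    errors.append((mate, int(pos), true_b, obs))
            has_indel = bool(rng.random() < config.indel_fraction)
            if has_indel:
                # one random inserted base mid-read in R2, length preserved
                pos = int(rng.integers(5, S - 5))
                ins = str(rng.choice(_BASES))
                r2_list = r2_list[:pos] + [ins] + r2_list[pos:-1]
            r1_b = "".join(r1_list)
            r2_b = "".join(r2_list)

        def _quals(mate: str, length: int) -> str:
            q = [base_q_char] * length
            for m, pos, _t, _o in errors:
                if m == mate and pos < length:
                    q[pos] = err_q_char
            return "".join(q)

        r1_records.append(SequenceRead(name=name, bases=r1_b, quals=_quals("r1", S)))
        r2_records.append(SequenceRead(name=name, bases=r2_b, quals=_quals("r2", S)))
        truth_pairs.append({
            "template": template,
            "T": T,
            "true_offset": T - S,
            "adapter1_len": adapter1_len,
            "adapter2_len": adapter2_len,
            "errors": errors,
            "coord": (config.lane, config.tile, x, y),
            "polyx": is_polyx,
            "indel": has_indel,
        })

    truth = {
        "config": {"seed": config.seed, "n_pairs": config.n_pairs,
                   "read_len": S, "error_rate": config.error_rate},
        "expected_mismatch_fraction": expected_mismatch_fraction(
            config.error_rate, config.error_on),
        "pairs": truth_pairs,
    }
    return r1_records, r2_records, truth


def plant_polyx_bubble(records: Sequence[SequenceRead],
                       spec: BubbleSpec = BubbleSpec(),
                       seed: int = 0) -> Tuple[List[SequenceRead], dict]:
    """Append polyG reads forming a bubble cloud plus uniform background.

    n_rim_reads polyG reads get coordinates uniform in the disc of radius r
    around (cx, cy); Poisson(background_mean) additional polyG reads land
    uniformly on the tile. Returns (records + planted reads, ground truth
    with the circle and every planted coordinate).
    """
    rng = np.random.default_rng(seed)
    out = list(records)
    qual = chr(36 + PHRED_OFFSET)
    planted_bubble: List[Tuple[int, int]] = []
    planted_background: List[Tuple[int, int]] = []

    def _add(x: float, y: float, bucket: List[Tuple[int, int]]) -> None:
        xi = int(np.clip(round(x), 0, spec.tile_width - 1))
        yi = int(np.clip(round(y), 0, spec.tile_width - 1))
        name = format_coord(FlowcellCoord(spec.lane, spec.tile, xi, yi),
                            instrument="BUB", run=len(out))
        out.append(SequenceRead(name=name, bases="G" * spec.read_len,
                                quals=qual * spec.read_len))
        bucket.append((xi, yi))

    for _ in range(spec.n_rim_reads):
        radius = spec.r * np.sqrt(rng.random())
        theta = rng.random() * 2 * np.pi
        _add(spec.cx + radius * np.cos(theta), spec.cy + radius * np.sin(theta),
             planted_bubble)
    n_bg = int(rng.poisson(spec.background_mean))
    for _ in range(n_bg):
        _add(rng.random() * spec.tile_width, rng.random() * spec.tile_width,
             planted_background)

    truth = {
        "circle": {"lane": spec.lane, "tile": spec.tile, "cx": spec.cx,
                   "cy": spec.cy, "r": spec.r},
        "bubble_coords": planted_bubble,
        "background_coords": planted_background,
    }
    return out, truth
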