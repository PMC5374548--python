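"""Pipeline orchestration: per-file/pair QC runs and batch folders.

Stage order per unit (single FASTQ file or R1/R2 pair):

1. optional bubble detection (a first pass collects polyX read coordinates,
   then circles are fitted per lane/tile);
2. pre-filtering QC (per-cycle profiles, discontinuity, k-mer strand bias);
3. global trimming decided from the pre-filtering profile;
4. per-read filtering (quality, N-count, polyX, bubble) — for pairs, if
   either mate fails, both go to the bad stream so pairing is preserved;
5. overlap analysis for pairs: adapter cutting at negative offsets,
   quality-asymmetric base correction, sequencing-error profiling, optional
   merging of the overlap region into single-end output;
6. good reads written, post-filtering QC on the good reads, JSON+HTML report.

Batch mode discovers units in a folder and processes them independently;
results are byte-identical for any worker count.
"""

from __future__ import annotations

import json
import logging
import sys
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import filters as flt
from . import overlap as ovl
from .bubble import BubbleCircle, BubbleParams, PolyXHit, detect_bubbles
from .fastq_io import (ReadPair, SequenceRead, pair_files, parse_coord,
                       read_fastq, write_fastq)
from .filters import FilterVerdict, PolyXParams, annotate_bad
from .qc_profiler import (CycleProfile, bias_summary, discontinuity_curve,
                          kmer_strand_counts, profile_cycles)
from .trimmer import TrimDecision, apply_trim, compute_trim

logger = logging.getLogger("pairqc")

BAD_REASONS = ("quality", "n_count", "polyX", "bubble",
               "too_short_after_trim", "overlap_indel")


@dataclass(frozen=True)
class PipelineOptions:
    out_dir: Path = Path("pairqc_out")
    # trimming
    no_trim: bool = False
    trim_front: Optional[int] = None  # override automatic decision
    trim_tail: Optional[int] = None
    trim_front_max_percent: float = 10.0
    trim_tail_max_percent: float = 5.0
    # filters
    poly_size: int = 35
    poly_tolerance: int = 2
    max_n: int = 5
    min_mean_qual: float = 20.0
    low_qual: int = 15
    max_low_qual: Optional[int] = None
    # overlap
    min_overlap: int = 30
    max_mismatch_fraction: float = 0.05
    no_correction: bool = False
    store_overlap_only: bool = False
    require_overlap: bool = False
    qual_high: int = 30
    qual_low: int = 15
    profile_min_overlap: int = 50
    # bubble
    debubble: bool = False
    bubble_params: BubbleParams = field(default_factory=BubbleParams)
    # report
    kmer_k: int = 8
    kmer_max_reads: int = 100_000
    discontinuity_window: int = 5
    write_html: bool = True


@dataclass
class RunSummary:
    """Machine-readable result of one pipeline unit (JSON-stable schema)."""

    inputs: List[str]
    mode: str  # "pe" or "se"
    counts: Dict[str, int]
    bad_by_reason: Dict[str, int]
    trim: Dict[str, List[int]]
    overlap: Dict[str, int]
    error_stats: dict
    pre_profile: dict
    post_profile: dict
    strand_bias: list
    strand_bias_summary: Optional[float]
    discontinuity: List[float]
    bubble_circles: list
    error: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunSummary":
        return cls(**d)


def _failure_reason(reads: Sequence[SequenceRead],
                    coords: Sequence[Optional[object]],
                    circles: Sequence[BubbleCircle],
                    opts: PipelineOptions,
                    polyx_params: PolyXParams) -> str:
    """First failing filter reason across mates, in the fixed reporting order
    quality -> n_count -> polyX -> bubble; empty string when all pass."""
    verdicts: List[str] = []
    for read, coord in zip(reads, coords):
        v = flt.quality_filter(read, low_qual_threshold=opts.low_qual,
                               max_low_qual=opts.max_low_qual,
                               max_n=opts.max_n,
                               min_mean_qual=opts.min_mean_qual)
        if not v.passed:
            verdicts.append(v.reason)
        found, _, _ = flt.detect_polyx(read.bases, polyx_params)
        if found:
            verdicts.append("polyX")
        if circles:
            v = flt.bubble_filter(coord, circles)
            if not v.passed:
                verdicts.append(v.reason)
    for reason in ("quality", "n_count", "polyX", "bubble"):
        if reason in verdicts:
            return reason
    return ""


def _collect_polyx_hits(paths: Sequence[Path], polyx_params: PolyXParams
                        ) -> List[PolyXHit]:
    hits: List[PolyXHit] = []
    for path in paths:
        for read in read_fastq(path):
            found, base, _ = flt.detect_polyx(read.bases, polyx_params)
            if not found:
                continue
            coord = parse_coord(read.name)
            if coord is not None:
                hits.append(PolyXHit(coord=coord, base=base))
    return hits


def _profile_dict(reads: Sequence[SequenceRead]) -> dict:
    return profile_cycles(reads).to_dict()


def run_pipeline(r1_path: str | Path, r2_path: Optional[str | Path],
                 options: PipelineOptions = PipelineOptions()) -> RunSummary:
    """Run the full QC/filtering pipeline on one file or pair."""
    r1_path = Path(r1_path)
    r2_path = Path(r2_path) if r2_path is not None else None
    paired = r2_path is not None
    opts = options
    out_dir = Path(opts.out_dir)
    (out_dir / "good").mkdir(parents=True, exist_ok=True)
    (out_dir / "bad").mkdir(parents=True, exist_ok=True)
    if opts.store_overlap_only:
        (out_dir / "merged").mkdir(parents=True, exist_ok=True)

    polyx_params = PolyXParams(P=opts.poly_size, L=opts.poly_tolerance)

    # stage 1: bubble detection (separate first pass over the raw input)
    circles: List[BubbleCircle] = []
    if opts.debubble:
        paths = [r1_path] + ([r2_path] if paired else [])
        hits = _collect_polyx_hits(paths, polyx_params)
        circles = detect_bubbles(hits, opts.bubble_params)
        logger.info("stage=debubble unit=%s hits=%d circles=%d",
                    r1_path.name, len(hits), len(circles))

    r1_reads = list(read_fastq(r1_path))
    r2_reads = list(read_fastq(r2_path)) if paired else []
    if paired and len(r1_reads) != len(r2_reads):
        raise ValueError(
            f"record count mismatch: {r1_path.name} has {len(r1_reads)} reads, "
            f"{r2_path.name} has {len(r2_reads)}")

    # stage 2: pre-filtering QC
    pre_r1 = profile_cycles(r1_reads)
    pre_r2 = profile_cycles(r2_reads) if paired else None
    strand_table = kmer_strand_counts(r1_reads, k=opts.kmer_k,
                                      max_reads=opts.kmer_max_reads)
    disc = discontinuity_curve(r1_reads, window=opts.discontinuity_window)
    logger.info("stage=pre_qc unit=%s reads_in=%d", r1_path.name, len(r1_reads))

    # stage 3: global trim decision (per mate, from each mate's own profile)
    def _decide(profile: CycleProfile) -> TrimDecision:
        if opts.no_trim:
            return TrimDecision(front=0, tail=0)
        if opts.trim_front is not None or opts.trim_tail is not None:
            return TrimDecision(front=opts.trim_front or 0,
                                tail=opts.trim_tail or 0)
        return compute_trim(profile, opts.trim_front_max_percent,
                            opts.trim_tail_max_percent)

    trim_r1 = _decide(pre_r1)
    trim_r2 = _decide(pre_r2) if paired else None
    logger.info("stage=trim unit=%s r1=(%d,%d)%s", r1_path.name,
                trim_r1.front, trim_r1.tail,
                f" r2=({trim_r2.front},{trim_r2.tail})" if paired else "")

    # stages 4-5: per-unit filtering and overlap analysis
    good_r1: List[SequenceRead] = []
    good_r2: List[SequenceRead] = []
    bad_r1: List[SequenceRead] = []
    bad_r2: List[SequenceRead] = []
    merged: List[SequenceRead] = []
    bad_by_reason = {r: 0 for r in BAD_REASONS}
    n_overlapped = 0
    n_adapters_cut = 0
    n_corrected_bases = 0
    stats = ovl.ErrorStats()

    n_units = len(r1_reads)
    for i in range(n_units):
        reads = [r1_reads[i]] + ([r2_reads[i]] if paired else [])
        trimmed = [apply_trim(reads[0], trim_r1)]
        if paired:
            trimmed.append(apply_trim(reads[1], trim_r2))
        if any(t is None for t in trimmed):
            bad_by_reason["too_short_after_trim"] += 1
            bad_r1.append(annotate_bad(reads[0], "too_short_after_trim"))
            if paired:
                bad_r2.append(annotate_bad(reads[1], "too_short_after_trim"))
            continue
        coords = [parse_coord(r.name) for r in trimmed]
        reason = _failure_reason(trimmed, coords, circles, opts, polyx_params)
        if reason:
            bad_by_reason[reason] += 1
            bad_r1.append(annotate_bad(trimmed[0], reason))
            if paired:
                bad_r2.append(annotate_bad(trimmed[1], reason))
            continue

        if not paired:
            good_r1.append(trimmed[0])
            continue

        pair = ReadPair(r1=trimmed[0], r2=trimmed[1])
        result = ovl.find_overlap(pair, min_overlap=opts.min_overlap,
                                  max_ed_fraction=opts.max_mismatch_fraction)
        if result.overlapped and result.offset < 0:
            pair = ovl.cut_adapters(pair, result)
            n_adapters_cut += 1
            result = ovl.find_overlap(pair, min_overlap=min(opts.min_overlap,
                                                            len(pair.r1.bases)),
                                      max_ed_fraction=opts.max_mismatch_fraction)
        if result.overlapped:
            n_overlapped += 1
            if (result.hamming_dist is not None
                    and result.overlap_len > opts.profile_min_overlap):
                ovl.accumulate_error_stats(result, stats,
                                           min_profile_overlap=opts.profile_min_overlap,
                                           high_q=opts.qual_high,
                                           low_q=opts.qual_low)
            if result.edit_dist > 0:
                if (result.hamming_dist is None
                        or result.hamming_dist != result.edit_dist):
                    bad_by_reason["overlap_indel"] += 1
                    bad_r1.append(annotate_bad(pair.r1, "overlap_indel"))
                    bad_r2.append(annotate_bad(pair.r2, "overlap_indel"))
                    continue
                if not opts.no_correction:
                    pair, n_fixed, _uncorrectable = ovl.correct_pair(
                        pair, result, high_q=opts.qual_high, low_q=opts.qual_low)
                    n_corrected_bases += n_fixed
                    result = ovl.find_overlap(
                        pair, min_overlap=min(opts.min_overlap, len(pair.r1.bases)),
                        max_ed_fraction=opts.max_mismatch_fraction)
            if opts.store_overlap_only:
                merged.append(ovl.merge_overlap(pair, result))
                continue
        elif opts.require_overlap and opts.store_overlap_only:
            bad_by_reason.setdefault("no_overlap", 0)
            bad_by_reason["no_overlap"] += 1
            bad_r1.append(annotate_bad(pair.r1, "no_overlap"))
            bad_r2.append(annotate_bad(pair.r2, "no_overlap"))
            continue
        good_r1.append(pair.r1)
        good_r2.append(pair.r2)

    # stage 6: outputs and post-filtering QC
    write_fastq(good_r1, out_dir / "good" / r1_path.name.replace(".gz", ""))
    write_fastq(bad_r1, out_dir / "bad" / r1_path.name.replace(".gz", ""))
    if paired:
        write_fastq(good_r2, out_dir / "good" / r2_path.name.replace(".gz", ""))
        write_fastq(bad_r2, out_dir / "bad" / r2_path.name.replace(".gz", ""))
    if opts.store_overlap_only:
        merged_name = r1_path.name.replace(".gz", "").replace(".fastq", ".fq")
        write_fastq(merged, out_dir / "merged" / merged_name)

    post_reads = merged if opts.store_overlap_only else good_r1
    post_profile = {"r1": _profile_dict(post_reads)}
    if paired and not opts.store_overlap_only:
        post_profile["r2"] = _profile_dict(good_r2)
    pre_profile = {"r1": pre_r1.to_dict()}
    if paired:
        pre_profile["r2"] = pre_r2.to_dict()

    # in merged mode, non-overlapping pairs kept in good/ still count as good units
    n_good = (len(merged) + len(good_r1)) if opts.store_overlap_only else len(good_r1)
    summary = RunSummary(
        inputs=[r1_path.name] + ([r2_path.name] if paired else []),
        mode="pe" if paired else "se",
        counts={"total": n_units, "good": n_good,
                "bad": sum(bad_by_reason.values())},
        bad_by_reason=dict(bad_by_reason),
        trim={"r1": [trim_r1.front, trim_r1.tail],
              **({"r2": [trim_r2.front, trim_r2.tail]} if paired else {})},
        overlap=({"pairs_overlapped": n_overlapped,
                  "adapters_cut": n_adapters_cut,
                  "bases_corrected": n_corrected_bases,
                  "merged_reads": len(merged)} if paired else {}),
        error_stats=stats.to_dict() if paired else {},
        pre_profile=pre_profile,
        post_profile=post_profile,
        strand_bias=strand_table.to_list(),
        strand_bias_summary=(bias_summary(strand_table)
                             if strand_table.entries else None),
        discontinuity=disc,
        bubble_circles=[c.to_dict() for c in circles],
    )
    logger.info("stage=done unit=%s total=%d good=%d bad=%d",
                r1_path.name, n_units, summary.counts["good"],
                summary.counts["bad"])

    from .report import render_report
    render_report(summary, out_dir, write_html=opts.write_html)
    return summary


def _run_unit(args: Tuple[str, Optional[str], PipelineOptions]) -> dict:
    r1, r2, opts = args
    unit_dir = Path(opts.out_dir) / Path(r1).name.split(".")[0]
    unit_opts = replace(opts, out_dir=unit_dir)
    try:
        return run_pipeline(r1, r2, unit_opts).to_dict()
    except Exception as exc:  # per-unit failure must not kill the batch
        return RunSummary(
            inputs=[Path(r1).name] + ([Path(r2).name] if r2 else []),
            mode="pe" if r2 else "se", counts={"total": 0, "good": 0, "bad": 0},
            bad_by_reason={}, trim={}, overlap={}, error_stats={},
            pre_profile={}, post_profile={}, strand_bias=[],
            strand_bias_summary=None, discontinuity=[], bubble_circles=[],
            error=str(exc)).to_dict()


def run_batch(folder: str | Path, options: PipelineOptions = PipelineOptions(),
              workers: int = 1) -> List[RunSummary]:
    """Process every FASTQ unit in a folder; each unit writes to its own
    subfolder of options.out_dir. Summaries come back in discovery order and
    outputs are identical for any workers >= 1."""
    units = pair_files(folder)
    jobs = [(str(r1), str(r2) if r2 else None, options) for r1, r2 in units]
    if workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            dicts = list(pool.map(_run_unit, jobs))
    else:
        dicts = [_run_unit(j) for j in jobs]
    return [RunSummary.from_dict(d) for d in dicts]
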