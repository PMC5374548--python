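"""Report rendering: machine-readable JSON plus a self-contained static HTML.

The JSON file is the full RunSummary with a stable schema (it round-trips to
an equal summary). The HTML report embeds matplotlib figures as base64 PNG:
per-cycle base content and quality (pre/post filtering), the discontinuity
curve, the k-mer strand-bias scatter, and the 12-category base-transform bar
chart, plus the filtering summary tables.
"""

from __future__ import annotations

import base64
import io
import json
from pathlib import Path
from typing import TYPE_CHECKING, List

from .overlap import TRANSFORMS

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import RunSummary


def _fig_to_b64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=80, bbox_inches="tight",
                metadata={"Software": None})
    import matplotlib.pyplot as plt

    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _content_figure(profile: dict, title: str):
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    totals = profile.get("totals", [])
    cycles = list(range(len(totals)))
    for base in "ACGTN":
        series = profile.get("counts", {}).get(base, [])
        frac = [c / t if t else 0.0 for c, t in zip(series, totals)]
        ax1.plot(cycles, [100 * f for f in frac], label=base, lw=1)
    ax1.set_ylabel("base content (%)")
    ax1.set_title(title)
    ax1.legend(ncol=5, fontsize=8)
    ax2.plot(cycles, profile.get("mean_qual", []), color="tab:blue", lw=1)
    ax2.set_ylabel("mean quality (Phred)")
    ax2.set_xlabel("cycle")
    return fig


def _strand_bias_figure(entries: List[list]):
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    fwd = [e[1] for e in entries]
    rev = [e[2] for e in entries]
    ax.scatter(fwd, rev, s=4, alpha=0.4)
    lim = max(fwd + rev + [1])
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("forward k-mer count")
    ax.set_ylabel("reverse-complement count")
    ax.set_title("k-mer strand bias")
    return fig


def _transforms_figure(transforms: dict):
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    values = [transforms.get(t, 0) for t in TRANSFORMS]
    ax.bar(range(len(TRANSFORMS)), values, color="tab:orange")
    ax.set_xticks(range(len(TRANSFORMS)))
    ax.set_xticklabels(TRANSFORMS, rotation=45, fontsize=8)
    ax.set_ylabel("count")
    ax.set_title("sequencing error transforms (true → observed)")
    return fig


def _discontinuity_figure(curve: List[float]):
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 2.5))
    ax.plot(range(len(curve)), curve, lw=1)
    ax.set_xlabel("window start cycle")
    ax.set_ylabel("mean discontinuity")
    ax.set_title("per-cycle discontinuity")
    return fig


def _table(rows: List[tuple]) -> str:
    body = "".join(f"<tr><td>{k}</td><td>{v}</td></tr>" for k, v in rows)
    return f"<table border='1' cellpadding='4' cellspacing='0'>{body}</table>"


def render_report(summary: "RunSummary", out_dir: str | Path,
                  write_html: bool = True) -> List[Path]:
    """Write report.json (stable schema) and report.html; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    written = [json_path]
    if not write_html:
        return written

    import matplotlib

    matplotlib.use("Agg")

    sections = []
    counts_rows = [("input", ", ".join(summary.inputs)),
                   ("mode", "pair-end" if summary.mode == "pe" else "single-end"),
                   ("total", summary.counts.get("total", 0)),
                   ("good", summary.counts.get("good", 0)),
                   ("bad", summary.counts.get("bad", 0))]
    counts_rows += [(f"bad: {k}", v) for k, v in sorted(summary.bad_by_reason.items())]
    counts_rows += [(f"trim {m} (front, tail)", tuple(v))
                    for m, v in summary.trim.items()]
    if summary.overlap:
        counts_rows += list(summary.overlap.items())
    if summary.error_stats:
        counts_rows += [("overlapped bases", summary.error_stats.get("total", 0)),
                        ("mismatched bases", summary.error_stats.get("mismatched", 0)),
                        ("estimated error rate",
                         f"{summary.error_stats.get('rate', 0.0):.6f}")]
    if summary.strand_bias_summary is not None:
        counts_rows.append(("strand-bias summary", f"{summary.strand_bias_summary:.4f}"))
    sections.append("<h2>Summary</h2>" + _table(counts_rows))

    for label, profile_key in (("pre-filtering", "pre_profile"),
                               ("post-filtering", "post_profile")):
        profiles = getattr(summary, profile_key) or {}
        for mate, profile in sorted(profiles.items()):
            if not profile.get("totals"):
                continue
            b64 = _fig_to_b64(_content_figure(
                profile, f"{label} per-cycle profile ({mate})"))
            sections.append(f"<h2>{label} QC ({mate})</h2>"
                            f"<img src='data:image/png;base64,{b64}'/>")

    if summary.discontinuity:
        b64 = _fig_to_b64(_discontinuity_figure(summary.discontinuity))
        sections.append(f"<h2>Discontinuity</h2><img src='data:image/png;base64,{b64}'/>")
    if summary.strand_bias:
        b64 = _fig_to_b64(_strand_bias_figure(summary.strand_bias))
        sections.append(f"<h2>Strand bias</h2><img src='data:image/png;base64,{b64}'/>")
    transforms = (summary.error_stats or {}).get("transforms", {})
    if summary.mode == "pe":
        b64 = _fig_to_b64(_transforms_figure(transforms))
        sections.append("<h2>Sequencing error transforms</h2>"
                        f"<img src='data:image/png;base64,{b64}'/>")
    if summary.bubble_circles:
        rows = [(f"lane {c['lane']} tile {c['tile']}",
                 f"center ({c['cx']:.0f}, {c['cy']:.0f}) r={c['r']:.0f} "
                 f"support={c['support']}") for c in summary.bubble_circles]
        sections.append("<h2>Bubbles</h2>" + _table(rows))

    html = ("<!DOCTYPE html><html><head><meta charset='utf-8'>"
            "<title>pairqc report</title></head><body>"
            "<h1>pairqc report</h1>" + "".join(sections) + "</body></html>\n")
    html_path = out_dir / "report.html"
    html_path.write_text(html)
    written.append(html_path)
    return written
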