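"""Introgression-segment calling and population summaries.

The segment length rule follows graphical-genotype practice for substitution
lines: an inter-marker interval flanked by two donor-type markers (DD) counts
as 100 % donor, an interval flanked by one donor and one recurrent marker (DR)
counts as 50 % donor, and an RR interval as 0 %.  A maximal run of consecutive
donor-state markers therefore yields one segment whose estimated length is the
DD span plus two half flanking DR gaps:

    [first_run_marker - gap_left / 2,  last_run_marker + gap_right / 2]

Homozygous (``D``) and heterozygous (``H``) runs are called separately and
never merged; where a D run abuts an H run the shared boundary is the midpoint
between the adjacent markers.  Missing calls (``U``) are transparent — gaps
are measured across them to the nearest informative marker — while
non-parental calls (``N``) break runs like ``R``.  A run containing the first
(last) informative marker of a chromosome extends to the terminus on that
side by default, since no recombination evidence bounds it
(``end_extension="marker"`` stops at the marker instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genetic_map import GeneticMap
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

DONOR_STATES = {"D": "homozygous", "H": "heterozygous"}

#: Histogram bin edges (cM) used for segment-length frequency reports:
#: <5, 5-10, 10-20, >20.
DEFAULT_LENGTH_BINS = (0.0, 5.0, 10.0, 20.0, float("inf"))


@dataclass(frozen=True)
class Segment:
    """One contiguous donor introgression in one line."""

    line: str
    chromosome: str
    start_cm: float
    end_cm: float
    zygosity: str  # "homozygous" | "heterozygous"
    markers: tuple[str, ...]

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


def call_segments(
    matrix: GenotypeMatrix,
    end_extension: str = "terminus",
) -> list[Segment]:
    """Call every donor segment in every line of ``matrix``.

    Returns segments sorted by (line, chromosome order, start).  Degenerate
    zero-length runs (co-located flanking markers) are dropped with a warning.
    """
    if end_extension not in {"terminus", "marker"}:
        raise ValidationError(f"end_extension must be terminus|marker, got {end_extension!r}")
    segments: list[Segment] = []
    gmap = matrix.map
    per_chrom = [
        (chrom, length, gmap.markers_on(chrom)["marker"].to_numpy(),
         gmap.positions_cm(chrom))
        for chrom, length in gmap.chromosomes.items()
    ]
    for line_id in matrix.line_ids:
        calls = matrix.calls.loc[line_id]
        for chrom, length, ids, pos in per_chrom:
            states = calls[ids].to_numpy()
            keep = states != "U"  # missing markers are transparent
            s, p, m = states[keep], pos[keep], ids[keep]
            segments.extend(
                _call_chromosome(line_id, chrom, length, m, p, s, end_extension)
            )
    return segments


def _call_chromosome(line_id, chrom, length, ids, pos, states, end_extension):
    out = []
    n = len(states)
    i = 0
    while i < n:
        st = states[i]
        if st not in DONOR_STATES:
            i += 1
            continue
        j = i
        while j + 1 < n and states[j + 1] == st:
            j += 1
        if i == 0:
            start = 0.0 if end_extension == "terminus" else float(pos[0])
        else:
            start = (pos[i - 1] + pos[i]) / 2.0
        if j == n - 1:
            end = float(length) if end_extension == "terminus" else float(pos[j])
        else:
            end = (pos[j] + pos[j + 1]) / 2.0
        if end > start:
            out.append(
                Segment(
                    line=line_id, chromosome=chrom,
                    start_cm=float(start), end_cm=float(end),
                    zygosity=DONOR_STATES[st], markers=tuple(ids[i : j + 1]),
                )
            )
        else:
            logger.warning(
                "dropping zero-length segment at %s chr%s marker(s) %s",
                line_id, chrom, list(ids[i : j + 1]),
            )
        i = j + 1
    return out


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    """Tidy export table: one row per segment, lengths in cM."""
    return pd.DataFrame(
        [
            {
                "line": s.line,
                "chromosome": s.chromosome,
                "start_cM": s.start_cm,
                "end_cM": s.end_cm,
                "zygosity": s.zygosity,
                "length_cM": s.length_cm,
                "markers": ",".join(s.markers),
            }
            for s in segments
        ],
        columns=["line", "chromosome", "start_cM", "end_cM", "zygosity", "length_cM", "markers"],
    )


def frame_to_segments(df: pd.DataFrame) -> list[Segment]:
    return [
        Segment(
            line=str(r.line), chromosome=str(r.chromosome),
            start_cm=float(r.start_cM), end_cm=float(r.end_cM),
            zygosity=str(r.zygosity), markers=tuple(str(r.markers).split(",")) if r.markers else (),
        )
        for r in df.itertuples()
    ]


def segments_to_bed(segments: list[Segment], gmap: GeneticMap) -> pd.DataFrame:
    """BED-like physical-coordinate export (0-based half-open).

    Each segment is mapped to the physical span of its supporting markers;
    requires bp positions in the map.
    """
    bp = dict(zip(gmap.table["marker"], gmap.table["bp"]))
    rows = []
    for s in segments:
        positions = [bp[m] for m in s.markers if pd.notna(bp.get(m))]
        if not positions:
            continue
        rows.append(
            {
                "chrom": s.chromosome,
                "chromStart": int(min(positions)) - 1,
                "chromEnd": int(max(positions)),
                "name": f"{s.line}:{s.zygosity}",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "chromStart", "chromEnd", "name"])


# -- interval arithmetic ---------------------------------------------------

def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of closed intervals as a sorted, disjoint list."""
    merged: list[list[float]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def union_length(intervals: list[tuple[float, float]]) -> float:
    return sum(hi - lo for lo, hi in merge_intervals(intervals))


# -- population summaries --------------------------------------------------

@dataclass
class CoverageReport:
    """Per-chromosome segment counts, lengths and donor-genome coverage.

    ``per_chromosome`` has one row per chromosome with columns
    ``chromosome, length_cM, n_homozygous, mean_homozygous_length_cM,
    n_heterozygous, mean_heterozygous_length_cM, total_segment_length_cM,
    effective_coverage_cM, coverage_percent``; ``totals`` aggregates over the
    genome.  Effective coverage is the length of the union, across lines, of
    all donor segments (het + homo) — the donor genome represented by at
    least one line.
    """

    per_chromosome: pd.DataFrame
    totals: dict[str, float]

    def rounded(self, ndigits: int = 1) -> pd.DataFrame:
        out = self.per_chromosome.copy()
        for c in out.columns:
            if c != "chromosome":
                out[c] = out[c].astype(float).round(ndigits)
        return out


def coverage_report(segments: list[Segment], gmap: GeneticMap) -> CoverageReport:
    rows = []
    for chrom, length in gmap.chromosomes.items():
        segs = [s for s in segments if s.chromosome == chrom]
        for s in segs:
            if s.start_cm < -1e-9 or s.end_cm > length + 1e-9:
                raise ValidationError(
                    f"segment {s} outside chromosome {chrom} bounds [0, {length}]"
                )
        homo = [s for s in segs if s.zygosity == "homozygous"]
        het = [s for s in segs if s.zygosity == "heterozygous"]
        eff = union_length([(s.start_cm, s.end_cm) for s in segs])
        rows.append(
            {
                "chromosome": chrom,
                "length_cM": length,
                "n_homozygous": len(homo),
                "mean_homozygous_length_cM": float(np.mean([s.length_cm for s in homo])) if homo else 0.0,
                "n_heterozygous": len(het),
                "mean_heterozygous_length_cM": float(np.mean([s.length_cm for s in het])) if het else 0.0,
                "total_segment_length_cM": float(sum(s.length_cm for s in segs)),
                "effective_coverage_cM": eff,
                "coverage_percent": 100.0 * eff / length if length else 0.0,
            }
        )
    per = pd.DataFrame(rows)
    total_len = float(per["length_cM"].sum())
    eff_total = float(per["effective_coverage_cM"].sum())
    n_segs = int(per["n_homozygous"].sum() + per["n_heterozygous"].sum())
    all_lengths = [s.length_cm for s in segments]
    totals = {
        "map_length_cM": total_len,
        "n_segments": n_segs,
        "n_homozygous": int(per["n_homozygous"].sum()),
        "n_heterozygous": int(per["n_heterozygous"].sum()),
        "mean_segment_length_cM": float(np.mean(all_lengths)) if all_lengths else 0.0,
        "total_segment_length_cM": float(per["total_segment_length_cM"].sum()),
        "effective_coverage_cM": eff_total,
        "coverage_percent": 100.0 * eff_total / total_len if total_len else 0.0,
    }
    return CoverageReport(per_chromosome=per, totals=totals)


def length_histogram(
    segments: list[Segment],
    bin_edges: tuple[float, ...] = DEFAULT_LENGTH_BINS,
) -> pd.DataFrame:
    """Segment-length frequency table over half-open bins ``[lo, hi)``."""
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin edges must be strictly increasing")
    lengths = np.array([s.length_cm for s in segments], dtype=float)
    counts, _ = np.histogram(lengths, bins=edges) if len(lengths) else (
        np.zeros(len(edges) - 1, dtype=int), None)
    # numpy's last bin is closed; with an infinite upper edge this matches [lo, inf)
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin_low_cM": edges[:-1],
            "bin_high_cM": edges[1:],
            "count": counts.astype(int),
            "percent": 100.0 * counts / total if total else np.zeros(len(counts)),
        }
    )


def line_summaries(
    segments: list[Segment],
    matrix: GenotypeMatrix,
) -> pd.DataFrame:
    """Per-line segment counts, introgression totals and NIL status.

    A NIL (near-isogenic line) carries exactly one donor segment.  Background
    recovery weights heterozygous length at one half (one donor haplotype) in
    the donor fraction.
    """
    gmap = matrix.map
    total_map = gmap.total_length_cm
    by_line: dict[str, list[Segment]] = {lid: [] for lid in matrix.line_ids}
    for s in segments:
        by_line.setdefault(s.line, []).append(s)
    rows = []
    for lid in matrix.line_ids:
        segs = by_line[lid]
        homo = sum(s.length_cm for s in segs if s.zygosity == "homozygous")
        het = sum(s.length_cm for s in segs if s.zygosity == "heterozygous")
        donor_cm = homo + 0.5 * het
        rows.append(
            {
                "line": lid,
                "n_segments": len(segs),
                "n_homozygous": sum(s.zygosity == "homozygous" for s in segs),
                "n_heterozygous": sum(s.zygosity == "heterozygous" for s in segs),
                "total_introgression_cM": homo + het,
                "background_recovery_percent": 100.0 * (1.0 - donor_cm / total_map),
                "is_NIL": len(segs) == 1,
            }
        )
    return pd.DataFrame(rows)
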