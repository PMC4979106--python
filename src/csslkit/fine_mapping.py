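"""QTL interval refinement by donor-segment intersection on dense marker data.

Given several lines that share a phenotype, the region responsible must lie
where all of them carry donor chromatin.  On a dense, physically anchored
marker matrix (e.g. a SNP-chip-like assay), each line's donor intervals are
called with the same midpoint convention as genetic-coordinate segment
calling — boundaries halfway between adjacent informative markers, clipped to
the assayed marker range — and the candidate region is the set-intersection
of those intervals across lines.  Physical intervals are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhysicalInterval:
    """A physical (bp) interval supported by a set of lines."""

    chromosome: str
    start_bp: int
    end_bp: int
    lines: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError(f"start_bp {self.start_bp} > end_bp {self.end_bp}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def donor_intervals_bp(
    matrix: GenotypeMatrix,
    line: str,
    chromosome: str,
    include_het: bool = False,
) -> list[tuple[int, int]]:
    """Donor intervals (1-based inclusive bp) for one line on one chromosome.

    By default only homozygous donor calls count (fixed lines);
    ``include_het`` also accepts heterozygous calls.  Boundaries fall at
    midpoints between adjacent informative markers and never extend beyond
    the first/last assayed marker.
    """
    sub = matrix.map.markers_on(chromosome)
    if sub.empty:
        raise ValidationError(f"no markers on chromosome {chromosome!r}")
    if sub["bp"].isna().any():
        missing = sub.loc[sub["bp"].isna(), "marker"].tolist()
        raise ValidationError(
            f"markers without physical positions on chromosome {chromosome}: {missing[:5]}"
        )
    calls = matrix.line(line)[sub["marker"]].to_numpy()
    bp = sub["bp"].to_numpy(dtype=np.int64)
    keep = calls != "U"
    calls, bp = calls[keep], bp[keep]
    donor_states = {"D", "H"} if include_het else {"D"}
    n = len(calls)
    out: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if calls[i] not in donor_states:
            i += 1
            continue
        j = i
        while j + 1 < n and calls[j + 1] in donor_states:
            j += 1
        lo = int(bp[0]) if i == 0 else int((bp[i - 1] + bp[i]) // 2)
        hi = int(bp[-1]) if j == n - 1 else int((bp[j] + bp[j + 1]) // 2)
        out.append((lo, hi))
        i = j + 1
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two sorted disjoint inclusive-interval lists."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def shared_donor_region(
    matrix: GenotypeMatrix,
    lines: list[str],
    chromosome: str,
    include_het: bool = False,
) -> list[PhysicalInterval]:
    """Intervals where every listed line carries donor chromatin.

    An empty result is legal (no shared region); a requested line with no
    donor material on the chromosome makes the intersection empty with a
    warning.
    """
    if not lines:
        raise ValidationError("at least one line required")
    shared: list[tuple[int, int]] | None = None
    for line in lines:
        ivs = donor_intervals_bp(matrix, line, chromosome, include_het=include_het)
        if not ivs:
            logger.warning("line %s has no donor material on chromosome %s", line, chromosome)
            return []
        shared = ivs if shared is None else _intersect(shared, ivs)
        if not shared:
            return []
    return [
        PhysicalInterval(chromosome=str(chromosome), start_bp=lo, end_bp=hi,
                         lines=tuple(lines))
        for lo, hi in shared
    ]


def format_kb(length_bp: int) -> str:
    return f"{length_bp / 1000:g} kb"


def refine_qtl(
    qtl_name: str,
    region: PhysicalInterval,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Report a refined QTL interval against known-gene annotations.

    ``annotations`` is BED-like with columns ``chromosome, start_bp, end_bp,
    name`` (1-based inclusive).  The QTL is flagged ``novel`` when no supplied
    annotation overlaps the region.
    """
    overlapping = []
    if annotations is not None and len(annotations):
        ann = annotations[annotations["chromosome"].astype(str) == region.chromosome]
        for r in ann.itertuples():
            if int(r.start_bp) <= region.end_bp and int(r.end_bp) >= region.start_bp:
                overlapping.append(str(r.name))
    return {
        "qtl": qtl_name,
        "chromosome": region.chromosome,
        "start_bp": region.start_bp,
        "end_bp": region.end_bp,
        "length_bp": region.length_bp,
        "length": format_kb(region.length_bp),
        "overlapping_annotations": overlapping,
        "novel": not overlapping,
    }
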