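"""Shared test utilities: fixture builders and independent oracles.

The oracles here deliberately re-derive expected results by a different
route than the library (interval-by-interval classification, bp-grid
membership) so that tests compare two independent implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import csslkit as ck


def make_map(
    positions,
    length: float | None = None,
    chrom: str = "1",
    bp=None,
    prefix: str = "m",
) -> ck.GeneticMap:
    """Single-chromosome map from a list of cM positions."""
    n = len(positions)
    df = pd.DataFrame(
        {
            "marker": [f"{prefix}{i + 1}" for i in range(n)],
            "chromosome": [chrom] * n,
            "cm": list(positions),
            "bp": list(bp) if bp is not None else [pd.NA] * n,
        }
    )
    lengths = {chrom: length} if length is not None else None
    return ck.GeneticMap.from_dataframe(df, lengths=lengths)


def make_matrix(gmap: ck.GeneticMap, calls: dict[str, str]) -> ck.GenotypeMatrix:
    """Genotype matrix from per-line call strings in map order."""
    markers = gmap.marker_ids
    rows = {line: list(s) for line, s in calls.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
    return ck.GenotypeMatrix(map=gmap, calls=df)


# -- independent segment-rule oracle ---------------------------------------

def oracle_segments(
    states: str,
    positions,
    length: float,
    end_extension: str = "terminus",
) -> list[tuple[float, float, str]]:
    """Brute-force interval classifier for one line on one chromosome.

    Labels each inter-marker interval 100 % / 50 % / 0 % donor by its flanking
    marker states (DD / DR / RR), attributes terminal intervals to the end
    marker's state, then merges contiguous same-state donor pieces.  Returns
    (start, end, zygosity) tuples.
    """
    zyg = {"D": "homozygous", "H": "heterozygous"}
    inf = [(float(p), s) for p, s in zip(positions, states) if s != "U"]
    if not inf:
        return []
    pieces: list[tuple[float, float, str]] = []
    p0, s0 = inf[0]
    if s0 in zyg:
        pieces.append((0.0 if end_extension == "terminus" else p0, p0, s0))
    for (pa, sa), (pb, sb) in zip(inf, inf[1:]):
        mid = (pa + pb) / 2.0
        if sa in zyg and sb == sa:
            pieces.append((pa, pb, sa))  # DD interval: 100 % donor
        else:
            if sa in zyg:
                pieces.append((pa, mid, sa))  # left half of a DR interval
            if sb in zyg:
                pieces.append((mid, pb, sb))  # right half of a DR interval
    pn, sn = inf[-1]
    if sn in zyg:
        pieces.append((pn, length if end_extension == "terminus" else pn, sn))

    merged: list[list] = []
    for lo, hi, st in pieces:
        if merged and merged[-1][2] == st and lo <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi, st])
    return [(lo, hi, zyg[st]) for lo, hi, st in merged if hi > lo]


def random_small_matrix(rng: np.random.Generator):
    """Random toy matrix (<=5 lines, <=10 markers, 1-2 chromosomes) for
    oracle-equivalence checks."""
    n_chrom = int(rng.integers(1, 3))
    frames = []
    lengths = {}
    for c in range(n_chrom):
        n = int(rng.integers(1, 6))
        pos = np.sort(rng.uniform(0, 50, size=n)).round(2)
        length = float(pos[-1] + rng.uniform(0, 10))
        lengths[str(c + 1)] = round(length, 2)
        frames.append(
            pd.DataFrame(
                {
                    "marker": [f"c{c + 1}m{i}" for i in range(n)],
                    "chromosome": str(c + 1),
                    "cm": pos,
                }
            )
        )
    gmap = ck.GeneticMap.from_dataframe(pd.concat(frames, ignore_index=True), lengths=lengths)
    n_lines = int(rng.integers(1, 6))
    alphabet = np.array(list("RDHNU"))
    calls = {
        f"L{i}": "".join(rng.choice(alphabet, size=gmap.n_markers, p=[0.4, 0.25, 0.15, 0.1, 0.1]))
        for i in range(n_lines)
    }
    return make_matrix(gmap, calls)


def assert_segments_match_oracle(matrix: ck.GenotypeMatrix, end_extension="terminus"):
    got = ck.call_segments(matrix, end_extension=end_extension)
    for line in matrix.line_ids:
        for chrom, length in matrix.map.chromosomes.items():
            sub = matrix.map.markers_on(chrom)
            states = "".join(matrix.calls.loc[line, sub["marker"]])
            expected = oracle_segments(states, sub["cm"].to_numpy(), length, end_extension)
            mine = sorted(
                (s.start_cm, s.end_cm, s.zygosity)
                for s in got
                if s.line == line and s.chromosome == chrom
            )
            assert len(mine) == len(expected), (line, chrom, states, mine, expected)
            for (a, b, z), (ea, eb, ez) in zip(mine, sorted(expected)):
                assert z == ez and abs(a - ea) < 1e-9 and abs(b - eb) < 1e-9, (
                    line, chrom, states, mine, expected)


# -- fine-mapping grid oracle ----------------------------------------------

def grid_shared_membership(
    interval_lists: list[list[tuple[int, int]]], grid: np.ndarray
) -> np.ndarray:
    """Boolean membership on a bp grid: positions inside every line's
    interval set (inclusive endpoints)."""
    mask = np.ones(len(grid), dtype=bool)
    for ivs in interval_lists:
        m = np.zeros(len(grid), dtype=bool)
        for lo, hi in ivs:
            m |= (grid >= lo) & (grid <= hi)
        mask &= m
    return mask
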