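"""Lines x markers genotype matrices and graphical-genotype rendering data.

Calls use a closed five-letter alphabet:

========  =================================================
``R``     homozygous for the recurrent parent (e.g. 9311)
``D``     homozygous for the donor parent (e.g. CWR276)
``H``     heterozygous
``N``     non-parental allele
``U``     missing / unknown
========  =================================================

``N`` and ``U`` are never counted as donor material downstream; ``N`` breaks
donor runs while ``U`` is transparent to segment calling (see
:mod:`csslkit.segment_calling`).  A ``symbol_map`` on load supports alternate
file dialects such as A/B/H.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genetic_map import GeneticMap

logger = logging.getLogger(__name__)

CALL_ALPHABET = frozenset({"R", "D", "H", "N", "U"})

#: Graphical-genotype block state names keyed by call code.
BLOCK_STATES = {
    "R": "recurrent",
    "D": "donor",
    "H": "heterozygous",
    "N": "non_parental",
    "U": "unknown",
}

#: Conventional display colours for graphical genotypes.
STATE_COLORS = {
    "recurrent": "lightgray",
    "donor": "red",
    "heterozygous": "gold",
    "non_parental": "green",
    "unknown": "white",
}


@dataclass
class GenotypeMatrix:
    """Validated genotype calls for a set of lines over a map's markers.

    ``calls`` is indexed by line id with one single-character column per
    marker, in map order.
    """

    map: GeneticMap
    calls: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.calls.index = self.calls.index.astype(str)
        self.calls.index.name = "line"
        if self.calls.index.duplicated().any():
            dup = self.calls.index[self.calls.index.duplicated()].tolist()
            raise ValidationError(f"duplicate line id(s): {dup}")
        want = self.map.marker_ids
        have = list(self.calls.columns)
        missing = [m for m in want if m not in set(have)]
        extra = [m for m in have if m not in set(want)]
        if missing:
            raise ValidationError(f"genotype matrix missing map markers: {missing}")
        if extra:
            raise ValidationError(f"genotype matrix has markers absent from map: {extra}")
        if have != want:
            self.calls = self.calls[want]
        bad = ~self.calls.isin(CALL_ALPHABET)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            line, marker = self.calls.index[r], self.calls.columns[c]
            raise ValidationError(
                f"unknown genotype symbol {self.calls.iat[r, c]!r} "
                f"at line {line!r}, marker {marker!r}"
            )

    @property
    def line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_lines(self) -> int:
        return len(self.calls)

    def line(self, line_id: str) -> pd.Series:
        if line_id not in self.calls.index:
            raise ValidationError(f"unknown line id {line_id!r}")
        return self.calls.loc[line_id]

    def write(self, path: str | Path) -> None:
        out = self.calls.copy()
        out.index.name = "line"
        out.to_csv(path, sep="\t")

    def non_parental_counts(self) -> pd.Series:
        """Per-line tally of non-parental (``N``) calls."""
        return (self.calls == "N").sum(axis=1)


def load_genotypes(
    path: str | Path,
    gmap: GeneticMap,
    symbol_map: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a tab-separated genotype matrix (``line`` column + one per marker).

    Columns may be in any order; they are validated against the map and
    reordered to map order.  ``symbol_map`` translates an alternative call
    dialect (e.g. ``{"A": "R", "B": "D"}``) before validation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "line":
        df = df.rename(columns={df.columns[0]: "line"})
    df = df.set_index("line")
    df = df.fillna("U")
    if symbol_map:
        df = df.replace(symbol_map)
    return GenotypeMatrix(map=gmap, calls=df)


def graphical_genotype(matrix: GenotypeMatrix, line_id: str) -> pd.DataFrame:
    """Coloured-block representation of one line, per chromosome.

    Returns a frame with columns ``line, chromosome, start_cM, end_cM, state``
    whose blocks exactly partition each chromosome's ``[0, length]``.  Block
    boundaries fall at inter-marker midpoints (the same half-interval
    convention segment calling uses); runs of missing calls are emitted as
    explicit ``unknown`` blocks rather than being absorbed into neighbours.
    """
    calls = matrix.line(line_id)
    rows = []
    for chrom, length in matrix.map.chromosomes.items():
        sub = matrix.map.markers_on(chrom)
        pos = sub["cm"].to_numpy(dtype=float)
        states = calls[sub["marker"]].to_numpy()
        if len(pos) == 0:
            rows.append((line_id, chrom, 0.0, length, "unknown"))
            continue
        # maximal runs of identical call state, boundaries at midpoints
        run_starts = [0] + [i for i in range(1, len(states)) if states[i] != states[i - 1]]
        run_ends = run_starts[1:] + [len(states)]
        for s, e in zip(run_starts, run_ends):
            lo = 0.0 if s == 0 else (pos[s - 1] + pos[s]) / 2.0
            hi = length if e == len(states) else (pos[e - 1] + pos[e]) / 2.0
            if hi > lo:
                rows.append((line_id, chrom, lo, hi, BLOCK_STATES[states[s]]))
    return pd.DataFrame(
        rows, columns=["line", "chromosome", "start_cM", "end_cM", "state"]
    )


def write_blocks(blocks: pd.DataFrame, path: str | Path) -> None:
    blocks.to_csv(path, sep="\t", index=False)


def plot_genotypes(matrix: GenotypeMatrix, path: str | Path, lines: list[str] | None = None) -> None:
    """Render a graphical-genotype figure (one column per line) to ``path``.

    Requires matplotlib; the exported block table is the correctness surface,
    the figure is a convenience.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lines = lines or matrix.line_ids
    chroms = list(matrix.map.chromosomes)
    offsets = {}
    x = 0.0
    for c in chroms:
        offsets[c] = x
        x += matrix.map.chromosomes[c] + 10.0
    fig, ax = plt.subplots(figsize=(max(6, len(lines) * 0.12), 8))
    for i, line_id in enumerate(lines):
        blocks = graphical_genotype(matrix, line_id)
        for _, b in blocks.iterrows():
            y0 = offsets[b["chromosome"]] + b["start_cM"]
            ax.bar(
                i, b["end_cM"] - b["start_cM"], bottom=y0, width=0.8,
                color=STATE_COLORS[b["state"]], edgecolor="none",
            )
    ax.set_xlabel("line")
    ax.set_ylabel("stacked chromosomes (cM)")
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
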