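"""Genetic marker maps: loading, validation and spacing statistics.

A :class:`GeneticMap` holds an ordered set of chromosomes, each with a genetic
length in centimorgans (cM) and an ordered list of markers.  All coordinate
conventions used elsewhere in the package are owned here:

* cM positions are distances from the chromosome top (position 0); cM
  intervals are closed.
* physical (bp) intervals are 1-based inclusive.
* chromosome labels are strings; dialects like ``Chr.1`` / ``chr1`` normalise
  to ``"1"``.

The bundled reference geometry (:data:`RICE_CHROMOSOME_LENGTHS_CM`,
:data:`RICE_MARKER_COUNTS`) describes the 12-chromosome rice SSR framework map
used to genotype 9311 x CWR276 substitution lines: 313 polymorphic markers
over 1782 cM.  :func:`default_rice_map` turns it into a concrete map with
uniformly spaced markers, which the breeding simulator uses as its default
substrate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Genetic length (cM) of each rice chromosome in the bundled SSR framework map.
RICE_CHROMOSOME_LENGTHS_CM: dict[str, float] = {
    "1": 202.3, "2": 201.3, "3": 221.4, "4": 144.9, "5": 142.0, "6": 145.3,
    "7": 113.3, "8": 128.4, "9": 103.6, "10": 146.6, "11": 124.4, "12": 108.5,
}

#: Number of polymorphic SSR markers per chromosome in the bundled map (313 total).
RICE_MARKER_COUNTS: dict[str, int] = {
    "1": 36, "2": 31, "3": 26, "4": 23, "5": 22, "6": 31,
    "7": 20, "8": 26, "9": 23, "10": 21, "11": 28, "12": 26,
}

_CHROM_PREFIX = re.compile(r"^\s*chr\.?\s*", re.IGNORECASE)


def normalize_chromosome(label: object) -> str:
    """Normalise a chromosome label: ``Chr.1`` / ``chr1`` / ``1`` -> ``"1"``."""
    return _CHROM_PREFIX.sub("", str(label).strip())


@dataclass(frozen=True)
class Marker:
    """A single mapped marker."""

    id: str
    chromosome: str
    position_cm: float
    position_bp: int | None = None


@dataclass
class GeneticMap:
    """Ordered chromosomes plus per-chromosome sorted markers.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome label to genetic length in cM, in display order.
    table
        One row per marker with columns ``marker``, ``chromosome``, ``cm``
        and nullable ``bp``; sorted by (chromosome order, cm, marker id).
    """

    chromosomes: dict[str, float]
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        lengths: dict[str, float] | None = None,
    ) -> "GeneticMap":
        """Build a validated map from a marker table.

        ``df`` needs columns ``marker``, ``chromosome``, ``cm`` and may have
        ``bp``.  Chromosome lengths default to the last marker position unless
        ``lengths`` overrides them (framework maps typically extend beyond the
        last polymorphic marker).
        """
        df = df.copy()
        required = {"marker", "chromosome", "cm"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"marker table missing columns: {sorted(missing)}")
        df["marker"] = df["marker"].astype(str)
        df["chromosome"] = df["chromosome"].map(normalize_chromosome)
        df["cm"] = df["cm"].astype(float)
        if "bp" not in df.columns:
            df["bp"] = pd.NA
        df["bp"] = df["bp"].astype("Int64")

        dup = df["marker"][df["marker"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate marker id(s): {sorted(set(dup))}")
        if (df["cm"] < 0).any():
            bad = df.loc[df["cm"] < 0, "marker"].tolist()
            raise ValidationError(f"negative cM position for marker(s): {bad}")
        if df["bp"].notna().any() and (df["bp"].dropna() < 0).any():
            raise ValidationError("negative bp position in marker table")

        chrom_order = list(dict.fromkeys(df["chromosome"]))
        chroms: dict[str, float] = {}
        for c in chrom_order:
            chroms[c] = float(df.loc[df["chromosome"] == c, "cm"].max())
        if lengths is not None:
            lengths = {normalize_chromosome(k): float(v) for k, v in lengths.items()}
            unknown = set(lengths) - set(chroms)
            if unknown:
                raise ValidationError(
                    f"lengths override names unknown chromosome(s): {sorted(unknown)}"
                )
            chroms.update(lengths)

        # co-located markers are legal; ties break by marker id, with a warning
        ties = df.duplicated(subset=["chromosome", "cm"], keep=False)
        if ties.any():
            logger.warning(
                "co-located markers at identical cM positions: %s",
                df.loc[ties, "marker"].tolist(),
            )
        key = df["chromosome"].map({c: i for i, c in enumerate(chrom_order)})
        df = (
            df.assign(_k=key)
            .sort_values(["_k", "cm", "marker"], kind="stable")
            .drop(columns="_k")
            .reset_index(drop=True)
        )
        return cls(chromosomes=chroms, table=df)

    def _validate(self) -> None:
        for c, length in self.chromosomes.items():
            sub = self.table[self.table["chromosome"] == c]
            if len(sub) and sub["cm"].max() > length + 1e-9:
                raise ValidationError(
                    f"marker beyond chromosome {c} length {length} cM"
                )
        unknown = set(self.table["chromosome"]) - set(self.chromosomes)
        if unknown:
            raise ValidationError(f"markers on unknown chromosome(s): {sorted(unknown)}")

    # -- queries -----------------------------------------------------------

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def total_length_cm(self) -> float:
        return float(sum(self.chromosomes.values()))

    def markers_on(self, chromosome: str) -> pd.DataFrame:
        c = normalize_chromosome(chromosome)
        return self.table[self.table["chromosome"] == c]

    def positions_cm(self, chromosome: str) -> np.ndarray:
        return self.markers_on(chromosome)["cm"].to_numpy(dtype=float)

    def chromosome_of(self, marker: str) -> str:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise ValidationError(f"marker {marker!r} not in map")
        return str(row["chromosome"].iloc[0])

    def position_of(self, marker: str) -> float:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise ValidationError(f"marker {marker!r} not in map")
        return float(row["cm"].iloc[0])

    # -- io ----------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        out = self.table.rename(columns={"cm": "cM"})
        out.to_csv(path, sep="\t", index=False)

    def write_lengths(self, path: str | Path) -> None:
        pd.DataFrame(
            {"chromosome": list(self.chromosomes), "length_cM": list(self.chromosomes.values())}
        ).to_csv(path, sep="\t", index=False)


def load_map(path: str | Path, lengths_path: str | Path | None = None) -> GeneticMap:
    """Read a tab-separated marker map (columns ``marker  chromosome  cM  [bp]``).

    An optional lengths file (``chromosome  length_cM``) overrides the default
    chromosome length, which is otherwise the last marker position.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chromosome": str})
    df = df.rename(columns={"cM": "cm"})
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", dtype={"chromosome": str})
        lengths = dict(zip(lt["chromosome"], lt["length_cM"].astype(float)))
    return GeneticMap.from_dataframe(df, lengths=lengths)


def spacing_stats(gmap: GeneticMap) -> pd.DataFrame:
    """Per-chromosome marker-spacing statistics plus a ``total`` row.

    ``mean_spacing_cm`` is chromosome length divided by the marker COUNT, not
    by the number of adjacent intervals.  This is the convention framework-map
    tables in the CSSL literature print (202.3 cM / 36 markers = 5.62 cM), and
    it differs from the usual mean adjacent gap; ``min_gap_cm``/``max_gap_cm``
    report the adjacent-interval extremes for reference.
    """
    rows = []
    for c, length in gmap.chromosomes.items():
        pos = gmap.positions_cm(c)
        if len(pos) == 0:
            logger.warning("chromosome %s has no markers; excluded from spacing stats", c)
            continue
        gaps = np.diff(pos)
        rows.append(
            {
                "chromosome": c,
                "length_cm": length,
                "n_markers": len(pos),
                "mean_spacing_cm": length / len(pos),
                "min_gap_cm": float(gaps.min()) if len(gaps) else np.nan,
                "max_gap_cm": float(gaps.max()) if len(gaps) else np.nan,
            }
        )
    per = pd.DataFrame(rows)
    total_len = float(per["length_cm"].sum())
    total_n = int(per["n_markers"].sum())
    total = {
        "chromosome": "total",
        "length_cm": total_len,
        "n_markers": total_n,
        "mean_spacing_cm": total_len / total_n if total_n else np.nan,
        "min_gap_cm": float(per["min_gap_cm"].min()),
        "max_gap_cm": float(per["max_gap_cm"].max()),
    }
    return pd.concat([per, pd.DataFrame([total])], ignore_index=True)


def default_rice_map(
    lengths: dict[str, float] | None = None,
    marker_counts: dict[str, int] | None = None,
    with_bp: bool = False,
    bp_per_cm: float = 250_000.0,
) -> GeneticMap:
    """Reference 12-chromosome rice map with uniformly spaced markers.

    Markers named ``M<chrom>_<i>`` are placed at positions
    ``length * (i + 1) / n`` so the first marker sits one spacing unit from the
    top and the last marker at the chromosome end.  With ``with_bp`` a physical
    coordinate is attached at a constant ``bp_per_cm`` scale, which is adequate
    for exercising physical-coordinate code paths (real genomes are not
    linear in cM).
    """
    lengths = dict(lengths or RICE_CHROMOSOME_LENGTHS_CM)
    marker_counts = dict(marker_counts or RICE_MARKER_COUNTS)
    rows = []
    for c, length in lengths.items():
        n = marker_counts[c]
        for i in range(n):
            cm = length * (i + 1) / n
            rows.append(
                {
                    "marker": f"M{c}_{i + 1}",
                    "chromosome": c,
                    "cm": round(cm, 4),
                    "bp": int(round(cm * bp_per_cm)) if with_bp else pd.NA,
                }
            )
    return GeneticMap.from_dataframe(pd.DataFrame(rows), lengths=lengths)
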