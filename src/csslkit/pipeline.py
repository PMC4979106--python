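"""End-to-end analysis pipeline and run configuration.

``run_pipeline`` wires the stages together: load map and genotypes, call
segments, write population summaries (coverage, line summaries, length
histogram), then — when phenotypes are supplied — scan every trait at every
site and declare QTLs.  All outputs are plain TSV plus a JSON manifest
recording inputs, thresholds, seed and package version; identical config and
inputs give byte-identical tables (the timestamp lives only in the manifest).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .genetic_map import load_map, spacing_stats
from .genotypes import load_genotypes
from .qtl_scan import declare_qtls, scan_all
from .segment_calling import (
    DEFAULT_LENGTH_BINS,
    call_segments,
    coverage_report,
    length_histogram,
    line_summaries,
    segments_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File paths and thresholds for a full pipeline run."""

    map_path: str
    genotypes_path: str
    output_dir: str
    lengths_path: str | None = None
    phenotypes_path: str | None = None
    p_threshold: float = 0.01
    qtl_window_cm: float = 20.0
    min_group: int = 3
    end_extension: str = "terminus"
    length_bins: tuple[float, ...] = DEFAULT_LENGTH_BINS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.qtl_window_cm <= 0 or self.min_group <= 0:
            raise ValidationError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _check_exists(path: str | None, label: str) -> None:
    if path is not None and not Path(path).exists():
        raise ValidationError(f"{label} file not found: {path}")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the pipeline; returns a mapping of output name -> path."""
    for p, label in [
        (config.map_path, "map"), (config.genotypes_path, "genotypes"),
        (config.lengths_path, "lengths"), (config.phenotypes_path, "phenotypes"),
    ]:
        _check_exists(p, label)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs[name] = path

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            logger.error("pipeline stage %r failed: %s", name, exc)
            raise

    gmap = stage("load_map", load_map, config.map_path, config.lengths_path)
    emit("map_stats", spacing_stats(gmap))
    matrix = stage("load_genotypes", load_genotypes, config.genotypes_path, gmap)
    segments = stage("call_segments", call_segments, matrix,
                     end_extension=config.end_extension)
    emit("segments", segments_to_frame(segments))
    cov = stage("coverage", coverage_report, segments, gmap)
    emit("coverage", cov.per_chromosome)
    emit("line_summaries", line_summaries(segments, matrix))
    emit("length_histogram", length_histogram(segments, tuple(config.length_bins)))

    if config.phenotypes_path is not None:
        phenotypes = pd.read_csv(config.phenotypes_path, sep="\t")
        scans = stage("scan", scan_all, matrix, phenotypes, min_group=config.min_group)
        emit("scan", scans)
        qtls = stage("declare_qtls", declare_qtls, scans,
                     p_threshold=config.p_threshold, window_cm=config.qtl_window_cm)
        emit("qtls", qtls)

    manifest = {
        "csslkit_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "coverage_totals": cov.totals,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    outputs["manifest"] = manifest_path
    return outputs
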