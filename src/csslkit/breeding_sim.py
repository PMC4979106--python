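"""Forward simulation of a CSSL breeding programme with marker-assisted selection.

The simulator regenerates the standard interspecific substitution-line
pipeline: a donor x recurrent F1 is backcrossed to the recurrent parent three
times without selection, the BC3F1 population is genotyped with a reduced
marker panel and plants carrying few donor segments are selected, then
successive backcross branches (BC4F1..BC7F1) are genotyped with the full map,
selected for "fewer than *k* substituted segments", and selfed to fixation to
yield the final line set.  Phenotypes are generated from additive QTL effects
with per-site intercepts and residual noise.

Genomes are represented as recombination-tract lists per chromosome
(breakpoint positions in cM plus parental origin), so donor fractions and
heterozygosity are exact, not marker-sampled.  Meiosis follows the Haldane
model by default: crossover counts are Poisson with mean length/100 and
positions are uniform, with no interference — which makes the expected donor
fraction after *n* backcrosses exactly (1/2)^(n+1).  ``map_function="kosambi"``
is accepted as a count-matched approximation (same Poisson crossover count,
uniform positions); it does not model interference and is provided only so
configs written for either convention run.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genetic_map import GeneticMap, default_rice_map
from .genotypes import GenotypeMatrix
from .segment_calling import Segment, call_segments, merge_intervals, union_length

logger = logging.getLogger(__name__)

RECURRENT, DONOR = 0, 1

# A haplotype is (ends, origins): tract i covers (ends[i-1], ends[i]] with
# parental origin origins[i]; ends[-1] equals the chromosome length.
Haplotype = tuple[np.ndarray, np.ndarray]
# An individual maps chromosome label -> (haplotype, haplotype).
Individual = dict[str, tuple[Haplotype, Haplotype]]


def _uniform_hap(length: float, origin: int) -> Haplotype:
    return (np.array([length], dtype=float), np.array([origin], dtype=np.int8))


def founder(gmap: GeneticMap, origin: int) -> Individual:
    return {
        c: (_uniform_hap(l, origin), _uniform_hap(l, origin))
        for c, l in gmap.chromosomes.items()
    }


def f1(gmap: GeneticMap) -> Individual:
    """Donor x recurrent hybrid: one intact haplotype from each parent."""
    return {
        c: (_uniform_hap(l, RECURRENT), _uniform_hap(l, DONOR))
        for c, l in gmap.chromosomes.items()
    }


def origin_at(hap: Haplotype, positions: np.ndarray) -> np.ndarray:
    """Parental origin of ``hap`` at each cM position (tracts closed at ends)."""
    ends, origins = hap
    idx = np.minimum(np.searchsorted(ends, positions, side="left"), len(origins) - 1)
    return origins[idx]


def _copy_region(hap: Haplotype, lo: float, hi: float, out_e: list, out_o: list) -> None:
    ends, origins = hap
    i = int(np.searchsorted(ends, lo, side="right"))
    while i < len(ends) and ends[i] < hi:
        out_e.append(float(ends[i]))
        out_o.append(int(origins[i]))
        i += 1
    if hi > lo:
        idx = min(int(np.searchsorted(ends, hi, side="left")), len(origins) - 1)
        out_e.append(float(hi))
        out_o.append(int(origins[idx]))


def _simplify(ends: list, origins: list) -> Haplotype:
    e_out, o_out = [], []
    for e, o in zip(ends, origins):
        if o_out and o == o_out[-1]:
            e_out[-1] = e
        elif e_out and e == e_out[-1]:
            # zero-length tract of a different origin: ignore
            continue
        else:
            e_out.append(e)
            o_out.append(o)
    return (np.array(e_out, dtype=float), np.array(o_out, dtype=np.int8))


def meiose_chromosome(
    pair: tuple[Haplotype, Haplotype],
    length: float,
    rng: np.random.Generator,
    obligate_chiasma: bool = False,
) -> Haplotype:
    """One recombinant gamete haplotype for a single chromosome."""
    if length <= 0:
        return (np.array([0.0]), pair[0][1][:1].copy())
    n_co = int(rng.poisson(length / 100.0)) if length > 0 else 0
    if obligate_chiasma and length > 0:
        while n_co == 0:
            n_co = int(rng.poisson(length / 100.0))
    xs = np.sort(rng.uniform(0.0, length, size=n_co)) if n_co else np.empty(0)
    cur = int(rng.integers(2))
    ends: list[float] = []
    origins: list[int] = []
    prev = 0.0
    for x in [*xs.tolist(), length]:
        _copy_region(pair[cur], prev, x, ends, origins)
        prev = x
        cur ^= 1
    return _simplify(ends, origins)


def meiose(
    parent: Individual,
    gmap: GeneticMap,
    rng: np.random.Generator,
    map_function: str = "haldane",
    obligate_chiasma: bool = False,
) -> dict[str, Haplotype]:
    """One gamete from ``parent`` (independent assortment across chromosomes)."""
    if map_function not in {"haldane", "kosambi"}:
        raise ValidationError(f"unknown map function {map_function!r}")
    return {
        c: meiose_chromosome(parent[c], l, rng, obligate_chiasma)
        for c, l in gmap.chromosomes.items()
    }


def cross(
    a: Individual, b: Individual, gmap: GeneticMap, rng: np.random.Generator, **kw
) -> Individual:
    ga = meiose(a, gmap, rng, **kw)
    gb = meiose(b, gmap, rng, **kw)
    return {c: (ga[c], gb[c]) for c in gmap.chromosomes}


# -- genome summaries (exact, tract-based) ---------------------------------

def donor_fraction(ind: Individual, gmap: GeneticMap) -> float:
    """Fraction of the diploid genome carrying donor origin."""
    donor = 0.0
    for c in gmap.chromosomes:
        for hap in ind[c]:
            ends, origins = hap
            widths = np.diff(np.concatenate([[0.0], ends]))
            donor += float(widths[origins == DONOR].sum())
    return donor / (2.0 * gmap.total_length_cm)


def heterozygous_fraction(ind: Individual, gmap: GeneticMap) -> float:
    """Fraction of the genome where the two haplotypes differ in origin."""
    het = 0.0
    for c in gmap.chromosomes:
        (ea, oa), (eb, ob) = ind[c]
        cuts = np.union1d(ea, eb)
        ia = np.minimum(np.searchsorted(ea, cuts, side="left"), len(oa) - 1)
        ib = np.minimum(np.searchsorted(eb, cuts, side="left"), len(ob) - 1)
        widths = np.diff(np.concatenate([[0.0], cuts]))
        het += float(widths[oa[ia] != ob[ib]].sum())
    return het / gmap.total_length_cm


def genotype_calls(
    ind: Individual, gmap: GeneticMap, markers: list[str] | None = None
) -> pd.Series:
    """Reduce an individual to marker calls in {R, D, H} (noise-free assay)."""
    out: dict[str, str] = {}
    for c in gmap.chromosomes:
        sub = gmap.markers_on(c)
        if markers is not None:
            sub = sub[sub["marker"].isin(markers)]
        if sub.empty:
            continue
        pos = sub["cm"].to_numpy(dtype=float)
        a = origin_at(ind[c][0], pos)
        b = origin_at(ind[c][1], pos)
        tot = a.astype(int) + b.astype(int)
        codes = np.where(tot == 2, "D", np.where(tot == 0, "R", "H"))
        out.update(zip(sub["marker"], codes))
    order = markers if markers is not None else gmap.marker_ids
    return pd.Series([out[m] for m in order], index=order, dtype=object)


def genotype_matrix(
    individuals: dict[str, Individual], gmap: GeneticMap
) -> GenotypeMatrix:
    calls = pd.DataFrame(
        {lid: genotype_calls(ind, gmap) for lid, ind in individuals.items()}
    ).T
    calls.index.name = "line"
    return GenotypeMatrix(map=gmap, calls=calls)


def marker_subset(gmap: GeneticMap, target: int) -> list[str]:
    """Evenly thinned marker panel of ``target`` markers (quota per chromosome
    by largest remainder, evenly spaced indices within each chromosome)."""
    counts = {c: len(gmap.markers_on(c)) for c in gmap.chromosomes}
    total = sum(counts.values())
    if target >= total:
        return gmap.marker_ids
    quota = {c: target * n / total for c, n in counts.items()}
    base = {c: int(np.floor(q)) for c, q in quota.items()}
    short = target - sum(base.values())
    for c in sorted(quota, key=lambda c: quota[c] - base[c], reverse=True)[:short]:
        base[c] += 1
    chosen: list[str] = []
    for c in gmap.chromosomes:
        ids = gmap.markers_on(c)["marker"].tolist()
        k = min(base[c], len(ids))
        if k == 0:
            continue
        idx = np.unique(np.round(np.linspace(0, len(ids) - 1, k)).astype(int))
        chosen.extend(ids[i] for i in idx)
    return chosen


# -- marker-assisted selection ---------------------------------------------

@dataclass(frozen=True)
class MASRule:
    """Two-stage selection rule: eligibility by segment count, then greedy
    maximum-coverage ranking.

    ``max_segments`` is exclusive ("fewer than k substituted segments");
    heterozygous segments count toward it when ``count_het`` (the usual
    reading).  Among eligible plants, selection repeatedly takes the plant
    whose donor segments add the most new cM to the running union of selected
    donor material, breaking ties by lowest line id, until ``target`` plants
    are chosen.
    """

    max_segments: int = 3
    target: int | None = None
    count_het: bool = True


def mas_select(matrix: GenotypeMatrix, rule: MASRule) -> list[str]:
    segments = call_segments(matrix)
    by_line: dict[str, list[Segment]] = {lid: [] for lid in matrix.line_ids}
    for s in segments:
        by_line[s.line].append(s)

    def n_counted(segs: list[Segment]) -> int:
        if rule.count_het:
            return len(segs)
        return sum(s.zygosity == "homozygous" for s in segs)

    eligible = [lid for lid in matrix.line_ids if n_counted(by_line[lid]) < rule.max_segments]
    target = rule.target if rule.target is not None else len(eligible)
    if len(eligible) < target:
        logger.warning(
            "MAS selection infeasible: %d eligible plants for target %d; selecting all",
            len(eligible), target,
        )
        return sorted(eligible)

    union: dict[str, list[tuple[float, float]]] = {}
    union_len: dict[str, float] = {}

    def gain(lid: str) -> float:
        g = 0.0
        per_chrom: dict[str, list[tuple[float, float]]] = {}
        for s in by_line[lid]:
            per_chrom.setdefault(s.chromosome, []).append((s.start_cm, s.end_cm))
        for c, ivs in per_chrom.items():
            cur = union.get(c, [])
            g += union_length(cur + ivs) - union_len.get(c, 0.0)
        return g

    # lazy greedy: cached gains only shrink as the union grows (submodularity)
    heap = [(-gain(lid), lid) for lid in eligible]
    heapq.heapify(heap)
    selected: list[str] = []
    while heap and len(selected) < target:
        neg_g, lid = heapq.heappop(heap)
        g = gain(lid)
        # re-queue unless still ahead of the next candidate (ties: lowest id)
        if heap and (-g, lid) > heap[0]:
            heapq.heappush(heap, (-g, lid))
            continue
        selected.append(lid)
        for s in by_line[lid]:
            merged = merge_intervals(union.get(s.chromosome, []) + [(s.start_cm, s.end_cm)])
            union[s.chromosome] = merged
            union_len[s.chromosome] = sum(hi - lo for lo, hi in merged)
    return selected


# -- the crossing scheme ----------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the simulated breeding programme.

    Defaults reproduce the published scheme this package models: 176 BC1F1
    plants, three unselected backcross generations, ~1,000 BC3F1 plants
    genotyped with a 230-marker panel from which 236 are selected, 376 plants
    per subsequent backcross generation genotyped with the full 313-marker
    map, branch selections of 58/65/43/32 lines at BC4F1..BC7F1 under the
    "fewer than three substituted segments" rule, and selfing to BC4F5 /
    BC5-7F4.  Population sizes the source programme did not report (BC2F1,
    BC5-7F1) default to 400 and 376.
    """

    map: GeneticMap = field(default_factory=default_rice_map)
    map_function: str = "haldane"
    seed: int = 0
    n_bc1: int = 176
    n_bc2: int = 400
    n_bc3: int = 1000
    bc3_marker_count: int = 230
    bc3_rule: MASRule = field(default_factory=lambda: MASRule(max_segments=4, target=236))
    branch_sizes: dict[int, int] = field(default_factory=lambda: {4: 376, 5: 376, 6: 376, 7: 376})
    branch_rules: dict[int, MASRule] = field(
        default_factory=lambda: {
            4: MASRule(max_segments=3, target=58),
            5: MASRule(max_segments=3, target=65),
            6: MASRule(max_segments=3, target=43),
            7: MASRule(max_segments=3, target=32),
        }
    )
    selfing_generations: dict[int, int] = field(
        default_factory=lambda: {4: 4, 5: 3, 6: 3, 7: 3}
    )
    n_self_progeny: int = 8
    obligate_chiasma: bool = False

    def __post_init__(self) -> None:
        for name in ("n_bc1", "n_bc2", "n_bc3"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        """Build a config from plain YAML/JSON data, coercing nested rules."""
        raw = dict(raw)
        if isinstance(raw.get("bc3_rule"), dict):
            raw["bc3_rule"] = MASRule(**raw["bc3_rule"])
        for key in ("branch_sizes", "selfing_generations"):
            if key in raw:
                raw[key] = {int(k): int(v) for k, v in raw[key].items()}
        if "branch_rules" in raw:
            raw["branch_rules"] = {
                int(k): (MASRule(**v) if isinstance(v, dict) else v)
                for k, v in raw["branch_rules"].items()
            }
        return cls(**raw)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stage])


def _self_to_fixation(
    ind: Individual,
    gmap: GeneticMap,
    generations: int,
    n_progeny: int,
    rng: np.random.Generator,
    map_function: str,
) -> Individual:
    """Self for ``generations`` generations, fixing the donor segments.

    Each generation keeps the offspring that (1) lost donor alleles at the
    fewest markers where the current plant carries donor material and (2) has
    the fewest remaining heterozygous calls — i.e. homozygosity selection at
    the target segments, degrading to single-seed descent when no offspring
    improves."""
    cur = ind
    for _ in range(generations):
        target = genotype_calls(cur, gmap).isin(["D", "H"]).to_numpy()
        best = None
        best_key = None
        for _ in range(n_progeny):
            off = cross(cur, cur, gmap, rng, map_function=map_function)
            calls = genotype_calls(off, gmap).to_numpy()
            lost = int((calls[target] == "R").sum())
            key = (lost, int((calls == "H").sum()))
            if best_key is None or key < best_key:
                best, best_key = off, key
        cur = best
    return cur


def run_scheme(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Execute the full crossing scheme; returns the final line set and a
    pedigree log (one row per generation/selection event).

    Deterministic for a given config: every stage draws from its own child
    stream of the master seed, so identical config + seed gives identical
    output.
    """
    gmap = config.map
    mf = config.map_function
    rec = founder(gmap, RECURRENT)
    ped_rows = []

    def log(stage: str, n_in: int, n_out: int, note: str) -> None:
        ped_rows.append({"stage": stage, "n_candidates": n_in, "n_selected": n_out, "note": note})

    hybrid = f1(gmap)
    log("F1", 1, 1, "donor x recurrent")

    rng = _stage_rng(config.seed, 1)
    bc1 = [cross(hybrid, rec, gmap, rng, map_function=mf,
                 obligate_chiasma=config.obligate_chiasma) for _ in range(config.n_bc1)]
    log("BC1F1", 1, config.n_bc1, "backcross, no selection")

    rng = _stage_rng(config.seed, 2)
    bc2 = [cross(bc1[int(rng.integers(len(bc1)))], rec, gmap, rng, map_function=mf,
                 obligate_chiasma=config.obligate_chiasma) for _ in range(config.n_bc2)]
    log("BC2F1", config.n_bc1, config.n_bc2, "backcross, no selection")

    rng = _stage_rng(config.seed, 3)
    bc3 = [cross(bc2[int(rng.integers(len(bc2)))], rec, gmap, rng, map_function=mf,
                 obligate_chiasma=config.obligate_chiasma) for _ in range(config.n_bc3)]
    log("BC3F1", config.n_bc2, config.n_bc3, "backcross, no selection")

    # genotype BC3F1 with the reduced panel and select carriers of few segments
    panel = marker_subset(gmap, config.bc3_marker_count)
    panel_map = GeneticMap.from_dataframe(
        gmap.table[gmap.table["marker"].isin(panel)], lengths=gmap.chromosomes
    )
    bc3_named = {f"BC3_{i:04d}": ind for i, ind in enumerate(bc3)}
    bc3_matrix = genotype_matrix(bc3_named, panel_map)
    selected_ids = mas_select(bc3_matrix, config.bc3_rule)
    parents = [bc3_named[lid] for lid in selected_ids]
    log("BC3F1-MAS", config.n_bc3, len(parents),
        f"<{config.bc3_rule.max_segments} segments on {len(panel)}-marker panel, greedy coverage")

    lines: dict[str, Individual] = {}
    line_no = 0
    for gen in sorted(config.branch_sizes):
        rng = _stage_rng(config.seed, 10 + gen)
        size = config.branch_sizes[gen]
        pop = [cross(parents[int(rng.integers(len(parents)))], rec, gmap, rng,
                     map_function=mf, obligate_chiasma=config.obligate_chiasma)
               for _ in range(size)]
        log(f"BC{gen}F1", len(parents), size, "backcross of selected plants")

        named = {f"BC{gen}_{i:04d}": ind for i, ind in enumerate(pop)}
        gmat = genotype_matrix(named, gmap)
        rule = config.branch_rules[gen]
        chosen = mas_select(gmat, rule)
        log(f"BC{gen}F1-MAS", size, len(chosen),
            f"<{rule.max_segments} segments on full map, greedy coverage")

        rng_self = _stage_rng(config.seed, 20 + gen)
        n_self = config.selfing_generations.get(gen, 3)
        for lid in chosen:
            fixed = _self_to_fixation(named[lid], gmap, n_self,
                                      config.n_self_progeny, rng_self, mf)
            line_no += 1
            lines[f"CSSL{line_no:03d}"] = fixed
        log(f"BC{gen}F{n_self + 1}", len(chosen), len(chosen),
            f"{n_self} selfing generations with homozygosity selection")
        parents = [named[lid] for lid in chosen]

    final = genotype_matrix(lines, gmap)
    pedigree = pd.DataFrame(ped_rows)
    return final, pedigree


# -- phenotype generation ----------------------------------------------------

@dataclass(frozen=True)
class TraitModel:
    """Additive QTL model for one trait.

    Phenotype of line *i* at site *s*, replicate *r*:

        y = intercept_s + sum_q a_q * x_iq + e,   e ~ N(0, sd_s^2)

    with x coded +1 for donor homozygote, 0 for heterozygote, -1 for
    recurrent homozygote at each QTL marker, so ``a`` is the conventional
    additive effect (half the D-R homozygote difference).
    """

    name: str
    qtls: tuple[tuple[str, float], ...]
    intercept: float | dict[str, float] = 0.0
    residual_sd: float | dict[str, float] = 1.0

    def intercept_at(self, site: str) -> float:
        return self.intercept[site] if isinstance(self.intercept, dict) else self.intercept

    def sd_at(self, site: str) -> float:
        return self.residual_sd[site] if isinstance(self.residual_sd, dict) else self.residual_sd


_X_CODE = {"D": 1.0, "H": 0.0, "R": -1.0}


def simulate_phenotypes(
    matrix: GenotypeMatrix,
    models: list[TraitModel],
    sites: list[str],
    rng: np.random.Generator,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Long-format phenotype table: ``line, site, replicate, trait, value``."""
    marker_set = set(matrix.map.marker_ids)
    for m in models:
        unknown = [q for q, _ in m.qtls if q not in marker_set]
        if unknown:
            raise ValidationError(f"trait {m.name!r} references unknown marker(s): {unknown}")
    rows = []
    for model in models:
        genetic = np.zeros(matrix.n_lines)
        for marker, a in model.qtls:
            calls = matrix.calls[marker]
            if calls.isin(["U", "N"]).any():
                logger.warning(
                    "U/N calls at QTL marker %s contribute 0 to trait %s",
                    marker, model.name,
                )
            genetic += a * calls.map(_X_CODE).fillna(0.0).to_numpy()
        for site in sites:
            mu = model.intercept_at(site) + genetic
            sd = model.sd_at(site)
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, sd, size=matrix.n_lines) if sd > 0 else 0.0
                vals = mu + noise
                rows.extend(
                    {"line": lid, "site": site, "replicate": rep,
                     "trait": model.name, "value": float(v)}
                    for lid, v in zip(matrix.line_ids, vals)
                )
    return pd.DataFrame(rows, columns=["line", "site", "replicate", "trait", "value"])
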