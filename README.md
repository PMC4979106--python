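# csslkit

Analysis toolkit for **chromosome segment substitution line (CSSL)
populations** — line sets that carry one or a few donor chromosome segments
(for example from wild rice, *Oryza rufipogon*) in an otherwise uniform
recurrent-parent background (for example the *indica* cultivar 9311).  CSSLs
are the workhorse material for fine mapping quantitative trait loci (QTLs)
and for moving wild alleles into elite cultivars, and their analysis follows
a standard pipeline that this package implements end to end:

1. **Genetic maps** (`csslkit.genetic_map`) — load/validate marker maps,
   per-chromosome spacing statistics.  Mean spacing follows the framework-map
   convention *length / marker count* (202.3 cM with 36 markers → 5.62 cM).
2. **Genotype matrices** (`csslkit.genotypes`) — lines × markers calls over
   the five-state alphabet `R` (recurrent homozygote), `D` (donor
   homozygote), `H` (heterozygote), `N` (non-parental), `U` (missing), plus
   graphical-genotype block rendering.
3. **Segment calling** (`csslkit.segment_calling`) — donor introgression
   segments by the graphical-genotype length rule: an inter-marker interval
   flanked by two donor markers (DD) counts 100 % donor, a donor/recurrent
   (DR) interval counts 50 %, so a segment's estimated length is its DD span
   plus two half flanking DR gaps.  Population summaries: per-chromosome
   effective coverage (union of donor segments across lines), segment-length
   histograms, per-line summaries and NIL (single-segment line) status.
4. **Breeding simulation** (`csslkit.breeding_sim`) — a tract-based forward
   simulator of the crossing scheme that produces CSSLs (F1 → three
   unselected backcrosses → marker-assisted selection on segment count →
   further backcross branches → selfing to fixation), with Haldane meiosis
   (Poisson crossovers, mean length/100), exact donor-fraction bookkeeping,
   and additive-QTL phenotype generation.
5. **QTL scanning** (`csslkit.qtl_scan`) — single-marker one-way ANOVA per
   trait and site; per marker the F-test p-value, PVE = 100 · SS_between /
   SS_total, and the additive effect Add = (mean_D − mean_R)/2; clustering of
   significant markers into named QTLs (`qDTH10-1` style) with a two-site
   consistency flag; Welch t-tests against the recurrent parent; trait
   correlation matrices.
6. **Fine mapping** (`csslkit.fine_mapping`) — on a dense bp-anchored
   matrix, the shared donor region across phenotype-sharing lines is the
   intersection of their donor intervals.
7. **Pipeline & CLI** (`csslkit.pipeline`, `csslkit.cli`) — a `csslkit`
   command with `map-stats`, `plot-genotypes`, `call-segments`, `summarize`,
   `simulate`, `scan`, `finemap` and `run` subcommands over TSV files, plus
   a YAML-configured end-to-end run with a JSON manifest.

The `examples/` directory has one short narrative script per capability.

## Worked example

```python
import pandas as pd
import csslkit as ck

gmap = ck.GeneticMap.from_dataframe(
    pd.DataFrame({"marker": ["m1", "m2", "m3", "m4", "m5"],
                  "chromosome": "1",
                  "cm": [5.0, 10.0, 15.0, 20.0, 28.0]}),
    lengths={"1": 30.0})
matrix = ck.GenotypeMatrix(map=gmap, calls=pd.DataFrame(
    {"m1": ["R", "R"], "m2": ["D", "H"], "m3": ["D", "R"],
     "m4": ["D", "R"], "m5": ["R", "R"]},
    index=["CSSL_A", "CSSL_B"]))

segments = ck.call_segments(matrix)
print(ck.segments_to_frame(segments).to_string(index=False))
```

prints

```
  line chromosome  start_cM  end_cM     zygosity  length_cM  markers
CSSL_A          1       7.5    24.0   homozygous       16.5 m2,m3,m4
CSSL_B          1       7.5    12.5 heterozygous        5.0       m2
```

CSSL_A's donor run spans markers at 10–20 cM; adding half of the 5 cM gap to
m1 and half of the 8 cM gap to m5 gives the interval [7.5, 24.0] and the
estimated length 16.5 cM = (20 − 10) + 5/2 + 8/2.  CSSL_B carries a single
heterozygous marker, so its segment is the two half-gaps around m2.
`ck.coverage_report(segments, gmap)` then reports the union of both lines'
segments — 16.5 cM of the 30 cM chromosome, 55.0 % coverage — and
`ck.line_summaries` flags both lines as NILs (one segment each).

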