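# Methods

This note documents the models, conventions and design choices behind
csslkit, in the order the pipeline uses them.

## Coordinates and call alphabet

Genetic positions are distances in centimorgans (cM) from the chromosome
top; cM intervals are closed.  Physical positions are 1-based inclusive bp.
Chromosome labels are strings, with `Chr.1`/`chr1` dialects normalised to
`"1"`.  Genotype calls use a closed five-letter alphabet: `R` (recurrent
homozygote), `D` (donor homozygote), `H` (heterozygote), `N` (non-parental
allele), `U` (missing).  `N` and `U` are never counted as donor material
anywhere: `N` breaks donor runs exactly like `R`, while `U` is transparent
(see below).  Alternative file dialects (A/B/H) are handled by a symbol map
on load.

## Marker-spacing statistics

Mean marker spacing per chromosome is **chromosome length divided by marker
count**, not by the number of adjacent intervals.  This is the convention
CSSL framework-map tables print (202.3 cM with 36 markers reads 5.62 cM, and
1782 cM over 313 markers reads 5.69 ≈ 5.7 cM) and it differs from the usual
mean adjacent gap; the adjacent-gap minimum and maximum are reported
separately.  Chromosome lengths default to the last marker position and are
normally overridden by an explicit lengths table, since framework maps
extend beyond the last polymorphic marker.  Co-located markers are legal
(SSR maps contain 0.1 cM gaps and exact ties); ties sort by marker id with a
logged warning.

## Segment calling

The length rule is the standard graphical-genotype estimate for substitution
lines: an inter-marker interval flanked by two donor-type markers (DD)
counts as 100 % donor, one flanked by a donor and a recurrent marker (DR) as
50 %, and an RR interval as 0 %.  A maximal run of consecutive same-state
donor markers (`D` or `H`) therefore becomes one segment on

    [first_run_marker − gap_left / 2,  last_run_marker + gap_right / 2]

with gaps measured to the nearest *informative* marker.  Conventions the
rule itself leaves open, and how this package resolves them:

* **Chromosome ends.** A run containing the first (last) informative marker
  extends to the terminus on that side, because no recombination evidence
  bounds it there.  `end_extension="marker"` stops at the marker instead.
* **Missing data.** `U` calls are transparent: a donor run continues across
  them and flanking gaps are measured to the nearest informative marker.
  This matches graphical-genotype practice and avoids splitting a segment at
  a failed assay.  (The graphical-genotype *renderer* instead emits explicit
  `unknown` blocks for `U` runs — a presentation choice so missing data
  stays visible in figures; segment statistics never use those blocks.)
* **Zygosity.** Homozygous (`D`) and heterozygous (`H`) runs are never
  merged; where they abut, the boundary is the midpoint between the adjacent
  `D` and `H` markers.
* **Degenerate runs.** A zero-length segment (all defining positions
  coincide) is dropped with a warning.

Every inter-marker interval interpretation is covered by an independent
brute-force classifier in the test suite; the two implementations agree
exactly on thousands of random matrices.

Population summaries: *effective coverage* per chromosome is the length of
the union, across lines, of all donor segments (het + homo) — the donor
genome represented by at least one line; *coverage percent* divides by the
chromosome's genetic length.  Per-line summaries count segments, flag NILs
(exactly one segment), and report background recovery as
100 × (1 − donor cM fraction), where heterozygous length is weighted one
half (one donor haplotype); total introgression length counts both
zygosities at full length.  The segment-length histogram uses half-open bins
[lo, hi) with default edges 0, 5, 10, 20, ∞ cM.  Reports round cM to one
decimal place.

## Breeding simulator

Genomes are **recombination-tract lists** per chromosome — breakpoints in cM
with parental origin — so donor fraction and heterozygosity are computed
exactly from tract lengths rather than sampled at markers.

**Meiosis** follows the Haldane model: crossover count per chromosome is
Poisson with mean length/100, positions uniform, no interference, with free
recombination between chromosomes.  This makes the expected donor fraction
after *n* backcrosses exactly (1/2)^(n+1) — 6.25 % at BC3F1, all
heterozygous — which the calibration tests assert to 3 standard errors.
Obligate chiasma is off by default (zero-crossover meioses occur, as the
pure Poisson model implies); a flag forces at least one crossover.
`map_function="kosambi"` is accepted as a count-matched approximation (the
same Poisson count and uniform positions); it does **not** model
interference and exists so configs written for either convention run — the
caveat applies wherever interference would matter.

**Crossing scheme** (defaults; all sizes configurable): an F1 between donor
and recurrent founders; 176 BC1F1 plants; unselected backcrosses to ~400
BC2F1 and 1,000 BC3F1; BC3F1 genotyped with a 230-marker panel (per-
chromosome quotas by largest remainder, evenly spaced within chromosomes)
and subjected to marker-assisted selection; then backcross branches of 376
plants at BC4F1..BC7F1 genotyped with the full 313-marker map, selecting
58/65/43/32 lines under the "fewer than three substituted segments" rule and
selfing them (four generations for the first branch, three for the rest) to
give 198 lines.  Sizes the source programme did not publish (BC2F1 and the
BC5–7 F1 populations) default to 400 and 376; the MAS-selected plants of
each generation parent the next backcross, since they carry the target
segments.

**Marker-assisted selection** is a two-stage rule.  Stage one is the
eligibility filter the breeding literature states: fewer than *k* donor
segments (k = 3 at BC4 onward, exclusive; heterozygous segments count by
default).  Stage two — how to pick among eligible plants — is this package's
choice: greedy maximum coverage, repeatedly taking the plant whose donor
segments add the most new cM to the running union of selected donor
material (ties to the lowest line id), implemented as a lazy-heap greedy
(valid because marginal coverage gain is submodular).  At BC3F1, where the
selection criterion is unstated, the same rule runs with threshold 4; in
simulated populations far fewer than 236 BC3F1 plants meet that threshold,
in which case all qualifying plants are selected with a logged warning — the
documented behaviour for infeasible selections.

**Selfing to fixation**: each generation, `n_self_progeny` (default 8)
selfed offspring are scored by (markers where donor material was lost,
remaining heterozygous calls), and the lexicographic minimum is kept —
homozygosity selection that fixes rather than discards the target segments,
degrading to single-seed descent when no offspring improves.

**Phenotypes** are additive: y = site intercept + Σ a·x + ε with x coded
+1/0/−1 for D/H/R at each QTL marker and ε ~ N(0, site SD²); `U`/`N` at a
QTL marker contribute 0 with a warning.  No dominance, epistasis or G×E
beyond the per-site intercept; no gametophytic selection, hybrid sterility
or segregation distortion (real interspecific populations show all three, so
simulated coverage gaps are purely sampling effects).

**Reproducibility**: one master seed; each stage draws from its own child
stream (`default_rng([seed, stage])`), so identical config + seed gives
byte-identical output.

### What the simulator does and does not emulate

The generator reproduces the published scheme's population sizes, marker
geometry (12 chromosomes, 1782 cM, 313 markers at the published
per-chromosome counts — placed uniformly, as the real positions are not
published), backcross/MAS/selfing structure, and additive effect sizes of
the reported magnitude (e.g. 21.2 days for a heading-date QTL).  It does not
reproduce the real population's segment-length distribution (simulated lines
carry fewer, longer segments than the published 2.16 segments/line averaging
~6 cM, because the real programme's unstated BC3 selection and larger
effective parent pool cannot be recovered from the publication), nor marker
ascertainment, genotyping error, or the biological transmission distortions
above.  Passing tests therefore demonstrate correctness of the algorithms
and calibration of the statistics under a faithful model of the *design*,
not recovery of the published population's exact summary numbers.

## QTL scan

The analysis unit is the line mean across replicates — the plot-design
convention for substitution-line trials; replicate-level mixed models are
out of scope.  Per marker, a one-way ANOVA of line means on genotype group:
`R` vs `D`, with `H` as a third group when at least `min_group` (default 3)
lines carry it; groups below the minimum are excluded, and markers with
fewer than two usable groups are skipped.  Reported: the F-test p-value
(clipped below at 1e-300 so p > 0 always holds; a constant phenotype gives
p = 1, PVE = 0), PVE = 100 · SS_between/SS_total (the R² of the one-marker
model — single-point analysis, not a simultaneous multi-QTL fit), and
Add = (mean_D − mean_R)/2, the substitution-line convention in which a
negative value means the donor allele decreases the trait.  No
multiple-testing correction by default, matching the fixed P < 0.01
single-point convention; Bonferroni is available.

QTL declaration clusters significant markers per trait and chromosome:
consecutive significant markers within 20 cM (configurable; the sources
report only nearest markers, so the window is this package's choice)
collapse to one QTL at the most significant marker, named
`q` + trait code + chromosome + `-` + index in cM order (`qDTH10-1`).  A QTL
is consistent across sites when every scanned site is significant somewhere
in the cluster; effect-direction agreement is reported alongside.

Comparisons of individual lines against the recurrent parent use Welch's
two-sample t-test on replicate values (pooled-variance optional).  Trait
correlations are Pearson on line means, pairwise-complete, with 0.05/0.01
significance flags.

## Fine mapping

On a dense bp-anchored matrix, each line's donor intervals use the same
midpoint convention as cM segment calling, clipped to the assayed marker
range (never extrapolated beyond the first/last marker — the chip defines
the observable window).  The candidate region for a phenotype shared by *k*
lines is the set-intersection of their donor interval lists; only homozygous
donor calls count by default (fixed lines), with a flag to include
heterozygotes.  Intersection is order-independent and monotone (adding a
line never enlarges the region); an empty result is legal and a line with no
donor material on the chromosome yields an empty intersection with a
warning.  `refine_qtl` reports the interval length (kb) and overlap with
supplied BED-like annotations, flagging the region novel when none overlap.

## Numerical and testing choices

Interval unions/intersections are computed on sorted endpoint lists with
exact float comparisons; segment boundaries are midpoints of input
positions, so no tolerance accumulates.  Statistical tests use scipy
(F, t, Pearson).  Calibration tests run at sizes chosen to make 3-standard-
error bands tight while keeping the suite fast: 5,000 simulated BC3F1 plants
for Mendelian expectations, 10,000 meioses for the Poisson crossover mean,
100 phenotype replicates on a 198-line population for effect recovery
(the crossing scheme is simulated once and phenotype noise is replicated —
the standard parameter-recovery design), and 200 null scans pooled (~48,000
marker tests) for the type-I error band.  Within a scan, neighbouring
markers share donor lines, so per-scan false-positive counts are
over-dispersed relative to binomial; the marginal rate is still 0.01 and the
pooled check uses the binomial band, with the inflation visible (not
asserted) in per-scan variances.

## Known limitations

* The length rule estimates segment ends at inter-marker midpoints; true
  recombination breakpoints within a gap are unknowable from marker data, so
  segment lengths carry half-gap uncertainty on each side.
* The Kosambi option does not model interference (count-matched only).
* The simulator's MAS at BC3F1 uses an assumed threshold (4) for an
  unpublished criterion; simulated populations select fewer plants there
  than the real programme did.
* QTL scanning is single-point: no interval mapping, no composite methods,
  and linked QTLs within a clustering window merge.
* Physical-coordinate export maps a segment to its supporting-marker span
  only; cM↔bp interpolation is out of scope.
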