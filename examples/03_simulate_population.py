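"""Simulating a small CSSL breeding programme.

Runs a down-scaled version of the backcross / marker-assisted selection /
selfing scheme (the full-scale defaults take ~half a minute) and summarises
the resulting line set: segment counts, donor-genome coverage, and the
segment-length histogram.
"""

import csslkit as ck
from csslkit import breeding_sim as bs

config = bs.SimConfig(
    seed=7,
    n_bc1=30, n_bc2=60, n_bc3=150,
    bc3_rule=bs.MASRule(max_segments=5, target=40),
    branch_sizes={4: 80, 5: 80},
    branch_rules={4: bs.MASRule(max_segments=3, target=15),
                  5: bs.MASRule(max_segments=3, target=15)},
    selfing_generations={4: 3, 5: 3},
)
matrix, pedigree = bs.run_scheme(config)
print("Pedigree of the simulated programme:")
print(pedigree.to_string(index=False))

segments = ck.call_segments(matrix)
cov = ck.coverage_report(segments, config.map)
summ = ck.line_summaries(segments, matrix)
print(
    f"\n{matrix.n_lines} lines; {cov.totals['n_segments']} donor segments "
    f"({cov.totals['n_homozygous']} homozygous, {cov.totals['n_heterozygous']} het); "
    f"mean {summ['n_segments'].mean():.2f} segments/line; "
    f"{int(summ['is_NIL'].sum())} NILs."
)
print(
    f"Donor genome covered by at least one line: "
    f"{cov.totals['effective_coverage_cM']:.0f} cM "
    f"({cov.totals['coverage_percent']:.1f} % of the {config.map.total_length_cm:.0f} cM map)."
)
print("\nSegment-length histogram (<5, 5-10, 10-20, >20 cM):")
print(ck.length_histogram(segments).round(1).to_string(index=False))
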