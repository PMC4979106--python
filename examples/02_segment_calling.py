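"""Calling donor introgression segments from a toy genotype matrix.

A segment's estimated length is the span flanked by donor-type markers (DD,
100 % donor) plus half of each flanking donor/recurrent (DR) interval.  The
line below carries donor homozygote calls at 10-20 cM with recurrent
neighbours at 5 and 28 cM, so the segment is [7.5, 24.0] = 16.5 cM.
"""

import pandas as pd

import csslkit as ck

gmap = ck.GeneticMap.from_dataframe(
    pd.DataFrame(
        {
            "marker": ["m1", "m2", "m3", "m4", "m5"],
            "chromosome": "1",
            "cm": [5.0, 10.0, 15.0, 20.0, 28.0],
        }
    ),
    lengths={"1": 30.0},
)
matrix = ck.GenotypeMatrix(
    map=gmap,
    calls=pd.DataFrame(
        {"m1": ["R", "R"], "m2": ["D", "H"], "m3": ["D", "R"],
         "m4": ["D", "R"], "m5": ["R", "R"]},
        index=["CSSL_A", "CSSL_B"],
    ),
)

segments = ck.call_segments(matrix)
print(ck.segments_to_frame(segments).to_string(index=False))

cov = ck.coverage_report(segments, gmap)
print("\nPer-chromosome coverage (union across lines):")
print(cov.rounded().to_string(index=False))
print("\nLine summaries (a single-segment line is a NIL):")
print(ck.line_summaries(segments, matrix).round(1).to_string(index=False))
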