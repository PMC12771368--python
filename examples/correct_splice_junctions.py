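"""Correct noisy alignment gaps against a short-read junction reference.

Long-read alignments misplace splice gaps by a few bases.  Gaps whose two
boundaries both lie within 10 bp of the same reference intron are snapped to
it; gaps matching nothing are treated as spurious deletions and removed.
The reference keeps only junctions seen in two or more samples.
"""

import pandas as pd

from isopeak import GenomicInterval, JunctionSet, correct_introns, extract_introns

# junction table as parsed from STAR SJ.out.tab files of two samples
table = pd.DataFrame(
    [("chr1", 1000, 1200, "+", "leaf_1"),
     ("chr1", 1000, 1200, "+", "leaf_2"),      # supported twice -> kept
     ("chr1", 5000, 5400, "+", "leaf_1")],     # one sample -> discarded
    columns=["chrom", "start", "end", "strand", "sample"])
ref = JunctionSet.from_table(table, min_samples=2)
print(f"reference junctions kept: {len(ref)} of "
      f"{len(table.groupby(['chrom', 'start', 'end']))}")

# introns come from the N operations of a read's CIGAR string
chain = extract_introns("200M197N300M", pos=803, chrom="chr1", strand="+")
print("raw gap:", [(i.start, i.end) for i in chain])

corrected, stats = correct_introns(chain, ref, tolerance=10)
print("corrected:", [(i.start, i.end) for i in corrected], stats)

# a gap near the unsupported junction has no admissible candidate
orphan = [GenomicInterval("chr1", 5003, 5398, "+")]
removed, stats = correct_introns(orphan, ref, tolerance=10)
print("orphan gap ->", removed, stats)
# The 1003-1200 gap snaps to the supported intron 1000-1200; the gap near
# the single-sample junction is removed from the read's description.
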