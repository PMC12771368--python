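"""Call TSS peaks from read 5' ends with replicate support filtering.

Three replicates place read 5' ends around two alternative start sites.
Positions covered in fewer than two replicates are discarded, the rest are
pooled and clustered: candidate positions (pooled count > 2) closer than
10 bp of gap join one peak, whose summit is the pooled maximum.
"""

from isopeak import GenomicInterval
from isopeak.end_peaks import FIVE_PRIME, call_all_peaks
from isopeak.preprocess import AlignedRead


def read(rep, start, rid):
    return AlignedRead(rid, rep, GenomicInterval("chr1", start, start + 900, "+"))


reads = {
    "rep1": [read("rep1", 100, f"a{i}") for i in range(4)]
            + [read("rep1", 103, "a4")]
            + [read("rep1", 160, f"b{i}") for i in range(3)]
            + [read("rep1", 400, "noise1")],          # rep1-only position
    "rep2": [read("rep2", 100, f"c{i}") for i in range(3)]
            + [read("rep2", 161, f"d{i}") for i in range(2)],
    "rep3": [read("rep3", 101, "e0"), read("rep3", 160, "f0")],
}

peaks = call_all_peaks(reads, support_min_replicates=2, pooled_cutoff=2,
                       merge_dist=10)
for p in peaks[("chr1", "+", FIVE_PRIME)]:
    print(f"peak {p.region.start}-{p.region.end} summit={p.summit} "
          f"pooled={p.pooled_count} per-replicate={p.per_replicate}")
# Two peaks emerge, one per alternative TSS.  Positions seen in a single
# replicate (400, but also 103 and 161) never enter the pooled track, which
# is why the second peak is the single position 160 with pooled count 4.
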