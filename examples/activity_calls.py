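"""Chromatin-state and upstream-regulation activity calls for one locus.

The chromatin classifier compares normalized segmentation-label
frequencies: TSS >= 3x every repressive label (criterion 1) or all of
GS/GM/GE >= 2x (criterion 2).  Pol2 activity needs one peak both wider
than 519 bp and stronger than signal 2.38, or any of the seven cofactors
bound in the 2 kb upstream window.
"""

from psidr import (
    GenomicInterval,
    Peak,
    PseudogeneRecord,
    call_active_chromatin,
    call_pol2_active,
    count_tfbs,
    upstream_window,
)
from psidr.datamodel import SEGMENTATION_LABELS

freqs = {lab: 0.0 for lab in SEGMENTATION_LABELS}
freqs.update({"TSS": 0.30, "CTCF": 0.09, "LOW": 0.05})
active, crit = call_active_chromatin(freqs)
print(f"chromatin: active={active} via criterion {crit}")
# TSS at 0.30 is >= 3 x 0.09 (the strongest repressive label): criterion 1.

pg = PseudogeneRecord("PG1", GenomicInterval("chr1", 50_000, 52_500, "+"))
window = upstream_window(pg)
print(f"upstream window: {window.region.chrom}:{window.region.start}-{window.region.end}")

pol2 = [Peak(GenomicInterval("chr1", 48_500, 49_100), "Pol2", 3.1)]
cofactors = [Peak(GenomicInterval("chr1", 48_200, 48_400), "Taf1", 1.2)]
active, crit = call_pol2_active(pol2, cofactors, window)
print(f"Pol2: active={active} via criterion {'1+2' if crit == 12 else crit}")
# The 600 bp peak with signal 3.1 clears both thresholds on its own.

tfs = [
    Peak(GenomicInterval("chr1", 48_100, 48_300), "Myc", 1.0),
    Peak(GenomicInterval("chr1", 49_900, 50_100), "Jun", 1.0),  # only half inside
]
n, factors = count_tfbs(tfs, window)
print(f"TFBS count: {n} ({sorted(factors)})")
# Jun straddles the window edge with exactly half its width inside, so it
# fails the strict majority rule; only Myc counts.
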