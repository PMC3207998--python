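"""Scan a 3'UTR for canonical microRNA seed sites.

A seed site is classified by how the mRNA pairs the miR 5' end:
6mer (perfect match to miR positions 2-7), 7mer-A1 (6mer plus an A opposite
miR position 1), 7mer-m8 (6mer plus a match to miR position 8) and 8mer
(both).  This example builds the four patterns for one miR, plants each in a
toy UTR and recovers them with `scan_utr`.
"""

from seedvar import (
    GenomicPlacement,
    MicroRNA,
    NucleotideSequence,
    build_site_patterns,
    scan_utr,
)

mir = MicroRNA.from_string("mir-ex", "UAGCUUAUCAGACUGAUGUUGA")
patterns = build_site_patterns(mir)
print(f"miR {mir.name}: seed match {patterns.pattern_6mer}, "
      f"8mer site pattern {patterns.pattern_8mer}")

# a UTR carrying one site of each class, separated by T runs
spacer = "T" * 12
utr = NucleotideSequence(
    "utr-ex",
    spacer
    + patterns.pattern_8mer + spacer      # 8mer
    + patterns.pattern_7m8 + "G" + spacer  # 7mer-m8 (non-A at the A1 slot)
    + "G" + patterns.pattern_7a1 + spacer  # 7mer-A1 (mismatch at m8)
    + "G" + patterns.pattern_6mer + "G" + spacer,  # bare 6mer
)
placement = GenomicPlacement("1", 10_000, 10_000 + len(utr), "+")

for hit in scan_utr(utr, [mir], placement=placement):
    print(
        f"{hit.site_type:>8} at UTR {hit.window_start}-{hit.window_end} "
        f"(chr{hit.chrom}:{hit.genomic_start}-{hit.genomic_end} {hit.strand})"
    )
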