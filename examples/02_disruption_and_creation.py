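"""Call SNPs that abolish an existing seed site or create a new one.

A SNP inside a site's 8-position frame is re-classified under both alleles:
the verdict is abolished/downgraded/unchanged/upgraded by comparing the seed
classes.  A SNP outside any site can still *create* a site when its alternate
allele completes a seed match; such candidates are filtered with a proxy
pairing-score/energy duplex scorer.
"""

from seedvar import (
    GenomicPlacement,
    MicroRNA,
    NucleotideSequence,
    build_site_patterns,
    classify_disruption,
    detect_created_sites,
    extract_window,
    scan_utr,
)
from seedvar.seedcore import reverse_complement
from seedvar.variants import SnpRecord

mir = MicroRNA.from_string("mir-ex", "UAGCUUAUCAGACUGAUGUUGA")
patterns = build_site_patterns(mir)

# --- disruption: a seed-position SNP abolishes an 8mer -----------------
utr = NucleotideSequence("utr-ex", "T" * 10 + patterns.pattern_8mer + "T" * 10)
placement = GenomicPlacement("1", 5_000, 5_000 + len(utr), "+")
(site,) = scan_utr(utr, [mir], placement=placement)
g = site.genomic_start + 3  # a seed base (frame position 4 on the mRNA)
snp = SnpRecord("rs_disrupt", "1", g, utr.residues[site.window_start + 2], "G"
                if utr.residues[site.window_start + 2] != "G" else "C")
call = classify_disruption(site, snp, mir, utr)
print(f"{snp.rsid}: {call.ref_class} -> {call.alt_class or 'no site'} "
      f"({call.verdict}), MRE position {call.pos_in_mre}")

# --- creation: the alt allele restores a broken seed -------------------
# embed the full complementary context with one seed base mutated in the ref
target = reverse_complement(mir.sequence.residues[1:]) + "A"
ctx = "T" * 12 + target + "T" * 12
broken_idx = 12 + len(target) - 5  # inside the seed match
ref_seq = ctx[:broken_idx] + ("G" if ctx[broken_idx] != "G" else "C") + ctx[broken_idx + 1 :]
utr2 = NucleotideSequence("utr-cnm", ref_seq)
snp2 = SnpRecord("rs_create", "1", 8_000 + broken_idx + 1,
                 ref_seq[broken_idx], ctx[broken_idx])
placement2 = GenomicPlacement("1", 8_000, 8_000 + len(ref_seq), "+")
window = extract_window(utr2, snp2, placement=placement2)
for hit in detect_created_sites(window, [mir]):
    print(f"{hit.snp.rsid}: creates {hit.site_type} for {hit.mir_name} "
          f"(pairing score {hit.pairing_score:.0f}, energy {hit.energy_proxy:.0f})")
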