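"""SNP ingestion and intersection with seed sites.

A bi-allelic 3'UTR SNP that falls inside the 8-position MRE frame of a
predicted seed site can weaken, abolish, leave unchanged or even strengthen
the site, depending on which frame position it hits and which base the
alternate allele substitutes.  This module locates SNPs within sites, calls
the position-in-MRE, re-classifies the site under each allele and summarises
disruption calls by seed class.

Position-in-MRE numbering follows the miR: MRE position *k* is the mRNA base
pairing miR position *k*, so position 1 is the 3'-most frame base on the mRNA
(``numbering="mrna"`` flips to 5'->3' mRNA counting).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .seedcore import (
    MicroRNA,
    NucleotideSequence,
    SeedSiteHit,
    build_site_patterns,
    classify_window,
    complement_base,
    site_rank,
)

__all__ = [
    "SnpRecord",
    "MressDisruptionCall",
    "DataIntegrityError",
    "normalize_chrom",
    "fold_maf",
    "snp_in_site",
    "classify_disruption",
    "summarize_by_seed_type",
    "read_vcf_snps",
    "write_disruption_calls",
]

VERDICTS = ("abolished", "downgraded", "unchanged", "upgraded")


class DataIntegrityError(ValueError):
    """Input records contradict each other (e.g. VCF ref vs UTR sequence)."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` so mixed-source chromosome names compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def fold_maf(freq: float) -> float:
    """Fold an allele frequency onto the minor-allele scale: min(f, 1-f)."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {freq}")
    return min(freq, 1.0 - freq)


@dataclass(frozen=True)
class SnpRecord:
    """A bi-allelic single-base substitution with per-population frequencies.

    ``pop_freqs`` maps population label -> alt-allele (or reported-allele)
    frequency; an empty map encodes "no frequency data" and is distinct from
    a reported frequency of 0.
    """

    rsid: str
    chrom: str
    pos: int  # 1-based gDNA
    ref_allele: str
    alt_allele: str
    pop_freqs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        for allele in (self.ref_allele, self.alt_allele):
            if len(allele) != 1 or allele.upper() not in "ACGT":
                raise ValueError(f"{self.rsid}: allele {allele!r} is not a single base")
        if self.ref_allele.upper() == self.alt_allele.upper():
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())

    def max_folded_maf(self) -> Optional[float]:
        """Largest folded MAF across populations; None when no data."""
        if not self.pop_freqs:
            return None
        return max(fold_maf(f) for f in self.pop_freqs.values())


def snp_in_site(site: SeedSiteHit, snp: SnpRecord, numbering: str = "mir") -> Optional[int]:
    """Return the SNP's 1-8 MRE position within a site, or None if outside.

    Membership uses the full 8-position frame.  ``numbering="mir"`` counts
    positions by the miR base they pair (position 1 = 3'-most mRNA base);
    ``numbering="mrna"`` counts 1-8 along the mRNA 5'->3'.
    """
    if numbering not in ("mir", "mrna"):
        raise ValueError(f"unknown numbering {numbering!r}")
    if site.genomic_start is None or site.chrom is None:
        raise ValueError("site lacks genomic coordinates")
    if normalize_chrom(site.chrom) != snp.chrom:
        return None
    if not site.genomic_start <= snp.pos <= site.genomic_end:
        return None
    # 1-based index along the mRNA 5'->3' within the 8-base frame
    if site.strand == "+":
        u = snp.pos - site.genomic_start + 1
    else:
        u = site.genomic_end - snp.pos + 1
    return 9 - u if numbering == "mir" else u


@dataclass(frozen=True)
class MressDisruptionCall:
    """Effect of one SNP on one seed site, under both alleles."""

    snp: SnpRecord
    site: SeedSiteHit
    mir_name: str
    pos_in_mre: int
    ref_class: Optional[str]
    alt_class: Optional[str]
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def _verdict(ref_class: Optional[str], alt_class: Optional[str]) -> str:
    r, a = site_rank(ref_class), site_rank(alt_class)
    if a == r:
        return "unchanged"
    if a > r:
        return "upgraded"
    return "abolished" if alt_class is None else "downgraded"


def classify_disruption(
    site: SeedSiteHit,
    snp: SnpRecord,
    mir: MicroRNA,
    utr: NucleotideSequence,
    numbering: str = "mir",
) -> MressDisruptionCall:
    """Re-classify a site's 8-base window with the ref and the alt allele.

    Alleles are reported on the genomic forward strand; for minus-strand
    sites they are complemented onto the mRNA before substitution.  A ref
    allele that contradicts the UTR sequence raises
    :class:`DataIntegrityError` naming both bases.
    """
    pos = snp_in_site(site, snp, numbering=numbering)
    if pos is None:
        raise ValueError(f"{snp.rsid} does not fall inside the site frame")
    window = utr.residues[site.window_start - 1 : site.window_end]
    # 0-based index within the mRNA-strand window
    if site.strand == "+":
        widx = snp.pos - site.genomic_start
    else:
        widx = site.genomic_end - snp.pos
    if site.strand == "+":
        ref_mrna, alt_mrna = snp.ref_allele, snp.alt_allele
    else:
        ref_mrna = complement_base(snp.ref_allele)
        alt_mrna = complement_base(snp.alt_allele)
    if window[widx] != ref_mrna:
        raise DataIntegrityError(
            f"{snp.rsid}: UTR base {window[widx]!r} at {site.utr_name} position "
            f"{site.window_start + widx} disagrees with mRNA-strand ref allele {ref_mrna!r}"
        )
    patterns = build_site_patterns(mir)
    ref_class = classify_window(window, patterns)
    alt_window = window[:widx] + alt_mrna + window[widx + 1 :]
    alt_class = classify_window(alt_window, patterns)
    return MressDisruptionCall(
        snp=snp,
        site=site,
        mir_name=mir.name,
        pos_in_mre=pos,
        ref_class=ref_class,
        alt_class=alt_class,
        verdict=_verdict(ref_class, alt_class),
    )


def summarize_by_seed_type(calls: Iterable[MressDisruptionCall]) -> Counter:
    """Count disruption calls by the seed class present with the ref allele."""
    return Counter(c.ref_class for c in calls if c.ref_class is not None)


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf_snps(path, pop_af_keys: Optional[Mapping[str, str]] = None) -> list[SnpRecord]:
    """Read bi-allelic SNVs from a VCF.

    Multi-allelic records, indels and symbolic alleles are dropped at
    ingestion.  ``pop_af_keys`` maps population label -> INFO key holding that
    population's alt-allele frequency (e.g. ``{"EUR": "AF_EUR"}``); absent
    keys leave the population out of the frequency map.
    """
    from cyvcf2 import VCF

    snps: list[SnpRecord] = []
    for var in VCF(str(path)):
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref.upper() not in "ACGT" or alt.upper() not in "ACGT":
            continue
        freqs = {}
        if pop_af_keys:
            for pop, key in pop_af_keys.items():
                val = var.INFO.get(key)
                if val is not None:
                    freqs[pop] = float(val)
        snps.append(
            SnpRecord(
                rsid=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=ref,
                alt_allele=alt,
                pop_freqs=freqs,
            )
        )
    return snps


def write_disruption_calls(calls: Sequence[MressDisruptionCall], path) -> None:
    """Write disruption calls as a TSV shaped like the validated-site table."""
    cols = [
        "rsid",
        "chrom",
        "pos",
        "ref",
        "alt",
        "folded_maf",
        "site_type",
        "pos_in_mre",
        "mir",
        "utr",
        "verdict",
        "alt_class",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            maf = c.snp.max_folded_maf()
            fh.write(
                "\t".join(
                    [
                        c.snp.rsid,
                        c.snp.chrom,
                        str(c.snp.pos),
                        c.snp.ref_allele,
                        c.snp.alt_allele,
                        "NA" if maf is None else f"{maf:.4g}",
                        c.ref_class or "none",
                        str(c.pos_in_mre),
                        c.mir_name,
                        c.site.utr_name,
                        c.verdict,
                        c.alt_class or "none",
                    ]
                )
                + "\n"
            )
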