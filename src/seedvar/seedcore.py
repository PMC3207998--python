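"""Canonical microRNA seed-site patterns and 3'UTR scanning.

A mature microRNA (miR) represses its target mRNA primarily through
Watson-Crick pairing between miR positions 2-7 (the *seed*) and a
complementary stretch in the target 3'UTR.  Four canonical site classes are
recognised, in increasing order of expected repression efficacy:

``6mer``
    perfect pairing to miR positions 2-7 only;
``7mer-A1``
    6mer plus an adenine opposite miR position 1 (the A is a property of the
    target, not of complementarity to the miR);
``7mer-m8``
    6mer plus a Watson-Crick match to miR position 8;
``8mer``
    both the position-1 A and the position-8 match.

All matching is done on a DNA alphabet: RNA input (U) is normalised to T at
ingestion so that genomic context, dbSNP alleles and miR sequences live in a
single alphabet.  ``N`` is accepted as an unknown/sentinel base; it never
matches any pattern.

Coordinates are 1-based inclusive internally (dbSNP convention); BED I/O
converts to and from 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

__all__ = [
    "SITE_TYPES",
    "SITE_RANK",
    "AlphabetError",
    "NucleotideSequence",
    "MicroRNA",
    "SitePatternSet",
    "GenomicPlacement",
    "SeedSiteHit",
    "reverse_complement",
    "complement_base",
    "build_site_patterns",
    "classify_window",
    "site_rank",
    "scan_utr",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_hits_bed",
]

#: Canonical site classes, weakest to strongest.
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

#: Rank of each class under the 8mer > 7mer-m8 > 7mer-A1 > 6mer hierarchy;
#: ``None`` (no site) ranks 0.
SITE_RANK = {None: 0, "6mer": 1, "7mer-A1": 2, "7mer-m8": 3, "8mer": 4}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


class AlphabetError(ValueError):
    """A sequence contains a character outside the A/C/G/T/U/N alphabet."""


def _normalise(residues: str, name: str = "<sequence>") -> str:
    s = residues.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise AlphabetError(
                f"{name}: invalid character {ch!r} at position {i + 1} "
                "(expected A, C, G, T, U or N)"
            )
    return s


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence held internally on the DNA alphabet.

    ``U`` on input is mapped to ``T``; any other non-ACGTN character raises
    :class:`AlphabetError` naming the offending position.
    """

    name: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalise(self.residues, self.name))
        if not self.residues:
            raise ValueError(f"{self.name}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, idx):
        return self.residues[idx]


def complement_base(base: str) -> str:
    """Watson-Crick complement of a single DNA base (N maps to N)."""
    if len(base) != 1 or base.upper().replace("U", "T") not in _VALID:
        raise AlphabetError(f"invalid base {base!r}")
    return base.upper().replace("U", "T").translate(_COMPLEMENT)


def reverse_complement(seq: NucleotideSequence | str) -> NucleotideSequence | str:
    """Reverse complement; returns the same type it is given.

    An involution: applying it twice returns the input.
    """
    if isinstance(seq, NucleotideSequence):
        return NucleotideSequence(seq.name, seq.residues[::-1].translate(_COMPLEMENT))
    return _normalise(seq)[::-1].translate(_COMPLEMENT)


@dataclass(frozen=True)
class MicroRNA:
    """A mature miR sequence (5'->3') with its seed at positions 2-7."""

    name: str
    sequence: NucleotideSequence
    family_conserved: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError(
                f"{self.name}: mature miR must be at least 8 nt, got {len(self.sequence)}"
            )

    @classmethod
    def from_string(cls, name: str, residues: str, family_conserved: bool = False) -> "MicroRNA":
        return cls(name, NucleotideSequence(name, residues), family_conserved)

    @property
    def seed(self) -> str:
        """Residues at miR positions 2-7 (1-based), DNA alphabet."""
        return self.sequence.residues[1:7]


@dataclass(frozen=True)
class SitePatternSet:
    """Target-strand (mRNA 5'->3') match patterns for the four site classes."""

    mir: MicroRNA
    pattern_6mer: str
    pattern_7a1: str
    pattern_7m8: str
    pattern_8mer: str


def build_site_patterns(mir: MicroRNA) -> SitePatternSet:
    """Derive the four mRNA-strand site patterns for a miR.

    The 6mer pattern is the reverse complement of the seed (miR 2-7); the
    7mer-m8 pattern prepends the complement of miR position 8; the 7mer-A1 and
    8mer patterns append a literal A, which the target must carry opposite miR
    position 1 regardless of what miR position 1 is.
    """
    p6 = reverse_complement(mir.seed)
    m8 = complement_base(mir.sequence.residues[7])
    return SitePatternSet(
        mir=mir,
        pattern_6mer=p6,
        pattern_7a1=p6 + "A",
        pattern_7m8=m8 + p6,
        pattern_8mer=m8 + p6 + "A",
    )


def classify_window(window8: str, patterns: SitePatternSet) -> Optional[str]:
    """Classify an 8-base mRNA window against one miR's patterns.

    The window is the fixed 8-position MRE frame in mRNA 5'->3' orientation:
    its first base pairs miR position 8 and its last base sits opposite miR
    position 1.  Returns the maximal matching class under
    8mer > 7mer-m8 > 7mer-A1 > 6mer, or ``None`` when the seed (window
    positions 2-7) does not match.
    """
    if len(window8) != 8:
        raise ValueError(f"expected an 8-base window, got {len(window8)} bases")
    w = window8.upper().replace("U", "T")
    if w[1:7] != patterns.pattern_6mer:
        return None
    m8_match = w[0] == patterns.pattern_7m8[0]
    a1_match = w[7] == "A"
    if m8_match and a1_match:
        return "8mer"
    if m8_match:
        return "7mer-m8"
    if a1_match:
        return "7mer-A1"
    return "6mer"


def site_rank(site_type: Optional[str]) -> int:
    """Integer rank of a site class (``None`` = 0, 8mer = 4)."""
    return SITE_RANK[site_type]


@dataclass(frozen=True)
class GenomicPlacement:
    """Genomic location of a UTR: 0-based half-open interval plus strand.

    The UTR sequence itself is always stored as the mRNA strand (5'->3'); for
    minus-strand placements the genome holds its reverse complement.
    """

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start

    def utr_to_genomic(self, utr_pos: int) -> int:
        """Map a 1-based position along the mRNA to a 1-based gDNA coordinate."""
        if self.strand == "+":
            return self.start + utr_pos
        return self.end - utr_pos + 1

    def genomic_to_utr(self, gpos: int) -> int:
        """Inverse of :meth:`utr_to_genomic` (may fall outside 1..len)."""
        if self.strand == "+":
            return gpos - self.start
        return self.end - gpos + 1


@dataclass(frozen=True)
class SeedSiteHit:
    """A located canonical seed site (fixed 8-position MRE frame).

    ``window_start``/``window_end`` are 1-based inclusive offsets of the frame
    within the UTR; genomic coordinates are 1-based inclusive gDNA.  MRE
    position *k* is the mRNA base pairing miR position *k*, so position 1 is
    the 3'-most base of the frame on the mRNA.
    """

    mir_name: str
    utr_name: str
    site_type: str
    window_start: int
    window_end: int
    chrom: Optional[str] = None
    genomic_start: Optional[int] = None
    genomic_end: Optional[int] = None
    strand: str = "+"
    phastcons_score: Optional[float] = None
    mirsvr_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.window_end - self.window_start != 7:
            raise ValueError("MRE frame must span exactly 8 positions")


def scan_utr(
    utr: NucleotideSequence,
    mirs: Iterable[MicroRNA],
    placement: Optional[GenomicPlacement] = None,
    min_phastcons: Optional[float] = None,
    mirsvr_max: Optional[float] = None,
    site_scores: Optional[Mapping[tuple, tuple]] = None,
    require_genomic: bool = False,
) -> list[SeedSiteHit]:
    """Scan a 3'UTR for canonical seed sites of each miR.

    One hit is emitted per (miR, window offset) achieving a class; overlapping
    hits are all reported.  ``site_scores`` maps
    ``(utr_name, mir_name, window_start)`` to ``(phastcons, mirsvr)``; when an
    annotation is present for a hit, the conservation filter
    (``phastcons >= min_phastcons``) and the down-regulation-score filter
    (``mirsvr <= mirsvr_max``) are applied, mirroring the use of
    precomputed prediction files.  Hits without annotation are kept.

    Genomic coordinates are filled in from ``placement``; minus-strand windows
    are mapped through the reverse-complement coordinate transform.
    """
    if require_genomic and placement is None:
        raise ValueError(f"{utr.name}: genomic coordinates requested but no placement given")
    if placement is not None and len(placement) != len(utr):
        raise ValueError(
            f"{utr.name}: placement length {len(placement)} != sequence length {len(utr)}"
        )
    seq = utr.residues
    hits: list[SeedSiteHit] = []
    for mir in mirs:
        patterns = build_site_patterns(mir)
        for off in range(len(seq) - 7):
            site_type = classify_window(seq[off : off + 8], patterns)
            if site_type is None:
                continue
            wstart, wend = off + 1, off + 8
            phast = svr = None
            if site_scores is not None:
                ann = site_scores.get((utr.name, mir.name, wstart))
                if ann is not None:
                    phast, svr = ann
                    if min_phastcons is not None and phast is not None and phast < min_phastcons:
                        continue
                    if mirsvr_max is not None and svr is not None and svr > mirsvr_max:
                        continue
            chrom = gstart = gend = None
            strand = "+"
            if placement is not None:
                g1 = placement.utr_to_genomic(wstart)
                g2 = placement.utr_to_genomic(wend)
                chrom = placement.chrom
                gstart, gend = min(g1, g2), max(g1, g2)
                strand = placement.strand
            hits.append(
                SeedSiteHit(
                    mir_name=mir.name,
                    utr_name=utr.name,
                    site_type=site_type,
                    window_start=wstart,
                    window_end=wend,
                    chrom=chrom,
                    genomic_start=gstart,
                    genomic_end=gend,
                    strand=strand,
                    phastcons_score=phast,
                    mirsvr_score=svr,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# FASTA / BED I/O


def read_fasta(path) -> list[NucleotideSequence]:
    """Read a FASTA file into :class:`NucleotideSequence` records (U -> T)."""
    return [NucleotideSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Sequence[NucleotideSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.residues), 70):
                fh.write(s.residues[i : i + 70] + "\n")


def read_bed(path) -> dict[str, GenomicPlacement]:
    """Read a BED6 file of UTR placements, keyed by the name column."""
    placements: dict[str, GenomicPlacement] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else "+"
            placements[name] = GenomicPlacement(chrom, start, end, strand)
    return placements


def write_hits_bed(hits: Sequence[SeedSiteHit], path) -> None:
    """Write seed-site hits as BED6 intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.genomic_start is None:
                continue
            name = f"{h.utr_name}|{h.mir_name}|{h.site_type}"
            fh.write(
                f"{h.chrom}\t{h.genomic_start - 1}\t{h.genomic_end}\t{name}\t0\t{h.strand}\n"
            )
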