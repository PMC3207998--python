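"""Detection of SNP alleles that create novel miR seed sites (CNM SNPs).

For every 3'UTR SNP the 22 bases flanking each side are extracted, giving a
45-base mRNA-strand window with the SNP fixed at position 23.  A miR *creates*
a site at this SNP when the 8-position MRE frame containing position 23
classifies strictly higher with the alternate allele than with the reference
allele.  Candidate duplexes are then filtered with a proxy pairing/energy
scorer whose thresholds play the same role as the alignment-score and
free-energy cutoffs of classical target-prediction tools: they trim weak
duplexes, they are not quantitative outputs.

The proxy scorer performs an antiparallel Smith-Waterman local alignment of
the miR against the target window.  Watson-Crick pairs score +5, G:U wobbles
+2, mismatches -3, gaps -8, and contributions from miR seed positions 2-8 are
doubled.  The energy proxy is ``-(3*GC + 2*AT + 1*GT)`` in pseudo-kcal/mol
over the paired positions of the optimal alignment, so it decreases (gets
more favourable) with duplex length and GC content.  A perfect duplex with a
21-nt miR scores 140 on this scale, roughly twice the default score
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .seedcore import (
    GenomicPlacement,
    MicroRNA,
    NucleotideSequence,
    build_site_patterns,
    classify_window,
    site_rank,
)
from .variants import SnpRecord, complement_base

__all__ = [
    "SENTINEL",
    "ProxyScoringParams",
    "SnpWindow",
    "CnmHit",
    "extract_window",
    "duplex_score",
    "detect_created_sites",
    "write_cnm_hits",
]

#: Pads windows truncated at UTR ends; never matches a pattern, never pairs.
SENTINEL = "N"

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # G:U wobble on the DNA representation
_PAIR_ENERGY = {("G", "C"): 3.0, ("C", "G"): 3.0, ("A", "T"): 2.0, ("T", "A"): 2.0,
                ("G", "T"): 1.0, ("T", "G"): 1.0}


@dataclass(frozen=True)
class ProxyScoringParams:
    """Scoring scheme and filter thresholds for the proxy duplex scorer."""

    match_wc: float = 5.0
    match_gu: float = 2.0
    mismatch: float = -3.0
    gap: float = -8.0
    seed_weight: float = 2.0  # multiplier over miR positions 2-8
    score_min: float = 70.0  # proxy-scale equivalent of the classical 150 cutoff
    energy_max: float = -20.0  # pseudo-kcal/mol


@dataclass(frozen=True)
class SnpWindow:
    """A SNP-centred 45-base mRNA-strand window (ref and alt versions)."""

    snp: SnpRecord
    sequence_ref: str
    sequence_alt: str
    snp_offset: int = 23  # 1-based

    def __post_init__(self) -> None:
        if len(self.sequence_ref) != len(self.sequence_alt):
            raise ValueError("ref and alt windows differ in length")
        i = self.snp_offset - 1
        if not 0 <= i < len(self.sequence_ref):
            raise ValueError("snp_offset outside the window")
        diffs = [k for k, (a, b) in enumerate(zip(self.sequence_ref, self.sequence_alt)) if a != b]
        if diffs != [i]:
            raise ValueError(f"windows must differ exactly at offset {self.snp_offset}")


def extract_window(
    utr: NucleotideSequence,
    snp: SnpRecord,
    placement: Optional[GenomicPlacement] = None,
    utr_pos: Optional[int] = None,
    flank: int = 22,
) -> SnpWindow:
    """Extract the ref/alt windows of ``2*flank + 1`` bases around a SNP.

    The SNP's 1-based position along the mRNA is either given directly
    (``utr_pos``) or derived from the UTR's genomic placement.  Windows
    truncated by the UTR ends are padded with :data:`SENTINEL`.  Alleles are
    complemented onto the mRNA for minus-strand placements.
    """
    if utr_pos is None:
        if placement is None:
            raise ValueError("need either utr_pos or a genomic placement")
        utr_pos = placement.genomic_to_utr(snp.pos)
    if not 1 <= utr_pos <= len(utr):
        raise ValueError(f"{snp.rsid}: position {utr_pos} outside UTR {utr.name}")
    strand = placement.strand if placement is not None else "+"
    ref_mrna = snp.ref_allele if strand == "+" else complement_base(snp.ref_allele)
    alt_mrna = snp.alt_allele if strand == "+" else complement_base(snp.alt_allele)
    if utr.residues[utr_pos - 1] != ref_mrna:
        raise ValueError(
            f"{snp.rsid}: UTR base {utr.residues[utr_pos - 1]!r} at position {utr_pos} "
            f"disagrees with mRNA-strand ref allele {ref_mrna!r}"
        )
    i = utr_pos - 1
    left = utr.residues[max(0, i - flank) : i]
    right = utr.residues[i + 1 : i + 1 + flank]
    left = SENTINEL * (flank - len(left)) + left
    right = right + SENTINEL * (flank - len(right))
    return SnpWindow(
        snp=snp,
        sequence_ref=left + ref_mrna + right,
        sequence_alt=left + alt_mrna + right,
        snp_offset=flank + 1,
    )


def _pair_score(mir_base: str, target_base: str, mir_pos: int, p: ProxyScoringParams) -> float:
    if SENTINEL in (mir_base, target_base):
        s = p.mismatch
    elif (mir_base, target_base) in _WC:
        s = p.match_wc
    elif (mir_base, target_base) in _GU:
        s = p.match_gu
    else:
        s = p.mismatch
    if 2 <= mir_pos <= 8:
        s *= p.seed_weight
    return s


def duplex_score(
    mir: MicroRNA, target: str, params: ProxyScoringParams = ProxyScoringParams()
) -> tuple[float, float]:
    """Proxy pairing score and energy for a miR/target duplex.

    The miR (5'->3') is aligned antiparallel against the target (5'->3'), so
    miR base *i* pairs target bases read 3'->5'.  The pairing score is the
    optimal local-alignment score under the scheme in ``params``; the energy
    proxy sums -3 per GC, -2 per AT and -1 per G:U pair over the paired
    (non-gap, complementary) positions of that alignment.  Deterministic:
    ties are broken towards the earliest cell and diagonal moves.
    """
    if len(target) < 8:
        raise ValueError("target must be at least 8 bases")
    q = mir.sequence.residues  # miR 5'->3'; position i+1
    t = target.upper().replace("U", "T")[::-1]  # traverse target 3'->5'
    m, n = len(q), len(t)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        row = H[i]
        prev = H[i - 1]
        for j in range(1, n + 1):
            diag = prev[j - 1] + _pair_score(q[i - 1], t[j - 1], i, params)
            up = prev[j] + params.gap
            left = row[j - 1] + params.gap
            v = max(0.0, diag, up, left)
            row[j] = v
            if v > best:
                best, bi, bj = v, i, j
    # traceback to recover paired positions for the energy proxy
    energy = 0.0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        v = H[i][j]
        diag = H[i - 1][j - 1] + _pair_score(q[i - 1], t[j - 1], i, params)
        if abs(v - diag) < 1e-9:
            energy -= _PAIR_ENERGY.get((q[i - 1], t[j - 1]), 0.0)
            i, j = i - 1, j - 1
        elif abs(v - (H[i - 1][j] + params.gap)) < 1e-9:
            i -= 1
        else:
            j -= 1
    return best, energy


@dataclass(frozen=True)
class CnmHit:
    """A miR seed site created by a SNP's alternate allele."""

    snp: SnpRecord
    mir_name: str
    site_type: str
    window_offset: int  # 1-based start of the 8-position frame in the window
    pairing_score: float
    energy_proxy: float
    ref_class: Optional[str] = None


def detect_created_sites(
    window: SnpWindow,
    mirs: Iterable[MicroRNA],
    params: ProxyScoringParams = ProxyScoringParams(),
    require_strict_creation: bool = True,
) -> list[CnmHit]:
    """Find miR sites created by the alternate allele at the SNP position.

    Only 8-position frames containing the SNP offset are considered.  A hit
    requires the alt-allele class to strictly exceed the ref-allele class at
    the same frame (``require_strict_creation=False`` relaxes this to "alt
    achieves any class", i.e. any-new-frame semantics) and the proxy duplex
    on the alt window to pass ``params.score_min`` / ``params.energy_max``.
    """
    off = window.snp_offset  # 1-based
    n = len(window.sequence_alt)
    lo = max(1, off - 7)
    hi = min(n - 7, off)
    hits: list[CnmHit] = []
    for mir in mirs:
        patterns = build_site_patterns(mir)
        score = energy = None  # lazy: one duplex evaluation per (miR, window)
        for f in range(lo, hi + 1):
            ref_w = window.sequence_ref[f - 1 : f + 7]
            alt_w = window.sequence_alt[f - 1 : f + 7]
            ref_class = classify_window(ref_w, patterns)
            alt_class = classify_window(alt_w, patterns)
            if alt_class is None:
                continue
            if require_strict_creation and site_rank(alt_class) <= site_rank(ref_class):
                continue
            if score is None:
                score, energy = duplex_score(mir, window.sequence_alt, params)
            if score < params.score_min or energy > params.energy_max:
                continue
            hits.append(
                CnmHit(
                    snp=window.snp,
                    mir_name=mir.name,
                    site_type=alt_class,
                    window_offset=f,
                    pairing_score=score,
                    energy_proxy=energy,
                    ref_class=ref_class,
                )
            )
    return hits


def write_cnm_hits(hits: Sequence[CnmHit], path) -> None:
    """TSV output; PS/ES/S-T column names follow target-prediction convention."""
    with open(path, "w") as fh:
        fh.write("rsid\tmiR\tS-T\tframe_offset\tPS\tES\n")
        for h in hits:
            fh.write(
                f"{h.snp.rsid}\t{h.mir_name}\t{h.site_type}\t{h.window_offset}"
                f"\t{h.pairing_score:.1f}\t{h.energy_proxy:.1f}\n"
            )
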