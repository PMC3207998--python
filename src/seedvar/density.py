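"""Sliding-window SNP density around validated seed sites.

For each seed site a 42-base region is considered: 18 bases upstream of the
first seed base (miR-position-2 pairing base), the 6 seed bases, and 18 bases
downstream.  A 6-base window slides across this region at 1-base steps,
giving 37 windows whose start offsets run from -18 to +18 relative to the
first seed base.  Density is reported as SNPs/kb:

    density(offset) = count(offset) * 1000 / (n_sites(offset) * window)

where ``count`` pools (site, SNP) co-occurrences over all sites and
``n_sites`` is the number of sites whose window at that offset is fully
covered by the contig (all sites when contig bounds are unknown).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .seedcore import SeedSiteHit
from .variants import SnpRecord, normalize_chrom

__all__ = ["DensityProfile", "window_density", "seed_average", "write_profile"]


@dataclass(frozen=True)
class DensityProfile:
    """Per-offset SNP counts and densities over the sliding-window region."""

    offsets: np.ndarray  # window start offsets relative to first seed base
    counts: np.ndarray
    n_sites: np.ndarray  # sites contributing at each offset
    density: np.ndarray  # SNPs/kb
    window: int
    total_sites: int


def _seed_relative_offset(site: SeedSiteHit, snp: SnpRecord) -> Optional[int]:
    """SNP offset along the mRNA relative to the first seed base (0-based).

    The 8-position frame holds the seed (miR positions 2-7) at mRNA indices
    2..7; index 2 is the first seed base.  Offsets are signed along the mRNA
    5'->3', negative = upstream.
    """
    if site.chrom is None or normalize_chrom(site.chrom) != snp.chrom:
        return None
    if site.strand == "+":
        u = snp.pos - site.genomic_start + 1
    else:
        u = site.genomic_end - snp.pos + 1
    return u - 2


def window_density(
    sites: Sequence[SeedSiteHit],
    snps: Sequence[SnpRecord],
    window: int = 6,
    flank: int = 18,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> DensityProfile:
    """Compute the sliding-window SNP density profile over seed-site regions."""
    offsets = np.arange(-flank, flank + 1)
    counts = np.zeros(offsets.size, dtype=int)
    n_sites = np.zeros(offsets.size, dtype=int)

    for site in sites:
        if site.genomic_start is None:
            raise ValueError("density requires sites with genomic coordinates")
        # which window offsets are fully inside the contig for this site
        if contig_lengths is None:
            n_sites += 1
        else:
            clen = contig_lengths[normalize_chrom(site.chrom)] if site.chrom else None
            for k, w in enumerate(offsets):
                # mRNA positions covered by this window, as frame indices u
                u_lo, u_hi = w + 2, w + 2 + window - 1
                if site.strand == "+":
                    g_lo = site.genomic_start + u_lo - 1
                    g_hi = site.genomic_start + u_hi - 1
                else:
                    g_hi = site.genomic_end - u_lo + 1
                    g_lo = site.genomic_end - u_hi + 1
                if g_lo >= 1 and (clen is None or g_hi <= clen):
                    n_sites[k] += 1

    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)

    for site in sites:
        for snp in by_chrom.get(normalize_chrom(site.chrom), []):
            d = _seed_relative_offset(site, snp)
            if d is None:
                continue
            lo = max(-flank, d - window + 1)
            hi = min(flank, d)
            for w in range(lo, hi + 1):
                counts[w + flank] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(
            n_sites > 0, counts * 1000.0 / (n_sites * float(window)), 0.0
        )
    return DensityProfile(
        offsets=offsets,
        counts=counts,
        n_sites=n_sites,
        density=density,
        window=window,
        total_sites=len(sites),
    )


def seed_average(profile: DensityProfile) -> float:
    """Mean density over the windows starting on seed positions (offsets 0-5)."""
    mask = (profile.offsets >= 0) & (profile.offsets < profile.window)
    if not mask.any():
        raise ValueError("profile does not cover the seed offsets")
    return float(profile.density[mask].mean())


def write_profile(profile: DensityProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tcount\tn_sites\tdensity_snps_per_kb\n")
        for o, c, n, d in zip(profile.offsets, profile.counts, profile.n_sites, profile.density):
            fh.write(f"{o}\t{c}\t{n}\t{d:.6g}\n")
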