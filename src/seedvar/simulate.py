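"""Synthetic data with planted ground truth for every pipeline stage.

The generator fabricates the full input bundle the survey consumes — mature
miR sequences, 3'UTRs with genomic placements, bi-allelic SNPs with
per-population allele frequencies, a pairwise-LD table, a GWAS catalog and
per-group allele counts — while recording exactly what was planted so every
stage can be checked against the truth:

* seed sites of each canonical class are written into UTRs such that the
  planted class is the maximal class at that frame;
* a fraction of planted sites receive a SNP at a seed position, whose
  alternate allele abolishes the site;
* creation events embed the full reverse complement of a miR with the seed
  broken by the reference allele and restored by the alternate allele, so
  the created duplex passes the default pairing/energy filters;
* per-population allele frequencies follow the Balding-Nichols model
  (Beta-distributed around an ancestral frequency drawn away from 0/1),
  with a larger differentiation parameter F for seed-site SNPs;
* LD is fabricated at the r^2 summary level by correlated allele copying
  within blocks of consecutive SNPs (the pipeline consumes r^2 tables, not
  haplotypes);
* catalog SNPs are drawn from the MAF-eligible universe with odds multiplied
  by ``enrichment_factor`` when their LD block contains a seed-site SNP.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .creation import SENTINEL
from .enrichment import GwasCatalog, LdTable
from .seedcore import (
    GenomicPlacement,
    MicroRNA,
    NucleotideSequence,
    build_site_patterns,
    reverse_complement,
    write_fasta,
)
from .variants import SnpRecord, complement_base, fold_maf

__all__ = ["SimulationConfig", "SimulatedWorld", "simulate_world", "write_world"]

_BASES = "ACGT"


def _default_planted() -> dict[str, int]:
    # class mix follows the predominance of 8mer/7mer-m8 calls among
    # genome-wide disruption predictions
    return {"8mer": 40, "7mer-m8": 40, "7mer-A1": 20, "6mer": 20}


def _default_pops() -> dict[str, int]:
    # four ancestry groups (African, Asian, European, American) with
    # HapMap-panel-scale allele counts (100 diploids each)
    return {"AFR": 200, "ASN": 200, "EUR": 200, "AMR": 200}


def _default_bn() -> dict[str, float]:
    return {"mre": 0.2, "other": 0.1}


@dataclass
class SimulationConfig:
    """Knobs for the synthetic world; defaults are the study conditions."""

    rng_seed: int = 0
    n_mirs: int = 8
    mir_length: int = 21
    n_utrs: int = 30
    utr_length: int = 1500
    n_planted_sites: Mapping[str, int] = field(default_factory=_default_planted)
    p_snp_in_seed: float = 0.5
    n_snps: int = 500  # background SNPs outside planted frames
    n_created_sites: int = 60
    populations: Mapping[str, int] = field(default_factory=_default_pops)
    balding_nichols_F: Mapping[str, float] = field(default_factory=_default_bn)
    ld_block_size: int = 5
    target_r2: float = 0.9
    catalog_size: int = 40
    enrichment_factor: float = 1.0
    n_haplotypes: int = 200  # virtual haplotypes used for LD copying

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_snp_in_seed <= 1.0:
            raise ValueError("p_snp_in_seed must be in [0, 1]")
        for key, F in self.balding_nichols_F.items():
            if not 0.0 < F < 1.0:
                raise ValueError(f"Balding-Nichols F for {key!r} must be in (0, 1)")
        for name, val in [
            ("n_mirs", self.n_mirs),
            ("mir_length", self.mir_length),
            ("n_utrs", self.n_utrs),
            ("utr_length", self.utr_length),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulatedWorld:
    """The generated bundle plus its ground-truth tables."""

    config: SimulationConfig
    mirs: list[MicroRNA]
    utrs: list[NucleotideSequence]
    placements: dict[str, GenomicPlacement]
    snps: list[SnpRecord]
    truth_sites: pd.DataFrame  # utr, mir, window_start, site_type
    truth_snps: pd.DataFrame  # rsid, kind, utr, utr_pos, mir, site_type, frame_start
    group_freqs: pd.DataFrame  # rsid, group, alt_count, n_alleles
    ld: LdTable
    ld_pairs: pd.DataFrame  # snpA, snpB, r2
    catalog: GwasCatalog
    mre_snps: set[str]  # rsids of seed-disrupting or site-creating SNPs

    @property
    def mress_snps(self) -> set[str]:
        t = self.truth_snps
        return set(t.loc[t["kind"] == "disruption", "rsid"])

    @property
    def cnm_snps(self) -> set[str]:
        t = self.truth_snps
        return set(t.loc[t["kind"] == "creation", "rsid"])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _class_frame(rng: np.random.Generator, patterns, site_type: str) -> str:
    """An 8-base mRNA frame whose maximal class is exactly ``site_type``."""
    comp8 = patterns.pattern_7m8[0]
    not_a = rng.choice([b for b in _BASES if b != "A"])
    not_comp8 = rng.choice([b for b in _BASES if b != comp8])
    if site_type == "8mer":
        return patterns.pattern_8mer
    if site_type == "7mer-m8":
        return patterns.pattern_7m8 + not_a
    if site_type == "7mer-A1":
        return not_comp8 + patterns.pattern_7a1
    if site_type == "6mer":
        return not_comp8 + patterns.pattern_6mer + not_a
    raise ValueError(f"unknown site type {site_type!r}")


def simulate_world(config: SimulationConfig) -> SimulatedWorld:
    """Generate the full synthetic input bundle with ground truth."""
    rng = np.random.default_rng(config.rng_seed)
    mirs = [
        MicroRNA.from_string(f"sim-miR-{i + 1}", _random_seq(rng, config.mir_length))
        for i in range(config.n_mirs)
    ]
    patterns = {m.name: build_site_patterns(m) for m in mirs}

    # --- UTRs, slots and planted sites -----------------------------------
    margin = 40  # keep plants away from UTR ends (density flanks, CNM windows)
    slot_w = max(config.mir_length + 10, 50)
    utr_seqs = [list(_random_seq(rng, config.utr_length)) for _ in range(config.n_utrs)]
    slots: list[tuple[int, int]] = []  # (utr index, 0-based slot start)
    for ui in range(config.n_utrs):
        pos = margin
        while pos + slot_w <= config.utr_length - margin:
            slots.append((ui, pos))
            pos += slot_w
    n_sites = sum(config.n_planted_sites.values())
    needed = n_sites + config.n_created_sites
    if needed > len(slots):
        raise ValueError(
            f"infeasible planting: {needed} plants requested, {len(slots)} slots available"
        )
    order = rng.permutation(len(slots))
    slot_iter = iter(order)

    site_rows = []
    snp_rows = []
    rsid_counter = [0]

    def next_rsid() -> str:
        rsid_counter[0] += 1
        return f"rs{rsid_counter[0]}"

    occupied = [np.zeros(config.utr_length, dtype=bool) for _ in range(config.n_utrs)]

    for site_type, count in config.n_planted_sites.items():
        for _ in range(count):
            ui, start = slots[next(slot_iter)]
            mir = mirs[int(rng.integers(config.n_mirs))]
            frame = _class_frame(rng, patterns[mir.name], site_type)
            utr_seqs[ui][start : start + 8] = list(frame)
            occupied[ui][start : start + 8] = True
            site_rows.append(
                {
                    "utr": f"utr{ui + 1}",
                    "mir": mir.name,
                    "window_start": start + 1,
                    "site_type": site_type,
                }
            )
            if rng.random() < config.p_snp_in_seed:
                u = int(rng.integers(2, 8))  # frame index 2..7 = seed positions
                idx = start + u - 1
                ref = utr_seqs[ui][idx]
                alt = str(rng.choice([b for b in _BASES if b != ref]))
                snp_rows.append(
                    {
                        "rsid": next_rsid(),
                        "kind": "disruption",
                        "utr": f"utr{ui + 1}",
                        "utr_pos": idx + 1,
                        "mir": mir.name,
                        "site_type": site_type,
                        "frame_start": start + 1,
                        "ref_mrna": ref,
                        "alt_mrna": alt,
                    }
                )

    # --- creation events --------------------------------------------------
    for _ in range(config.n_created_sites):
        ui, start = slots[next(slot_iter)]
        mir = mirs[int(rng.integers(config.n_mirs))]
        site_type = str(rng.choice(["8mer", "7mer-m8", "7mer-A1", "6mer"]))
        ext = list(reverse_complement(mir.sequence.residues))  # full-duplex context
        m = len(ext)
        frame = _class_frame(rng, patterns[mir.name], site_type)
        ext[m - 8 : m] = list(frame)
        u = int(rng.integers(2, 8))  # break/restore a seed position
        alt = ext[m - 8 + u - 1]
        ref = str(rng.choice([b for b in _BASES if b != alt]))
        ext[m - 8 + u - 1] = ref
        utr_seqs[ui][start : start + m] = ext
        occupied[ui][start : start + m] = True
        snp_rows.append(
            {
                "rsid": next_rsid(),
                "kind": "creation",
                "utr": f"utr{ui + 1}",
                "utr_pos": start + (m - 8) + u,
                "mir": mir.name,
                "site_type": site_type,
                "frame_start": start + (m - 8) + 1,
                "ref_mrna": ref,
                "alt_mrna": alt,
            }
        )

    # --- background SNPs --------------------------------------------------
    for _ in range(config.n_snps):
        for _attempt in range(100):
            ui = int(rng.integers(config.n_utrs))
            idx = int(rng.integers(config.utr_length))
            if not occupied[ui][idx]:
                break
        else:  # pragma: no cover - only under extreme occupancy
            continue
        occupied[ui][idx] = True
        ref = utr_seqs[ui][idx]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        snp_rows.append(
            {
                "rsid": next_rsid(),
                "kind": "background",
                "utr": f"utr{ui + 1}",
                "utr_pos": idx + 1,
                "mir": "",
                "site_type": "",
                "frame_start": 0,
                "ref_mrna": ref,
                "alt_mrna": alt,
            }
        )

    utrs = [
        NucleotideSequence(f"utr{ui + 1}", "".join(utr_seqs[ui]))
        for ui in range(config.n_utrs)
    ]

    # --- genomic placements (two chromosomes, alternating strands) --------
    placements: dict[str, GenomicPlacement] = {}
    cursors = {"1": 1000, "2": 1000}
    for ui, utr in enumerate(utrs):
        chrom = "1" if ui % 2 == 0 else "2"
        strand = "+" if (ui // 2) % 2 == 0 else "-"
        start = cursors[chrom]
        placements[utr.name] = GenomicPlacement(chrom, start, start + len(utr), strand)
        cursors[chrom] = start + len(utr) + 500

    # --- SNP records on the genomic strand --------------------------------
    truth_snps = pd.DataFrame(
        snp_rows,
        columns=[
            "rsid", "kind", "utr", "utr_pos", "mir", "site_type",
            "frame_start", "ref_mrna", "alt_mrna",
        ],
    )
    mre_snps = set(truth_snps.loc[truth_snps["kind"] != "background", "rsid"])

    # --- Balding-Nichols group frequencies --------------------------------
    pops = dict(config.populations)
    freq_rows = []
    pop_freq_maps: dict[str, dict[str, float]] = {}
    for row in truth_snps.itertuples():
        F = config.balding_nichols_F["mre" if row.rsid in mre_snps else "other"]
        p_anc = rng.uniform(0.05, 0.95)
        a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
        fmap = {}
        for pop, n_alleles in pops.items():
            p_g = float(rng.beta(a, b))
            cnt = int(rng.binomial(n_alleles, p_g))
            freq_rows.append(
                {"rsid": row.rsid, "group": pop, "alt_count": cnt, "n_alleles": n_alleles}
            )
            fmap[pop] = cnt / n_alleles
        pop_freq_maps[row.rsid] = fmap
    group_freqs = pd.DataFrame(freq_rows, columns=["rsid", "group", "alt_count", "n_alleles"])

    snps = []
    for row in truth_snps.itertuples():
        plc = placements[row.utr]
        gpos = plc.utr_to_genomic(row.utr_pos)
        if plc.strand == "+":
            ref_g, alt_g = row.ref_mrna, row.alt_mrna
        else:
            ref_g, alt_g = complement_base(row.ref_mrna), complement_base(row.alt_mrna)
        snps.append(
            SnpRecord(
                rsid=row.rsid,
                chrom=plc.chrom,
                pos=gpos,
                ref_allele=ref_g,
                alt_allele=alt_g,
                pop_freqs=pop_freq_maps[row.rsid],
            )
        )

    # --- LD by correlated allele copying within blocks --------------------
    rsids = [s.rsid for s in snps]
    flip = (1.0 - np.sqrt(config.target_r2)) / 2.0
    ld_rows = []
    block_of: dict[str, int] = {}
    for bi, bstart in enumerate(range(0, len(rsids), config.ld_block_size)):
        block = rsids[bstart : bstart + config.ld_block_size]
        for r in block:
            block_of[r] = bi
        if len(block) < 2:
            continue
        lead = rng.random(config.n_haplotypes) < 0.5
        haps = {block[0]: lead}
        for r in block[1:]:
            haps[r] = lead ^ (rng.random(config.n_haplotypes) < flip)
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                x = haps[block[i]].astype(float)
                y = haps[block[j]].astype(float)
                if x.std() == 0 or y.std() == 0:
                    r2 = 0.0
                else:
                    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
                ld_rows.append({"snpA": block[i], "snpB": block[j], "r2": r2})
    ld_pairs = pd.DataFrame(ld_rows, columns=["snpA", "snpB", "r2"])
    ld = LdTable(zip(ld_pairs["snpA"], ld_pairs["snpB"], ld_pairs["r2"]))

    # --- GWAS catalog ------------------------------------------------------
    eligible = [
        s for s in snps if (m := s.max_folded_maf()) is not None and m >= 0.01
    ]
    blocks_with_mre = {block_of[r] for r in mre_snps if r in block_of}
    weights = np.array(
        [
            config.enrichment_factor if block_of.get(s.rsid) in blocks_with_mre else 1.0
            for s in eligible
        ]
    )
    k = min(config.catalog_size, len(eligible))
    # weighted sampling without replacement via exponential keys
    keys = rng.exponential(size=len(eligible)) / weights
    chosen = np.argsort(keys)[:k]
    cat_rows = []
    for i, idx in enumerate(chosen):
        cat_rows.append(
            {
                "rsid": eligible[int(idx)].rsid,
                "trait": f"trait{i + 1}",
                "p_value": float(10.0 ** -rng.uniform(5.1, 25.0)),
                "pmid": int(20000000 + i),
            }
        )
    catalog = GwasCatalog(records=pd.DataFrame(cat_rows, columns=["rsid", "trait", "p_value", "pmid"]))

    truth_sites = pd.DataFrame(site_rows, columns=["utr", "mir", "window_start", "site_type"])
    return SimulatedWorld(
        config=config,
        mirs=mirs,
        utrs=utrs,
        placements=placements,
        snps=snps,
        truth_sites=truth_sites,
        truth_snps=truth_snps,
        group_freqs=group_freqs,
        ld=ld,
        ld_pairs=ld_pairs,
        catalog=catalog,
        mre_snps=mre_snps,
    )


def write_world(world: SimulatedWorld, outdir) -> dict[str, str]:
    """Write the bundle in the formats the pipeline reads; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "mirs": "mirs.fasta",
        "utrs": "utrs.fasta",
        "bed": "utrs.bed",
        "vcf": "snps.vcf",
        "ld": "ld.tsv",
        "catalog": "catalog.tsv",
        "group_freqs": "group_freqs.tsv",
        "truth_sites": "truth_sites.tsv",
        "truth_snps": "truth_snps.tsv",
    }.items()}

    write_fasta([m.sequence for m in world.mirs], paths["mirs"])
    write_fasta(world.utrs, paths["utrs"])
    with open(paths["bed"], "w") as fh:
        for utr in world.utrs:
            p = world.placements[utr.name]
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{utr.name}\t0\t{p.strand}\n")

    pops = list(world.config.populations)
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for pop in pops:
            fh.write(
                f'##INFO=<ID=AF_{pop},Number=1,Type=Float,'
                f'Description="Alt allele frequency in {pop}">\n'
            )
        for chrom in sorted({s.chrom for s in world.snps}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(world.snps, key=lambda x: (x.chrom, x.pos)):
            info = ";".join(f"AF_{p}={s.pop_freqs[p]:.6g}" for p in pops if p in s.pop_freqs)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.rsid}\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t{info or '.'}\n")

    world.ld_pairs.to_csv(paths["ld"], sep="\t", index=False)
    world.catalog.records.to_csv(paths["catalog"], sep="\t", index=False)
    world.group_freqs.to_csv(paths["group_freqs"], sep="\t", index=False)
    world.truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    world.truth_snps.to_csv(paths["truth_snps"], sep="\t", index=False)
    return paths
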