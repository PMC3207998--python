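"""SNP records, site intersection and disruption calls."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedvar.seedcore import (
    GenomicPlacement,
    MicroRNA,
    NucleotideSequence,
    build_site_patterns,
    classify_window,
    scan_utr,
)
from seedvar.variants import (
    DataIntegrityError,
    SnpRecord,
    classify_disruption,
    fold_maf,
    normalize_chrom,
    read_vcf_snps,
    snp_in_site,
    summarize_by_seed_type,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RANK = {None: 0, "6mer": 1, "7mer-A1": 2, "7mer-m8": 3, "8mer": 4}


def test_normalize_chrom():
    assert normalize_chrom("chr7") == "7"
    assert normalize_chrom("7") == "7"
    assert normalize_chrom("CHRX") == "X"


@pytest.mark.parametrize("f,expected", [(0.0, 0.0), (0.3, 0.3), (0.5, 0.5), (0.97, 0.03), (1.0, 0.0)])
def test_fold_maf_examples(f, expected):
    assert fold_maf(f) == pytest.approx(expected)


@given(st.floats(0, 1))
def test_fold_maf_symmetric_idempotent(f):
    m = fold_maf(f)
    assert 0 <= m <= 0.5
    assert fold_maf(1 - f) == pytest.approx(m)
    assert fold_maf(m) == pytest.approx(m)


def test_fold_maf_rejects_out_of_range():
    with pytest.raises(ValueError):
        fold_maf(1.2)


def test_snp_record_validation():
    with pytest.raises(ValueError):
        SnpRecord("rs1", "1", 100, "AC", "T")
    with pytest.raises(ValueError):
        SnpRecord("rs1", "1", 100, "A", "A")
    s = SnpRecord("rs1", "chr1", 100, "a", "t", {"EUR": 0.9, "AFR": 0.6})
    assert s.chrom == "1" and s.ref_allele == "A" and s.alt_allele == "T"
    assert s.max_folded_maf() == pytest.approx(0.4)
    assert SnpRecord("rs2", "1", 1, "C", "G").max_folded_maf() is None


def _site_on(strand, g_start=1001):
    mir = MicroRNA.from_string("m", "UAGCUUAUCAGACUGAUGUUGA")
    p = build_site_patterns(mir)
    seq = "TTTTT" + p.pattern_8mer + "TTTTT"
    utr = NucleotideSequence("u", seq)
    placement = GenomicPlacement("1", g_start - 1, g_start - 1 + len(seq), strand)
    (hit,) = scan_utr(utr, [mir], placement=placement)
    return mir, utr, hit


def test_snp_in_site_full_enumeration_plus_strand():
    _, _, site = _site_on("+")
    for g in range(site.genomic_start, site.genomic_end + 1):
        snp = SnpRecord("rs", "1", g, "A", "C")
        u = g - site.genomic_start + 1  # mRNA 5'->3' frame index
        assert snp_in_site(site, snp, numbering="mrna") == u
        assert snp_in_site(site, snp, numbering="mir") == 9 - u
    # just outside the frame on each side
    assert snp_in_site(site, SnpRecord("rs", "1", site.genomic_start - 1, "A", "C")) is None
    assert snp_in_site(site, SnpRecord("rs", "1", site.genomic_end + 1, "A", "C")) is None
    # other chromosome
    assert snp_in_site(site, SnpRecord("rs", "2", site.genomic_start, "A", "C")) is None
    with pytest.raises(ValueError):
        snp_in_site(site, SnpRecord("rs", "1", site.genomic_start, "A", "C"), numbering="bogus")


def test_snp_in_site_full_enumeration_minus_strand():
    _, _, site = _site_on("-")
    for g in range(site.genomic_start, site.genomic_end + 1):
        snp = SnpRecord("rs", "1", g, "A", "C")
        u = site.genomic_end - g + 1
        assert snp_in_site(site, snp, numbering="mrna") == u
        assert snp_in_site(site, snp, numbering="mir") == 9 - u


def _oracle_verdict(ref_class, alt_class):
    r, a = _RANK[ref_class], _RANK[alt_class]
    if a == r:
        return "unchanged"
    if a > r:
        return "upgraded"
    return "abolished" if alt_class is None else "downgraded"


def test_classify_disruption_exhaustive_plus_strand():
    """Every frame position x every alt base, against re-derived classes."""
    mir, utr, site = _site_on("+")
    patterns = build_site_patterns(mir)
    window = utr.residues[site.window_start - 1 : site.window_end]
    n_abolished = 0
    for widx in range(8):
        ref = window[widx]
        for alt in "ACGT":
            if alt == ref:
                continue
            snp = SnpRecord("rs", "1", site.genomic_start + widx, ref, alt)
            call = classify_disruption(site, snp, mir, utr)
            alt_window = window[:widx] + alt + window[widx + 1 :]
            want_alt = classify_window(alt_window, patterns)
            assert call.ref_class == "8mer"
            assert call.alt_class == want_alt
            assert call.verdict == _oracle_verdict("8mer", want_alt)
            assert call.pos_in_mre == 9 - (widx + 1)
            n_abolished += call.verdict == "abolished"
    # seed positions 2-7 (indices 1..6): any substitution kills the site
    assert n_abolished == 6 * 3


def test_classify_disruption_minus_strand_alleles_complemented():
    mir, utr, site = _site_on("-")
    window = utr.residues[site.window_start - 1 : site.window_end]
    widx = 3  # inside the seed
    g = site.genomic_end - widx
    ref_gdna = _COMP[window[widx]]  # forward-strand allele
    alt_gdna = "A" if ref_gdna != "A" else "C"
    snp = SnpRecord("rs", "1", g, ref_gdna, alt_gdna)
    call = classify_disruption(site, snp, mir, utr)
    assert call.ref_class == "8mer" and call.verdict == "abolished"
    # a ref allele contradicting the UTR raises, naming both bases
    bad = SnpRecord("rs", "1", g, alt_gdna, ref_gdna)
    with pytest.raises(DataIntegrityError):
        classify_disruption(site, bad, mir, utr)


def test_upgrade_verdict():
    """SNP turning the A1-opposite base into A: 7mer-m8 -> 8mer."""
    mir = MicroRNA.from_string("m", "UAGCUUAUCAGACUGAUGUUGA")
    p = build_site_patterns(mir)
    seq = "TTTTT" + p.pattern_7m8 + "G" + "TTTTT"
    utr = NucleotideSequence("u", seq)
    placement = GenomicPlacement("1", 1000, 1000 + len(seq), "+")
    (site,) = scan_utr(utr, [mir], placement=placement)
    assert site.site_type == "7mer-m8"
    snp = SnpRecord("rs", "1", site.genomic_end, "G", "A")
    call = classify_disruption(site, snp, mir, utr)
    assert call.verdict == "upgraded" and call.alt_class == "8mer"
    assert call.pos_in_mre == 1  # the miR-position-1 opposite base


def test_summarize_by_seed_type(world, mirs_by_name, utrs_by_name):
    utrs = {u.name: u for u in world.utrs}
    calls = []
    for utr in world.utrs:
        sites = scan_utr(utr, world.mirs, placement=world.placements[utr.name])
        for site in sites:
            for snp in world.snps:
                if snp.chrom == site.chrom and snp_in_site(site, snp) is not None:
                    calls.append(
                        classify_disruption(site, snp, mirs_by_name[site.mir_name], utrs[site.utr_name])
                    )
    counts = summarize_by_seed_type(calls)
    assert sum(counts.values()) == len([c for c in calls if c.ref_class])
    assert set(counts) <= {"8mer", "7mer-m8", "7mer-A1", "6mer"}
    assert counts.total() >= len(world.truth_snps.query("kind == 'disruption'"))


def test_read_vcf_filters_and_frequencies(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AF_EUR,Number=1,Type=Float,Description="x">\n'
        "##contig=<ID=1,length=100000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "1\t100\trs1\tA\tT\t.\t.\tAF_EUR=0.25\n"
        "1\t200\trs2\tA\tT,C\t.\t.\t.\n"  # multi-allelic: dropped
        "1\t300\trs3\tAT\tA\t.\t.\t.\n"  # indel: dropped
        "1\t400\t.\tG\tC\t.\t.\t.\n"  # no ID: synthesised
    )
    snps = read_vcf_snps(vcf, pop_af_keys={"EUR": "AF_EUR"})
    assert [s.rsid for s in snps] == ["rs1", "1:400"]
    assert snps[0].pop_freqs == {"EUR": pytest.approx(0.25)}
    assert snps[1].pop_freqs == {}


def test_world_vcf_round_trip(world, tmp_path):
    from seedvar.simulate import write_world

    paths = write_world(world, tmp_path / "bundle")
    cfg_keys = {p: f"AF_{p}" for p in world.group_freqs["group"].unique()}
    snps = read_vcf_snps(paths["vcf"], pop_af_keys=cfg_keys)
    assert len(snps) == len(world.snps)
    by_id = {s.rsid: s for s in snps}
    for orig in world.snps[:50]:
        back = by_id[orig.rsid]
        assert (back.chrom, back.pos, back.ref_allele, back.alt_allele) == (
            orig.chrom, orig.pos, orig.ref_allele, orig.alt_allele
        )
        for pop, f in orig.pop_freqs.items():
            assert back.pop_freqs[pop] == pytest.approx(f, abs=1e-4)
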