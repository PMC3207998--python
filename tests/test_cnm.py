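"""Created-site (CNM) detection and the proxy duplex scorer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedvar.creation import (
    ProxyScoringParams,
    SnpWindow,
    detect_created_sites,
    duplex_score,
    extract_window,
)
from seedvar.seedcore import (
    GenomicPlacement,
    MicroRNA,
    NucleotideSequence,
    build_site_patterns,
    reverse_complement,
)
from seedvar.variants import SnpRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# --- window extraction -----------------------------------------------------


def test_extract_window_center():
    seq = "".join("ACGT"[i % 4] for i in range(100))
    utr = NucleotideSequence("u", seq)
    snp = SnpRecord("rs", "1", 50, seq[49], "A" if seq[49] != "A" else "C")
    w = extract_window(utr, snp, utr_pos=50)
    assert len(w.sequence_ref) == 45 and w.snp_offset == 23
    assert w.sequence_ref == seq[27:72]
    assert w.sequence_alt[22] == snp.alt_allele
    assert w.sequence_ref[:22] == w.sequence_alt[:22]


def test_extract_window_sentinel_padding():
    seq = "ACGTACGTAC"
    utr = NucleotideSequence("u", seq)
    snp = SnpRecord("rs", "1", 2, "C", "G")
    w = extract_window(utr, snp, utr_pos=2)
    assert len(w.sequence_ref) == 45
    assert w.sequence_ref.startswith("N" * 21 + "A")
    assert w.sequence_ref.endswith("N" * (22 - 8))


def test_extract_window_via_placement_minus_strand():
    seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"
    utr = NucleotideSequence("u", seq)
    placement = GenomicPlacement("1", 1000, 1000 + len(seq), "-")
    utr_pos = 25
    g = placement.utr_to_genomic(utr_pos)
    ref_mrna = seq[utr_pos - 1]
    snp = SnpRecord("rs", "1", g, _COMP[ref_mrna], _COMP["A" if ref_mrna != "A" else "C"])
    w = extract_window(utr, snp, placement=placement)
    assert w.sequence_ref[22] == ref_mrna
    # mismatching ref allele is rejected
    bad = SnpRecord("rs", "1", g, ref_mrna, "A" if ref_mrna != "A" else "C")
    if _COMP[ref_mrna] != ref_mrna:
        with pytest.raises(ValueError):
            extract_window(utr, bad, placement=placement)


def test_snp_window_invariants():
    with pytest.raises(ValueError):
        SnpWindow(SnpRecord("rs", "1", 1, "A", "C"), "ACGT", "ACG")
    with pytest.raises(ValueError):  # differs at the wrong offset
        SnpWindow(SnpRecord("rs", "1", 1, "A", "C"), "AAAA", "AACA", snp_offset=1)


# --- proxy duplex scorer ---------------------------------------------------


def _oracle_duplex(mir_seq: str, target: str, p: ProxyScoringParams):
    """Independent NumPy Smith-Waterman over the same scheme (score only)."""
    q = mir_seq
    t = target.upper().replace("U", "T")[::-1]
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    H = np.zeros((len(q) + 1, len(t) + 1))
    for i in range(1, len(q) + 1):
        for j in range(1, len(t) + 1):
            pair = (q[i - 1], t[j - 1])
            if "N" in pair:
                s = p.mismatch
            elif pair in wc:
                s = p.match_wc
            elif pair in gu:
                s = p.match_gu
            else:
                s = p.mismatch
            if 2 <= i <= 8:
                s *= p.seed_weight
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, H[i - 1, j] + p.gap, H[i, j - 1] + p.gap)
    return H.max()


def test_perfect_duplex_reference_values():
    mir = MicroRNA.from_string("m", "ACGUACGUACGUACGUACGUA")
    target = reverse_complement(mir.sequence.residues)
    score, energy = duplex_score(mir, target)
    # 21 WC pairs, 7 seed-doubled: 5*(21 + 7) = 140
    assert score == pytest.approx(140.0)
    gc = sum(b in "GC" for b in mir.sequence.residues)
    assert energy == pytest.approx(-(3 * gc + 2 * (21 - gc)))


def test_duplex_score_orderings():
    mir = MicroRNA.from_string("m", "UAGCUUAUCAGACUGAUGUUGA")
    perfect = reverse_complement(mir.sequence.residues)
    score_p, energy_p = duplex_score(mir, perfect)
    # break two seed pairs: score and energy must both worsen
    broken = list(perfect)
    L = len(perfect)
    for k in (L - 3, L - 5):  # opposite miR positions 3 and 5
        broken[k] = "A" if broken[k] != "A" else "C"
    score_b, energy_b = duplex_score(mir, "".join(broken))
    assert score_b < score_p and energy_b > energy_p
    with pytest.raises(ValueError):
        duplex_score(mir, "ACGT")


def test_sentinel_never_pairs():
    mir = MicroRNA.from_string("m", "UAGCUUAUCAGACUGAUGUUGA")
    score, energy = duplex_score(mir, "N" * 30)
    assert score == 0.0 and energy == 0.0


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=10)
def test_duplex_score_matches_oracle_dp(seed):
    rng = np.random.default_rng(seed)
    mir_seq = "".join(rng.choice(list("ACGT"), size=21))
    target = "".join(rng.choice(list("ACGT"), size=45))
    mir = MicroRNA.from_string("m", mir_seq)
    score, _ = duplex_score(mir, target)
    assert score == pytest.approx(_oracle_duplex(mir_seq, target, ProxyScoringParams()))


# --- creation detection ----------------------------------------------------


def _creation_window(mir: MicroRNA):
    """45-base window where the alt allele completes an 8mer at the SNP."""
    p = build_site_patterns(mir)
    # pairs miR positions 2..end perfectly and ends in the 8mer pattern
    full = reverse_complement(mir.sequence.residues[1:]) + "A"
    # lay out the window so the 8mer's 4th frame base (a seed pair) is offset 23
    i = 19  # 0-based start of the 8mer frame in the window
    pad_left = i - (len(full) - 8)
    assert pad_left >= 0
    alt_seq = "T" * pad_left + full + "T" * (45 - pad_left - len(full))
    assert len(alt_seq) == 45 and alt_seq[i : i + 8] == p.pattern_8mer
    widx = i + 3
    alt_base = alt_seq[widx]
    ref_base = "A" if alt_base != "A" else "C"
    ref_seq = alt_seq[:widx] + ref_base + alt_seq[widx + 1 :]
    assert widx == 22, "window layout must put the SNP at offset 23"
    snp = SnpRecord("rs_c", "1", 500, ref_base, alt_base)
    return SnpWindow(snp, ref_seq, alt_seq), i + 1


def test_detect_created_sites_planted_8mer():
    mir = MicroRNA.from_string("m", "UAGCUUAUCAGACUGAUGUUGA")
    window, frame_start = _creation_window(mir)
    hits = detect_created_sites(window, [mir])
    assert len(hits) == 1
    h = hits[0]
    assert h.site_type == "8mer" and h.window_offset == frame_start
    assert h.ref_class is None
    assert h.pairing_score >= 70 and h.energy_proxy <= -20


def test_strict_creation_excludes_downgrades():
    """A SNP breaking the A1 base (8mer -> 7mer-m8) is not a creation event."""
    mir = MicroRNA.from_string("m", "UAGCUUAUCAGACUGAUGUUGA")
    p = build_site_patterns(mir)
    # ref window holds a full 8mer whose A1 base sits at the SNP offset
    left = "T" * 15
    ref = left + p.pattern_8mer + "T" * (45 - 15 - 8)
    widx = 15 + 7  # 0-based A1 position = offset 23
    alt = ref[:widx] + "C" + ref[widx + 1 :]
    w = SnpWindow(SnpRecord("rs", "1", 1, "A", "C"), ref, alt, snp_offset=23)
    strict = detect_created_sites(w, [mir], require_strict_creation=True)
    # at the 8mer frame the alt allele only downgrades: no strict hit there
    assert not any(h.window_offset == 16 for h in strict)
    relaxed = detect_created_sites(w, [mir], require_strict_creation=False)
    # relaxed semantics accept the surviving 7mer-m8 at that frame
    assert any(h.window_offset == 16 and h.site_type == "7mer-m8" for h in relaxed)


def test_detect_created_sites_score_filter():
    """Raising score_min above the perfect-duplex score suppresses all hits."""
    mir = MicroRNA.from_string("m", "UAGCUUAUCAGACUGAUGUUGA")
    window, _ = _creation_window(mir)
    assert detect_created_sites(window, [mir], ProxyScoringParams(score_min=1e9)) == []
    assert detect_created_sites(window, [mir], ProxyScoringParams(energy_max=-1e9)) == []


def test_detect_created_sites_frames_contain_snp():
    """Frames not containing the SNP offset are never reported."""
    mir = MicroRNA.from_string("m", "UAGCUUAUCAGACUGAUGUUGA")
    p = build_site_patterns(mir)
    # an 8mer far from the SNP plus a creation at the SNP
    window, _ = _creation_window(mir)
    decorated_alt = p.pattern_8mer + window.sequence_alt[8:]
    decorated_ref = p.pattern_8mer + window.sequence_ref[8:]
    w = SnpWindow(window.snp, decorated_ref, decorated_alt, snp_offset=23)
    for h in detect_created_sites(w, [mir]):
        assert h.window_offset <= 23 <= h.window_offset + 7


def test_relaxed_semantics_superset():
    mir = MicroRNA.from_string("m", "UAGCUUAUCAGACUGAUGUUGA")
    window, _ = _creation_window(mir)
    strict = detect_created_sites(window, [mir], require_strict_creation=True)
    relaxed = detect_created_sites(window, [mir], require_strict_creation=False)
    strict_keys = {(h.mir_name, h.window_offset) for h in strict}
    relaxed_keys = {(h.mir_name, h.window_offset) for h in relaxed}
    assert strict_keys <= relaxed_keys


def test_simulated_creation_events_all_recovered(world, mirs_by_name, utrs_by_name):
    truth = world.truth_snps.query("kind == 'creation'")
    snps = {s.rsid: s for s in world.snps}
    found = 0
    for row in truth.itertuples():
        utr = utrs_by_name[row.utr]
        window = extract_window(utr, snps[row.rsid], placement=world.placements[row.utr])
        hits = detect_created_sites(window, world.mirs)
        if any(h.mir_name == row.mir and h.site_type == row.site_type for h in hits):
            found += 1
    assert found == len(truth)
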