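"""Detector unit tests and brute-force property checks."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from atf4queue import scanner
from atf4queue.energy import (
    STACK,
    TERMINAL_AU,
    hairpin_energy_from_pairs,
    hairpin_loop_energy,
    predict_hairpins,
)
from atf4queue.scanner import (
    PICFootprintModel,
    classify_start_context,
    find_frameshift_signals,
    find_near_cognate_starts,
    find_orfs,
    queue_capacity,
    scan_methylation_motifs,
    stalled_psite_window,
)
from atf4queue.types import NEAR_COGNATE_CODONS, STOP_CODONS, StStElement, UORF

rna = st.text(alphabet="ACGU", min_size=10, max_size=60)


# ---------------------------------------------------------------------------
# Kozak context

@pytest.mark.parametrize(
    "seq,pos,expected",
    [
        ("GCCACCAUGG", 7, "strong"),   # canonical optimal context
        ("UUUUUUAUGU", 7, "weak"),     # neither determinant
        ("AAAAAAAUGC", 7, "medium"),   # -3 purine only
        ("UUUUUUAUGG", 7, "medium"),   # +4 G only
    ],
)
def test_context_rule_table(seq, pos, expected):
    assert classify_start_context(seq, pos).label == expected


def test_context_truncated_is_weak():
    ctx = classify_start_context("AUGCCC", 1)
    assert ctx.label == "weak" and ctx.truncated


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_context_depends_only_on_minus3_plus4(data):
    """Randomising every base except -3/+4 never changes the class."""
    m3 = data.draw(st.sampled_from("ACGU"))
    p4 = data.draw(st.sampled_from("ACGU"))
    cls = None
    for _ in range(3):
        pre = data.draw(st.text(alphabet="ACGU", min_size=2, max_size=2))
        post = data.draw(st.text(alphabet="ACGU", min_size=2, max_size=2))
        seq = pre + m3 + "XX" + "AUG" + p4 + post
        seq = seq.replace("X", data.draw(st.sampled_from("ACGU")))
        got = classify_start_context(seq, 6).label
        if cls is None:
            cls = got
        assert got == cls


# ---------------------------------------------------------------------------
# ORFs / start-stops

def test_start_stop_definition():
    orfs = find_orfs("AUGUAACCC", (1, 7))
    assert len(orfs) == 1 and isinstance(orfs[0], StStElement)
    assert orfs[0].start == 1 and orfs[0].stop == 4


def test_three_codon_uorf():
    orfs = find_orfs("AUG" + "CAACAACAA" + "UGA", (1, 1))
    (u,) = orfs
    assert isinstance(u, UORF) and u.n_codons == 3


def test_reference_uorf2_sixty_codons_minus_one_frame(reference):
    u2 = max(reference.uorfs, key=lambda u: u.n_codons)
    assert u2.n_codons == 60
    assert u2.frame_vs_cds == -1
    assert not u2.rei_permissive  # overlaps the main ORF


def test_stopless_orf_flagged():
    orfs = find_orfs("AUGCAACAACAA", (1, 1))
    assert orfs[0].stopless


def _brute_orfs(seq, region):
    """Independent enumeration: every AUG, walk codons to the first stop."""
    out = []
    for pos in range(region[0], region[1] + 1):
        if seq[pos - 1 : pos + 2] != "AUG":
            continue
        stop = None
        p = pos + 3
        while p + 2 <= len(seq):
            if seq[p - 1 : p + 2] in STOP_CODONS:
                stop = p
                break
            p += 3
        out.append((pos, stop))
    return out


@given(rna)
@settings(max_examples=500, deadline=None)
def test_find_orfs_matches_brute_force(seq):
    region = (1, max(1, len(seq) - 2))
    got = [
        (o.start, (o.stop if not getattr(o, "stopless", False) else None))
        for o in find_orfs(seq, region)
    ]
    assert got == _brute_orfs(seq, region)


@given(rna)
@settings(max_examples=500, deadline=None)
def test_near_cognates_match_brute_force(seq):
    region = (1, max(1, len(seq) - 2))
    got = {(s.position, s.codon) for s in find_near_cognate_starts(seq, region)}
    want = {
        (p, seq[p - 1 : p + 2])
        for p in range(region[0], region[1] + 1)
        if seq[p - 1 : p + 2] in NEAR_COGNATE_CODONS
    }
    assert got == want
    assert all(c != "AUG" for _, c in got)


# ---------------------------------------------------------------------------
# methylation motifs

def test_drach_motif_classes():
    (site,) = scan_methylation_motifs("GGACU")
    assert site.motif_class == frozenset({"DRACH", "RRACH"})
    (site,) = scan_methylation_motifs("UGACC")
    assert site.motif_class == frozenset({"DRACH"})
    assert scan_methylation_motifs("CCACC") == []  # D=C invalid


@given(rna)
@settings(max_examples=500, deadline=None)
def test_methylation_matches_brute_force(seq):
    got = {s.position for s in scan_methylation_motifs(seq)}
    want = set()
    for i in range(2, len(seq) - 2):
        d, r, a, c, h = seq[i - 2 : i + 3]
        if d in "AGU" and r in "AG" and a == "A" and c == "C" and h in "ACU":
            want.add(i + 1)
    assert got == want


def test_reference_methyl_analogs(reference):
    positions = {s.position for s in reference.methyl_sites}
    assert {225, 235, 286, 326} <= positions
    # control adenines are plain A's outside any motif
    assert reference.base(267) == "A" and 267 not in positions
    assert reference.base(311) == "A" and 311 not in positions


# ---------------------------------------------------------------------------
# hairpins

def test_perfect_stem_energy_hand_sum():
    """A GC-clamped 5-bp stem + 4-nt loop scores as the sum of its four
    stack terms plus the tetraloop penalty."""
    seq = "GGGGGAAAACCCCC"
    (hp,) = predict_hairpins(seq, min_stem=5, window=len(seq))
    by_hand = 4 * STACK[("GC", "GC")] + hairpin_loop_energy(4)
    assert hp.delta_G == pytest.approx(by_hand, abs=0.01)
    assert hp.five_prime_base == 1 and hp.three_prime_end == 14


def test_poly_a_has_no_hairpin():
    assert predict_hairpins("A" * 50) == []


def test_reported_energy_matches_pair_hand_sum(reference):
    """Internal consistency: every reported hairpin's delta_G equals the
    hand-summed energy of its own pair list."""
    for hp in predict_hairpins(reference.sequence[:420]):
        e = hairpin_energy_from_pairs(reference.sequence, list(hp.pairs))
        assert hp.delta_G == pytest.approx(e, abs=0.01)


def test_window_shorter_than_stem_raises():
    with pytest.raises(ValueError):
        predict_hairpins("GGGAAACCC" * 4, min_stem=4, window=8)


def test_reference_sl3(reference):
    sl = min(reference.stem_loops, key=lambda h: h.delta_G)
    assert sl.five_prime_base == 318
    assert sl.delta_G <= -15.0
    assert abs(sl.delta_G - (-15.40)) <= 2.0  # printed value, model tolerance
    lo, hi = sl.loop_interval
    assert lo <= 331 and 333 <= hi  # AUG3 exposed in the loop
    stem = {p for pair in sl.pairs for p in pair}
    assert 326 in stem  # RRACH2 adenine analog pairs in the stem


# ---------------------------------------------------------------------------
# queue geometry

@pytest.mark.parametrize(
    "d,f,capacity,remainder",
    [(150, 30, 5, 0), (29, 30, 0, 29), (132, 30, 4, 12), (60, 30, 2, 0)],
)
def test_queue_capacity_arithmetic(d, f, capacity, remainder):
    g = queue_capacity(100, 100 + d, f)
    assert g.capacity == capacity and g.remainder == remainder
    assert len(g.psite_positions) == capacity
    if capacity:
        assert g.psite_positions[0] == 100
        assert all(b - a == f for a, b in zip(g.psite_positions, g.psite_positions[1:]))


def test_queue_capacity_reference_geometry(reference):
    m = reference.manifest
    g = queue_capacity(m["uORF2_start"], m["SL3_five_prime_base"], 30)
    assert g.capacity == 5


@given(st.integers(31, 400), st.integers(1, 5))
@settings(max_examples=200, deadline=None)
def test_queue_capacity_monotone_and_scaling(d, k):
    base = queue_capacity(10, 10 + d, 30).capacity
    assert queue_capacity(10, 10 + d + 30, 30).capacity >= base
    assert queue_capacity(10, 10 + k * d, k * 30).capacity == base


def test_queue_upstream_of_start_raises():
    with pytest.raises(ValueError):
        queue_capacity(100, 90, 30)


# ---------------------------------------------------------------------------
# stalled-PIC window

def test_stalled_psite_reaches_cug(reference):
    sl = reference.manifest["SL3_five_prime_base"]
    (lo, hi), sites = stalled_psite_window(reference, sl)
    cug = [s for s in sites if s.codon == "CUG"]
    assert cug and cug[0].position == sl - 20
    assert lo <= sl - 20 <= hi


def test_stalled_psite_zero_window_is_exact(reference):
    sl = reference.manifest["SL3_five_prime_base"]
    model = PICFootprintModel(migration_window=0)
    (lo, hi), sites = stalled_psite_window(reference, sl, model)
    assert lo == hi == sl - 20
    assert all(s.position == sl - 20 for s in sites)


def test_stalled_psite_empty_when_no_codons():
    leader = scanner.annotate_leader("ACACAC" * 12 + "AUG" + "CAA" * 4, 73)
    (_, _), sites = stalled_psite_window(leader, 40)
    assert sites == []


# ---------------------------------------------------------------------------
# frameshift signals

def test_slippery_plus_ctract_optimal_spacing():
    seq = "GGAGGCGGG" + "AUAAUAAU" + "CCCCCUUCGACC" + "AAAA"
    sigs = find_frameshift_signals(seq, (1, len(seq)), frame_anchor=1)
    fs = [s for s in sigs if s.kind == "FS-A"]
    assert fs and fs[0].interval == (1, 9)
    assert fs[0].spacing_to_ctract == 8 and fs[0].optimal_spacing


def test_no_signals_in_balanced_sequence():
    seq = "ACGUACGUACGUACGUACGUACGUACGUACGU"
    assert find_frameshift_signals(seq, (1, len(seq))) == []


def test_reference_fs_a_triple_glycine(reference):
    fs = [f for f in reference.frameshift_signals if f.kind == "FS-A"]
    assert fs and fs[0].interval[0] == 318
    codons = [reference.slice(p, p + 2) for p in (318, 321, 324)]
    assert all(c.startswith("GG") for c in codons)  # three glycines
    assert fs[0].optimal_spacing


# ---------------------------------------------------------------------------
# orchestration round trip

def test_annotate_roundtrip_identity(reference):
    again = scanner.annotate_leader(reference.sequence, reference.cds_start,
                                    name=reference.name)
    assert again.st_st == reference.st_st
    assert again.uorfs == reference.uorfs
    assert again.start_sites == reference.start_sites
    assert again.stem_loops == reference.stem_loops
    assert again.frameshift_signals == reference.frameshift_signals
    assert {s.position for s in again.methyl_sites} == {
        s.position for s in reference.methyl_sites
    }


def test_annotate_without_upstream_augs():
    leader = scanner.annotate_leader("ACACAC" * 10 + "AUGCAACAA", 61)
    assert leader.uorfs == [] and leader.st_st == []
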