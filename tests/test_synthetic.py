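"""Reference leader, construct registry, random leaders, synthetic reads."""

import numpy as np
import pytest
from scipy import stats

from atf4queue import synthetic
from atf4queue.energy import predict_hairpins
from atf4queue.io import write_fasta
from atf4queue.scanner import queue_capacity
from atf4queue.synthetic import (
    ArchitectureSpec,
    apply_construct,
    apply_edits,
    construct_registry,
    generate_synthetic_footprints,
    load_leader_fasta,
    random_leader,
)
from atf4queue.types import reverse_edits


# ---------------------------------------------------------------------------
# reference manifest

def test_reference_manifest_architecture(reference):
    m = reference.manifest
    assert m["uORF1_n_codons"] == 3
    assert m["uORF2_n_codons"] == 60
    assert m["uORF2_frame_vs_cds"] == -1
    assert m["uORF2_AUG_to_SL3_nt"] == 150
    assert m["CUG_to_SL3_nt"] == 20
    assert m["CUG_context"] == "weak"
    assert m["AUG2_pos"] == m["AUG1_pos"] + 6          # two codons downstream
    assert m["AUG3_pos"] == m["AUG1_pos"] + 48         # 17th codon after AUG1
    assert m["AUG1_context"] == "medium" and m["AUG2_context"] == "medium"
    assert m["AUG3_context"] == "weak"
    assert m["SL3_delta_G"] <= -15.0
    assert 286 == m["AUG1_pos"] + 3                    # DRACH2 A adjacent to AUG1


def test_reference_is_deterministic(reference):
    synthetic.build_reference_leader.cache_clear()
    again = synthetic.build_reference_leader()
    assert again.sequence == reference.sequence


def test_reference_cug_in_main_frame(reference):
    cug = [s for s in reference.start_sites if s.codon == "CUG"]
    assert len(cug) == 1
    assert cug[0].frame_vs_cds == 0


# ---------------------------------------------------------------------------
# FASTA round trip

def test_fasta_roundtrip(tmp_path, reference):
    path = write_fasta(reference, tmp_path / "ref.fa")
    again = load_leader_fasta(path, reference.cds_start)
    assert again.sequence == reference.sequence
    assert again.manifest["uORF2_n_codons"] == 60


def test_fasta_multi_record_rejected(tmp_path):
    p = tmp_path / "two.fa"
    p.write_text(">a\nAUGCAA\n>b\nAUGCAA\n")
    with pytest.raises(ValueError, match="multi-record"):
        load_leader_fasta(p, 1)


def test_fasta_wrong_cds_codon_names_found_codon(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text(">a\nACGUACGUACGU\n")
    with pytest.raises(ValueError, match="ACG"):
        load_leader_fasta(p, 5)


def test_fasta_dna_is_transcribed(tmp_path):
    p = tmp_path / "dna.fa"
    p.write_text(">a\n" + "ACACAC" * 6 + "ATGCAACAT\n")
    leader = load_leader_fasta(p, 37)
    assert "T" not in leader.sequence


# ---------------------------------------------------------------------------
# constructs

def test_d_all_removes_upstream_augs(reference):
    mut = apply_construct(reference, "d-all")
    assert mut.st_st == [] and mut.uorfs == []
    assert mut.sequence[:282].count("AUG") == 0


def test_sl3mut1_unfolds_the_hairpin(reference):
    mut = apply_construct(reference, "SL3Mut-1")
    assert all(h.delta_G > -10 for h in predict_hairpins(mut.sequence))


def test_sl3mut2_unfolds_the_hairpin(reference):
    mut = apply_construct(reference, "SL3Mut-2")
    assert all(h.delta_G > -10 for h in predict_hairpins(mut.sequence))


def test_wt_ins_moves_sl3_by_180(reference):
    mut = apply_construct(reference, "wt_ins")
    assert len(mut.sequence) == len(reference.sequence) + 180
    assert mut.manifest["AUG1_to_SL3_nt"] == reference.manifest["AUG1_to_SL3_nt"] + 180
    # the hairpin itself is untouched: same pairs, shifted
    ref_sl = reference.stem_loops[0]
    mut_sl = min(mut.stem_loops, key=lambda h: h.delta_G)
    assert mut_sl.delta_G == ref_sl.delta_G
    assert [(a - 180, b - 180) for a, b in mut_sl.pairs] == list(ref_sl.pairs)


def test_uorf2_ins_extends_uorf2(reference):
    mut = apply_construct(reference, "uORF2_ins")
    u2 = max(mut.uorfs, key=lambda u: u.n_codons)
    assert u2.n_codons == 160  # 60 + 100 inserted codons
    assert mut.manifest["CUG_to_SL3_nt"] == 20  # local geometry unchanged


def test_cugmut_removes_the_cug(reference):
    mut = apply_construct(reference, "CUGMut")
    assert not any(s.codon == "CUG" for s in mut.start_sites)


def test_unknown_construct_rejected(reference):
    with pytest.raises(KeyError, match="bogus"):
        apply_construct(reference, "bogus")


def test_edit_base_mismatch_rejected(reference):
    from atf4queue.types import Edit

    with pytest.raises(ValueError, match="mismatch"):
        apply_edits(reference, (Edit("substitution", position=339, old="G", new="A"),))


def test_substitution_constructs_are_reversible(reference):
    """Applying a substitution construct then its reverse edits restores
    the reference byte-for-byte."""
    reg = construct_registry()
    for cid in ("SL3Mut-1", "SL3Mut-2", "CUGMut", "A235G", "A326G"):
        spec = reg[cid]
        mutated = apply_construct(reference, cid)
        back = apply_edits(mutated, reverse_edits(spec))
        assert back == reference.sequence, cid


def test_methylation_state_tracks_edits(reference):
    wt = {s.position: s.modified_nonstress for s in reference.methyl_sites}
    assert wt[235] and wt[326]
    m = apply_construct(reference, "A235G")
    pos = {s.position: s.modified_nonstress for s in m.methyl_sites}
    assert 235 not in pos and pos[326]
    ins = apply_construct(reference, "uORF2_ins")
    pos = {s.position: s.modified_nonstress for s in ins.methyl_sites}
    assert pos[235 + 300] and pos[326 + 300]  # shifted analogs still flagged


# ---------------------------------------------------------------------------
# random leaders

def test_random_leader_deterministic():
    spec = ArchitectureSpec()
    a = random_leader(spec, seed=11)
    b = random_leader(spec, seed=11)
    assert a.sequence == b.sequence


def test_random_leader_no_uorfs():
    spec = ArchitectureSpec(n_uorfs=(0, 0))
    leader = random_leader(spec, seed=1)
    assert leader.uorfs == [] and leader.st_st == []


@pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
def test_random_leader_stall_to_start_queue_capacity(k):
    spec = ArchitectureSpec(
        leader_length=(260, 260), n_uorfs=(1, 1), uorf_codons=(2, 2),
        hairpin_stem=8, stall_to_start=30 * k,
    )
    leader = random_leader(spec, seed=5 + k)
    u = leader.uorfs[0]
    sl = leader.stem_loops[0]
    assert sl.five_prime_base - u.start == 30 * k
    assert queue_capacity(u.start, sl.five_prime_base, 30).capacity == k


def test_random_leader_invariants_over_many_seeds():
    spec = ArchitectureSpec(n_uorfs=(0, 2), hairpin_stem=5)
    for seed in range(200):
        leader = random_leader(spec, seed=seed)
        leader.validate()


def test_random_leader_infeasible_spec():
    with pytest.raises(ValueError, match="infeasible"):
        ArchitectureSpec(leader_length=(20, 30), n_uorfs=(3, 3),
                         uorf_codons=(8, 8)).validate()


# ---------------------------------------------------------------------------
# synthetic footprints

def test_point_mass_reads_peak_at_p():
    dens = np.zeros(200)
    dens[99] = 1.0  # position 100
    reads = generate_synthetic_footprints(dens, depth=1000, read_length_dist=30, seed=7)
    assert len(reads) == 1000
    assert (reads.psite == 100).all()
    assert (reads.length == 30).all()
    assert (reads.start == 88).all()


def test_uniform_density_counts_within_4sd():
    L, depth = 50, 20000
    reads = generate_synthetic_footprints(np.ones(L), depth=depth, seed=3)
    counts = reads.psite.value_counts().reindex(range(1, L + 1), fill_value=0)
    expect = depth / L
    sd = np.sqrt(depth * (1 / L) * (1 - 1 / L))
    assert (np.abs(counts - expect) < 4 * sd).all()


def test_two_point_masses_disome_spacing():
    dens = np.zeros(300)
    dens[99] = dens[159] = 1.0  # 60 nt apart
    reads = generate_synthetic_footprints(dens, depth=4000, read_length_dist=60, seed=5)
    top = reads.start.value_counts().index[:2]
    assert abs(top[0] - top[1]) == 60


def test_footprint_chi_square_convergence():
    rng = np.random.default_rng(0)
    dens = rng.random(40) + 0.05
    depth = 100_000
    reads = generate_synthetic_footprints(dens, depth=depth, seed=12)
    counts = reads.psite.value_counts().reindex(range(1, 41), fill_value=0).to_numpy()
    expected = dens / dens.sum() * depth
    chi2 = ((counts - expected) ** 2 / expected).sum()
    p = 1 - stats.chi2.cdf(chi2, df=39)
    assert p > 0.001


def test_footprint_generator_rejects_bad_input():
    with pytest.raises(ValueError):
        generate_synthetic_footprints(np.ones(10), depth=0)
    with pytest.raises(ValueError):
        generate_synthetic_footprints(-np.ones(10), depth=10)
    with pytest.raises(ValueError):
        generate_synthetic_footprints(np.zeros(10), depth=10)
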