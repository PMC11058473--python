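"""Engine unit tests, invariants and oracle-equivalence checks."""

import math

import numpy as np
import pytest

from atf4queue import SimulationParams, simulate
from atf4queue.oracles import analytic_small_model, markov_oracle
from atf4queue.scanner import annotate_leader

from conftest import make_toy_leader


def _se(p, n):
    return math.sqrt(max(p * (1 - p), 1e-12) / n)


# ---------------------------------------------------------------------------
# basic behaviour

def test_zero_loading_gives_zero_counts(reference, fast_params):
    res = simulate(reference, fast_params.with_(k_load=0.0), t_max=200, seed=1)
    assert res.loads == 0
    assert res.initiation_counts == {} and res.protein_outputs == {}


def test_certain_initiation_all_loads_convert(fast_params):
    """A single main AUG with p_init -> 1 and ample time converts every
    load into a completed protein."""
    leader = annotate_leader("ACACAC" * 8 + "AUGCAACAUCAACAU", 49)
    par = fast_params.with_(
        p_tc_at_load=1.0,
        p_init={"AUG": {"strong": 0.999999, "medium": 0.999999, "weak": 0.999999}},
    )
    res = simulate(leader, par, t_max=3000, seed=2)
    assert res.loads > 100
    assert res.scanned_off == 0
    out = res.main_orf_output()
    assert out + res.active_at_end == res.loads


def test_seed_determinism(reference, fast_params):
    a = simulate(reference, fast_params, t_max=400, seed=9, record_log=True)
    b = simulate(reference, fast_params, t_max=400, seed=9, record_log=True)
    assert a.event_log == b.event_log
    assert a.initiation_counts == b.initiation_counts
    c = simulate(reference, fast_params, t_max=400, seed=10, record_log=True)
    assert c.event_log != a.event_log


def test_conservation_identity_many_runs(reference, fast_params):
    for seed in range(8):
        res = simulate(reference, fast_params, t_max=300, seed=seed)
        assert res.conservation_ok()


def test_t_max_must_be_positive(reference, fast_params):
    with pytest.raises(ValueError):
        simulate(reference, fast_params, t_max=0, seed=1)


def test_footprint_larger_than_track_rejected(fast_params):
    leader = annotate_leader("ACAC" + "AUGUAACAA" + "ACAC", 5)
    with pytest.raises(ValueError):
        simulate(leader, fast_params, t_max=10, seed=1)


# ---------------------------------------------------------------------------
# exclusion and queue geometry

def test_exclusion_no_footprint_overlap(reference):
    """Footprints of distinct ribosomes never overlap in any snapshot."""
    par = SimulationParams(k_load=0.6, p_tc_at_load=1.0, k0_unwind=0.2)
    res = simulate(reference, par, t_max=900, seed=4, snapshot_interval=3.0)
    up = par.pic_footprint.upstream_of_psite
    checked = 0
    for _, snap in res.snapshots:
        spans = []
        for species, ps, _ in snap:
            hi = ps + (par.pic_footprint.downstream_of_psite - 1 if species == 0
                       else par.footprint_80S - 1 - up)
            spans.append((ps - up, hi))
        spans.sort()
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            assert h1 < l2
            checked += 1
    assert checked > 100


def test_queue_bound_and_spacing(reference):
    """The 80S queue between the uORF2 AUG and SL3 never exceeds the
    geometric capacity (5), and packed neighbours sit exactly 30 nt apart."""
    par = SimulationParams(k_load=0.8, p_tc_at_load=1.0, k0_unwind=0.02,
                           queue_boost=8.0)
    res = simulate(reference, par, t_max=1500, seed=11, snapshot_interval=4.0)
    u2 = reference.manifest["uORF2_start"]
    sl = reference.manifest["SL3_five_prime_base"]
    max_in_region = 0
    spacing_ok = True
    saw_full_queue = False
    for _, snap in res.snapshots:
        e80 = sorted(ps for sp, ps, _ in snap if sp != 0 and u2 <= ps < sl)
        max_in_region = max(max_in_region, len(e80))
        if len(e80) >= 4:
            saw_full_queue = True
        for a, b in zip(e80, e80[1:]):
            if b - a == 30:
                continue
            if b - a < 30:
                spacing_ok = False
    assert max_in_region <= 5
    assert saw_full_queue
    assert spacing_ok


def test_no_exclusion_mode_allows_free_loading(reference, fast_params):
    par = fast_params.with_(exclusion=False, k_load=2.0)
    res = simulate(reference, par, t_max=300, seed=3)
    # expected loads ~ k_load * t_max, impossible under exclusion
    assert res.loads > 450


# ---------------------------------------------------------------------------
# oracle equivalence

def _toy_params(**kw):
    base = dict(k_load=0.05, v_scan=5.0, k_tc=1.0, tc_level=0.5,
                p_tc_at_load=0.0, p_rei_uorf=0.6, k_term=2.0)
    base.update(kw)
    return SimulationParams(**base)


TOY_CASES = [
    ("uorf+main", dict(uorf_codons=2, spacer=16), _toy_params()),
    ("no-uorf", dict(uorf_codons=0, spacer=20), _toy_params()),
    ("hairpin", dict(uorf_codons=0, spacer=10, hairpin=True),
     _toy_params(k0_unwind=0.5, p_tc_at_load=1.0)),
    ("uorf+hairpin", dict(uorf_codons=2, spacer=8, hairpin=True),
     _toy_params(k0_unwind=1.0)),
    ("low-tc", dict(uorf_codons=3, spacer=12), _toy_params(tc_level=0.15)),
]


@pytest.mark.parametrize("name,kw,par", TOY_CASES, ids=[c[0] for c in TOY_CASES])
def test_simulator_matches_markov_oracle(name, kw, par):
    """Long-run initiation fractions agree with the exact master equation
    (two ribosomes, exclusion) within 3 Monte-Carlo SEs."""
    leader, _, _ = make_toy_leader(name=name, **kw)
    mk = markov_oracle(leader, par, max_ribosomes=2)
    res = simulate(leader, par, t_max=120_000, seed=42, max_ribosomes=2,
                   record_occupancy=False)
    n = res.loads
    assert n > 2000
    for pos, frac in mk.initiation.items():
        sim = res.initiation_counts.get(pos, 0) / n
        tol = 3 * _se(frac, n) + 0.002
        assert abs(sim - frac) <= tol, (name, pos, sim, frac)
    off = res.scanned_off / n
    assert abs(off - mk.scanned_off) <= 3 * _se(mk.scanned_off, n) + 0.002


def test_single_ribosome_markov_equals_cascade():
    """With one ribosome the master equation has no exclusion and must
    equal the closed-form cascade exactly."""
    leader, _, _ = make_toy_leader(uorf_codons=2, spacer=16)
    par = _toy_params()
    mk = markov_oracle(leader, par, max_ribosomes=1)
    cas = analytic_small_model(leader, par)
    for pos in set(mk.initiation) | set(cas.initiation):
        assert mk.initiation.get(pos, 0) == pytest.approx(cas.initiation.get(pos, 0), abs=1e-9)
    assert mk.scanned_off == pytest.approx(cas.scanned_off, abs=1e-9)


def test_no_exclusion_simulator_matches_cascade(reference):
    """With exclusion disabled the stochastic engine must reproduce the
    collision-free cascade on the full reference leader."""
    par = SimulationParams(k_load=0.5, p_tc_at_load=0.0, k_tc=0.6, tc_level=0.4,
                           exclusion=False, p_rei_uorf=0.54, p_rei_stst=0.5)
    cas = analytic_small_model(reference, par)
    res = simulate(reference, par, t_max=30_000, seed=7, record_occupancy=False)
    n = res.loads
    assert n > 10_000
    for pos, frac in sorted(cas.initiation.items()):
        if frac < 5e-4:
            continue
        sim = res.initiation_counts.get(pos, 0) / n
        assert abs(sim - frac) <= 3 * _se(frac, n) + 0.002, (pos, sim, frac)


def test_markov_two_ribosomes_blocking_only_removes_flux():
    """Downstream initiation with a stall element and two ribosomes never
    exceeds the single-ribosome fraction (blocking removes flux)."""
    leader, _, cds = make_toy_leader(uorf_codons=0, spacer=10, hairpin=True)
    par = _toy_params(k0_unwind=0.05, p_tc_at_load=1.0, k_load=0.5, queue_boost=0.0)
    one = markov_oracle(leader, par, max_ribosomes=1)
    two = markov_oracle(leader, par, max_ribosomes=2)
    assert two.initiation.get(cds, 0) <= one.initiation.get(cds, 0) + 1e-9


def test_markov_fast_unwind_converges_to_no_stall():
    leader, _, cds = make_toy_leader(uorf_codons=0, spacer=10, hairpin=True)
    fast = markov_oracle(leader, _toy_params(k0_unwind=4000.0, p_tc_at_load=1.0),
                         max_ribosomes=1)
    no_stall_leader, _, cds2 = make_toy_leader(uorf_codons=0, spacer=10, hairpin=False)
    # compare initiation at the main AUG: the stall-free limit
    base = markov_oracle(no_stall_leader, _toy_params(p_tc_at_load=1.0),
                         max_ribosomes=1)
    assert fast.initiation[cds] == pytest.approx(base.initiation[cds2], rel=0.02)


# ---------------------------------------------------------------------------
# delayed reinitiation logic

def test_delayed_rei_monotone_in_tc_level():
    """On a uORF1 + main-ORF toy leader, the main-ORF initiation fraction
    decreases with TC availability (more TC -> recapture at the uORF...
    no: more TC -> the resumed 40S re-acquires TC sooner, which on a
    uORF-then-main leader *increases* main initiation; with an
    overlapping inhibitory uORF the relation inverts).  Checked exactly
    with the cascade on both architectures."""
    leader, _, cds = make_toy_leader(uorf_codons=2, spacer=16)
    fracs = []
    for tc in (0.1, 0.3, 0.6, 1.0):
        cas = analytic_small_model(leader, _toy_params(tc_level=tc))
        fracs.append(cas.initiation.get(cds, 0))
    assert all(b >= a for a, b in zip(fracs, fracs[1:]))


def test_uorf2_bearing_leader_output_decreases_with_tc(reference):
    """On the reference leader (inhibitory overlapping uORF2), main-ORF
    output falls as TC availability rises: the delayed-REI switch."""
    par = SimulationParams(k_load=0.4, p_tc_at_load=0.0, k_tc=0.5)
    outs = []
    for tc in (0.05, 0.3, 1.0):
        runs = [simulate(reference, par.with_(tc_level=tc), t_max=1000, seed=100 + k,
                         record_occupancy=False).main_orf_output() for k in range(6)]
        outs.append(np.mean(runs))
    assert outs[0] > outs[1] > outs[2]


def test_m6a_roadblock_slows_leak(reference):
    """A modified scanning-roadblock adenine reduces main-ORF output under
    the non-stress condition (it gates the leak path, not uORF2)."""
    par = SimulationParams(k_load=0.4, p_tc_at_load=1.0, tc_level=1.0)

    def out(block):
        runs = [simulate(reference, par.with_(m6a_block=block, stress=False),
                         t_max=1200, seed=300 + k, record_occupancy=False
                         ).main_orf_output() for k in range(8)]
        return np.mean(runs)

    assert out(40.0) < out(1.0)
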