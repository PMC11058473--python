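"""Continuous-time stochastic simulation of scanning, initiation,
elongation and queuing on an annotated leader.

One mRNA molecule is simulated as a 1-nt-resolution track.  43S/48S
pre-initiation complexes (PICs) load at the cap, scan 5'->3' in 1-nt
steps, acquire the ternary complex (TC) at a rate proportional to its
availability, and initiate at start codons with per-dwell probabilities
set by codon identity and Kozak context.  80S ribosomes elongate in
3-nt steps.  Every ribosome excludes others over its footprint; any
ribosome whose leading edge abuts a folded hairpin stalls until a
release event (rate k0*exp(dG_eff/dG_scale)); a PIC blocked behind
another ribosome may initiate at start codons within its migration
window at a boosted rate (the queuing route to start-codon selection).
Post-termination 40S subunits resume scanning TC-less after
REI-permissive uORFs and (with its own probability) after a start-stop.

Waiting times are exponential (Gillespie); runs are deterministic for a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import SimulationParams
from .types import STOP_CODONS, LeaderAnnotation, frame_between

# species codes
PIC = 0
E80S = 1
TERM = 2

# event codes
_LOAD, _HOP, _BIND, _INIT, _BOOST_INIT, _RELEASE = range(6)


@dataclass(frozen=True)
class StartInfo:
    position: int
    codon: str
    kind: str            # "stst" | "uorf" | "orf"
    p: float             # per-dwell initiation probability
    stop: int | None     # first base of the stop codon; None = runs off the track
    p_rei: float         # resumption probability after termination


class TrackSpec:
    """Leader + params compiled into per-position lookup tables."""

    def __init__(self, leader: LeaderAnnotation, params: SimulationParams):
        self.leader = leader
        self.params = params
        self.L = len(leader)
        seq = leader.sequence
        self.up = params.pic_footprint.upstream_of_psite
        self.pic_hi_off = params.pic_footprint.downstream_of_psite - 1
        self.e80_hi_off = params.footprint_80S - 1 - self.up
        if self.e80_hi_off < 0:
            raise ValueError("80S footprint smaller than the upstream extent")
        if params.pic_footprint.length >= self.L or params.footprint_80S >= self.L:
            raise ValueError("footprint larger than the track")

        self.starts: dict[int, StartInfo] = {}
        for st in leader.st_st:
            ctx = st.context.label if st.context else "weak"
            p = params.p_init_at(st.start, "AUG", ctx)
            self._add(StartInfo(st.start, "AUG", "stst", p, st.stop, params.p_rei_stst))
        for u in leader.uorfs:
            ctx = u.context.label if u.context else "weak"
            p = params.p_init_at(u.start, "AUG", ctx)
            stop = None if u.stopless else u.stop
            p_rei = params.p_rei_uorf if u.rei_permissive else 0.0
            self._add(StartInfo(u.start, "AUG", "uorf", p, stop, p_rei))
        for s in leader.start_sites:
            p = params.p_init_at(s.position, s.codon, s.context.label)
            if p <= 0 or s.position in self.starts:
                continue
            self._add(StartInfo(s.position, s.codon, "orf", p,
                                self._find_stop(seq, s.position), 0.0))

        # stall sites: folded hairpins; a modified stem adenine destabilises
        stalls: list[tuple[int, float]] = []
        for h in leader.stem_loops:
            dg = h.delta_G
            stem_positions = {p for pair in h.pairs for p in pair}
            for m in leader.methyl_sites:
                if m.modified(params.stress) and m.position in stem_positions:
                    dg += params.a326_destab
            stalls.append((h.five_prime_base, params.k_unwind(dg)))
        self.stall_sites = stalls

        # scanning roadblock adenines (modified, not part of a folded stem)
        stem_all = {p for h in leader.stem_loops for pair in h.pairs for p in pair}
        m6a = {m.position for m in leader.methyl_sites
               if m.modified(params.stress) and m.position not in stem_all}

        # per-position PIC hop slow-down factors (entering position p)
        slow: dict[int, float] = {}
        for st in leader.st_st:
            for p in range(st.start, st.stop + 3):
                slow[p] = slow.get(p, 1.0) * params.stst_block
        for p in m6a:
            slow[p] = slow.get(p, 1.0) * params.m6a_block
        self.pic_hop_rate = {}  # position p -> rate of the hop p -> p+1
        for p, f in slow.items():
            self.pic_hop_rate[p - 1] = params.v_scan / f
        # stall crossings override: PIC leading edge abuts the hairpin base
        for s, k in stalls:
            self.pic_hop_rate[s - 1 - self.pic_hi_off] = min(
                k, self.pic_hop_rate.get(s - 1 - self.pic_hi_off, math.inf)
            )
        self.e80_hop_rate = {}
        for s, k in stalls:
            k80 = k * params.unwind_mult_80S
            for p in range(s - 3 - self.e80_hi_off, s - self.e80_hi_off):
                self.e80_hop_rate[p] = min(k80, self.e80_hop_rate.get(p, math.inf))

        # migration-window candidates per position (computed lazily)
        self._window_cache: dict[int, tuple[StartInfo, ...]] = {}

    def _add(self, info: StartInfo):
        self.starts[info.position] = info

    @staticmethod
    def _find_stop(seq: str, pos: int) -> int | None:
        p = pos + 3
        while p + 2 <= len(seq):
            if seq[p - 1 : p + 2] in STOP_CODONS:
                return p
            p += 3
        return None

    def pic_hop(self, p: int) -> float:
        return self.pic_hop_rate.get(p, self.params.v_scan)

    def e80_hop(self, p: int) -> float:
        return self.e80_hop_rate.get(p, self.params.v_elong)

    def init_rate(self, info: StartInfo) -> float:
        """Initiation rate such that at an unperturbed position the
        per-dwell initiation probability is p: r = v * p / (1 - p)."""
        p = min(info.p, 0.999999)
        return self.params.v_scan * p / (1.0 - p)

    def window_starts(self, psite: int) -> tuple[StartInfo, ...]:
        if psite not in self._window_cache:
            w = self.params.pic_footprint.migration_window
            self._window_cache[psite] = tuple(
                info for pos, info in sorted(self.starts.items())
                if abs(pos - psite) <= w and pos != psite and info.p > 0
            )
        return self._window_cache[psite]


class _Rib:
    __slots__ = ("species", "psite", "tc", "origin", "stop", "p_rei",
                 "fate_resume", "t0")

    def __init__(self, species, psite, tc, t0):
        self.species = species
        self.psite = psite
        self.tc = tc
        self.origin = None
        self.stop = None
        self.p_rei = 0.0
        self.fate_resume = False
        self.t0 = t0


@dataclass
class SimulationResult:
    """Observables of one simulated mRNA molecule."""

    leader_name: str
    t_end: float
    realized_seed: int
    loads: int = 0
    scanned_off: int = 0
    recycled: int = 0
    runoff: int = 0
    active_at_end: int = 0
    initiation_counts: dict = field(default_factory=dict)
    protein_outputs: dict = field(default_factory=dict)
    occupancy: dict = field(default_factory=dict)   # species -> np.ndarray
    occupancy_80s_frame: np.ndarray | None = None   # (3, L) by origin frame
    snapshots: list = field(default_factory=list)   # [(t, ((species, psite, origin), ...))]
    event_log: list = field(default_factory=list)
    event_count: int = 0
    cds_start: int = 0
    footprint_80S: int = 30
    pic_footprint: object = None

    def conservation_ok(self) -> bool:
        """loads = scanned_off + recycled + run-off completions + active."""
        return self.loads == self.scanned_off + self.recycled + self.runoff + self.active_at_end

    def main_orf_output(self) -> int:
        """Completed synthesis from main-ORF-frame starts (the reporter
        signal: any initiation in frame 0 at/after the main AUG)."""
        total = 0
        for origin, n in self.protein_outputs.items():
            if origin >= self.cds_start and frame_between(origin, self.cds_start) == 0:
                total += n
        return total


def simulate(
    leader: LeaderAnnotation,
    params: SimulationParams,
    t_max: float,
    seed: int,
    snapshot_interval: float | None = None,
    burn_in_frac: float = 0.2,
    record_occupancy: bool = True,
    record_log: bool = False,
    max_log: int = 100_000,
    max_ribosomes: int | None = None,
) -> SimulationResult:
    """Simulate one mRNA molecule for ``t_max`` seconds."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    track = TrackSpec(leader, params)
    par = params
    rng = np.random.default_rng(seed)
    L = track.L
    up = track.up
    pic_hi = track.pic_hi_off
    e80_hi = track.e80_hi_off
    load_psite = 1 + up
    load_hi = load_psite + pic_hi
    exclusion = par.exclusion

    res = SimulationResult(
        leader_name=leader.name, t_end=t_max, realized_seed=seed,
        cds_start=leader.cds_start, footprint_80S=par.footprint_80S,
        pic_footprint=par.pic_footprint,
    )
    occ = {
        PIC: np.zeros(L + 1) if record_occupancy else None,
        E80S: np.zeros(L + 1) if record_occupancy else None,
    }
    occ_frame = np.zeros((3, L + 1)) if record_occupancy else None

    ribs: list[_Rib] = []
    t = 0.0
    burn_in = burn_in_frac * t_max
    next_snap = burn_in if snapshot_interval else math.inf

    def hi_of(r: _Rib) -> int:
        return r.psite + (pic_hi if r.species == PIC else e80_hi)

    def lo_of(r: _Rib) -> int:
        return r.psite - up

    def occ_flush(r: _Rib, now: float):
        if not record_occupancy or now <= r.t0:
            r.t0 = now
            return
        dt = now - r.t0
        lo = max(1, lo_of(r))
        hi = min(L, hi_of(r))
        key = PIC if r.species == PIC else E80S
        occ[key][lo : hi + 1] += dt
        if r.species != PIC and r.origin is not None:
            fr = (r.origin - leader.cds_start) % 3
            occ_frame[fr][lo : hi + 1] += dt
        r.t0 = now

    def free_interval(lo: int, hi: int, skip: _Rib | None) -> bool:
        if not exclusion:
            return True
        for r in ribs:
            if r is skip:
                continue
            if not (hi < lo_of(r) or lo > hi_of(r)):
                return False
        return True

    def log(kind, pos):
        if record_log and len(res.event_log) < max_log:
            res.event_log.append((round(t, 6), kind, pos))

    # event list buffers reused per iteration
    while True:
        rates: list[float] = []
        acts: list[tuple] = []

        if (max_ribosomes is None or len(ribs) < max_ribosomes) and (
            not ribs or not exclusion or lo_of(ribs[0]) > load_hi
        ):
            rates.append(par.k_load)
            acts.append((_LOAD,))

        for i, r in enumerate(ribs):
            ahead = ribs[i + 1] if i + 1 < len(ribs) else None
            if r.species == PIC:
                if not r.tc and par.k_tc * par.tc_level > 0:
                    rates.append(par.k_tc * par.tc_level)
                    acts.append((_BIND, r))
                # hop (or stall release / scan-off)
                blocked = False
                if exclusion and ahead is not None and (r.psite + 1 + pic_hi) >= lo_of(ahead):
                    blocked = True
                else:
                    rates.append(track.pic_hop(r.psite))
                    acts.append((_HOP, r, i))
                if r.tc:
                    info = track.starts.get(r.psite)
                    if info is not None and info.p > 0:
                        rates.append(track.init_rate(info))
                        acts.append((_INIT, r, info, r.psite))
                    if blocked and par.queue_boost > 0:
                        for winfo in track.window_starts(r.psite):
                            rates.append(par.queue_boost * track.init_rate(winfo))
                            acts.append((_BOOST_INIT, r, winfo))
            elif r.species == E80S:
                if r.stop is not None and r.psite == r.stop:
                    rates.append(par.k_term)
                    acts.append((_RELEASE, r, i))
                else:
                    if not (exclusion and ahead is not None
                            and (r.psite + 3 + e80_hi) >= lo_of(ahead)):
                        rates.append(track.e80_hop(r.psite))
                        acts.append((_HOP, r, i))
            else:  # TERM: finish termination / retry resumption
                rates.append(par.k_term)
                acts.append((_RELEASE, r, i))

        total = 0.0
        for x in rates:
            total += x
        if total <= 0.0:
            # nothing can move: jump to the next snapshot or the horizon
            if next_snap <= t_max:
                res.snapshots.append(
                    (next_snap, tuple((r.species, r.psite, r.origin) for r in ribs))
                )
                t = next_snap
                next_snap += snapshot_interval
                continue
            t = t_max
            break
        else:
            dt = rng.exponential(1.0 / total)
            t_next = t + dt
            while next_snap <= min(t_next, t_max):
                res.snapshots.append(
                    (next_snap, tuple((r.species, r.psite, r.origin) for r in ribs))
                )
                next_snap += snapshot_interval
            if t_next >= t_max:
                t = t_max
                break
            t = t_next
            # pick the event
            u = rng.random() * total
            acc = 0.0
            idx = 0
            for idx in range(len(rates)):
                acc += rates[idx]
                if u <= acc:
                    break
            a = acts[idx]
            res.event_count += 1
            code = a[0]

            if code == _LOAD:
                nr = _Rib(PIC, load_psite, rng.random() < par.p_tc_at_load, t)
                ribs.insert(0, nr)
                res.loads += 1
                log("load", load_psite)
            elif code == _BIND:
                a[1].tc = True
            elif code == _HOP:
                r = a[1]
                occ_flush(r, t)
                r.psite += 1 if r.species == PIC else 3
                if r.psite > L - 2:
                    occ_flush(r, t)
                    ribs.remove(r)
                    if r.species == PIC:
                        res.scanned_off += 1
                        log("scan_off", r.psite)
                    else:
                        res.runoff += 1
                        res.protein_outputs[r.origin] = res.protein_outputs.get(r.origin, 0) + 1
                        log("runoff", r.origin)
            elif code in (_INIT, _BOOST_INIT):
                r = a[1]
                info = a[2]
                if code == _BOOST_INIT:
                    # migration: the PIC relocates onto the window codon if
                    # the 80S footprint there is free
                    lo, hi = info.position - up, info.position + e80_hi
                    if not free_interval(lo, hi, r):
                        continue
                    occ_flush(r, t)
                    r.psite = info.position
                    ribs.sort(key=lambda x: x.psite)
                else:
                    occ_flush(r, t)
                res.initiation_counts[info.position] = (
                    res.initiation_counts.get(info.position, 0) + 1
                )
                log("init", info.position)
                if info.kind == "stst":
                    # initiation followed by immediate termination at the
                    # adjacent stop: the ribosome dwells as a roadblock
                    r.species = TERM
                    r.origin = info.position
                    r.stop = info.stop
                    r.p_rei = info.p_rei
                    r.fate_resume = None  # decided at the termination event
                    res.protein_outputs[info.position] = (
                        res.protein_outputs.get(info.position, 0) + 1
                    )
                else:
                    r.species = E80S
                    r.origin = info.position
                    r.stop = info.stop
                    r.p_rei = info.p_rei
                    r.tc = False
            elif code == _RELEASE:
                r = a[1]
                if r.species == E80S:
                    # termination at the stop codon
                    occ_flush(r, t)
                    r.species = TERM
                    res.protein_outputs[r.origin] = res.protein_outputs.get(r.origin, 0) + 1
                    r.fate_resume = None
                    log("terminate", r.psite)
                else:
                    if r.fate_resume is None:
                        r.fate_resume = bool(rng.random() < r.p_rei)
                    if not r.fate_resume:
                        occ_flush(r, t)
                        ribs.remove(r)
                        res.recycled += 1
                        log("recycle", r.psite)
                    else:
                        # resume scanning TC-less just past the stop codon
                        target = r.stop + 3 if r.stop is not None else r.psite
                        lo, hi = target - up, target + pic_hi
                        if free_interval(lo, hi, r):
                            occ_flush(r, t)
                            r.species = PIC
                            r.psite = target
                            r.tc = False
                            r.origin = None
                            r.stop = None
                            r.fate_resume = False
                            ribs.sort(key=lambda x: x.psite)
                            log("resume", target)
                        # else: stay TERM, retry at the next k_term event

    for r in ribs:
        occ_flush(r, t_max)
    res.active_at_end = len(ribs)
    if record_occupancy:
        res.occupancy = {
            "PIC": occ[PIC][1:] / t_max,
            "80S": occ[E80S][1:] / t_max,
        }
        res.occupancy_80s_frame = occ_frame[:, 1:] / t_max
    return res
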