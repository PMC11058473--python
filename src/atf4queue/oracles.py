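"""Independent verification oracles for the stochastic engine.

``analytic_small_model`` evaluates the collision-free limit exactly: each
PIC traverses the track alone, so per-position exponential races give a
closed-form forward recursion over (TC-bound, TC-less) scanning weights.

``markov_oracle`` builds the full continuous-time Markov chain of the
model with exclusion for a bounded number of simultaneous ribosomes on a
short leader, solves for the stationary distribution and reports
long-run event fractions.  It shares the per-position rate tables with
the engine but none of its event-loop machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import E80S, PIC, TERM, TrackSpec
from .params import SimulationParams
from .types import LeaderAnnotation


@dataclass
class CascadeResult:
    initiation: dict = field(default_factory=dict)   # start pos -> per-load fraction
    protein: dict = field(default_factory=dict)      # origin -> per-load fraction
    scanned_off: float = 0.0


def analytic_small_model(leader: LeaderAnnotation, params: SimulationParams) -> CascadeResult:
    """Exact per-load initiation fractions in the collision-free cascade."""
    track = TrackSpec(leader, params)
    L = track.L
    kb = params.k_tc * params.tc_level
    load_pos = 1 + track.up
    out = CascadeResult()

    # weights arriving at each position, processed left to right
    add_b = np.zeros(L + 2)
    add_u = np.zeros(L + 2)
    add_b[load_pos] = params.p_tc_at_load
    add_u[load_pos] = 1.0 - params.p_tc_at_load

    wb = wu = 0.0
    for p in range(load_pos, L - 1):
        wb += add_b[p]
        wu += add_u[p]
        v = track.pic_hop(p)
        if wu > 0 and kb > 0:
            bind = kb / (kb + v)
            wb += wu * bind
            wu *= 1.0 - bind
        info = track.starts.get(p)
        if info is not None and info.p > 0 and wb > 0:
            r = track.init_rate(info)
            q = r / (r + v)
            w_init = wb * q
            wb -= w_init
            out.initiation[p] = out.initiation.get(p, 0.0) + w_init
            if info.kind == "stst":
                out.protein[p] = out.protein.get(p, 0.0) + w_init
                add_u[info.stop + 3] += w_init * info.p_rei
            elif info.stop is not None:
                out.protein[p] = out.protein.get(p, 0.0) + w_init
                add_u[info.stop + 3] += w_init * info.p_rei
            else:
                out.protein[p] = out.protein.get(p, 0.0) + w_init
    out.scanned_off = wb + wu + add_b[L - 1 :].sum() + add_u[L - 1 :].sum()
    return out


# ---------------------------------------------------------------------------
# master-equation oracle

# ribosome tuple: (species, psite, tc, origin, fate) with fate in
# {0: n/a, 1: resume-pending}; origin indexes track.starts or -1
_MAX_STATES = 200_000


@dataclass
class MarkovResult:
    initiation: dict = field(default_factory=dict)
    protein: dict = field(default_factory=dict)
    scanned_off: float = 0.0
    load_rate: float = 0.0
    n_states: int = 0


def markov_oracle(
    leader: LeaderAnnotation,
    params: SimulationParams,
    max_ribosomes: int = 2,
) -> MarkovResult:
    """Stationary per-load event fractions of the exact master equation."""
    track = TrackSpec(leader, params)
    L = track.L
    up = track.up
    pic_hi = track.pic_hi_off
    e80_hi = track.e80_hi_off
    load_psite = 1 + up
    load_hi = load_psite + pic_hi
    kb = params.k_tc * params.tc_level

    def extent(rib):
        sp, ps = rib[0], rib[1]
        return (ps - up, ps + (pic_hi if sp == PIC else e80_hi))

    def free(state, lo, hi, skip=None):
        for i, rib in enumerate(state):
            if i == skip:
                continue
            rlo, rhi = extent(rib)
            if not (hi < rlo or lo > rhi):
                return False
        return True

    def norm(state):
        return tuple(sorted(state))

    # transitions: state -> list of (rate, new_state or None, tag)
    # tag: ("load",), ("init", pos), ("scan_off",), ("runoff", origin),
    #      ("protein", origin), ("recycle",) or None
    def transitions(state):
        outs = []
        ribs = sorted(state, key=lambda r: r[1])
        if len(ribs) < max_ribosomes and (
            not ribs or not params.exclusion or ribs[0][1] - up > load_hi
        ):
            for tc_flag, w in ((1, params.p_tc_at_load), (0, 1 - params.p_tc_at_load)):
                if w > 0:
                    new = norm(state + ((PIC, load_psite, tc_flag, -1, 0),))
                    outs.append((params.k_load * w, new, ("load",) if tc_flag >= 0 else None))
        for i, rib in enumerate(ribs):
            sp, ps, tc, origin, fate = rib
            others = tuple(r for j, r in enumerate(ribs) if j != i)
            ahead = ribs[i + 1] if i + 1 < len(ribs) else None
            if sp == PIC:
                if not tc and kb > 0:
                    outs.append((kb, norm(others + ((PIC, ps, 1, origin, 0),)), None))
                blocked = False
                nxt = ps + 1
                if params.exclusion and ahead is not None and nxt + pic_hi >= ahead[1] - up:
                    blocked = True
                else:
                    rate = track.pic_hop(ps)
                    if nxt > L - 2:
                        outs.append((rate, norm(others), ("scan_off",)))
                    else:
                        outs.append((rate, norm(others + ((PIC, nxt, tc, origin, 0),)), None))
                if tc:
                    cands = []
                    info = track.starts.get(ps)
                    if info is not None and info.p > 0:
                        cands.append((track.init_rate(info), info, ps))
                    if blocked and params.queue_boost > 0:
                        for winfo in track.window_starts(ps):
                            lo, hi = winfo.position - up, winfo.position + e80_hi
                            if free(others, lo, hi):
                                cands.append(
                                    (params.queue_boost * track.init_rate(winfo),
                                     winfo, winfo.position)
                                )
                    for rate, info, pos in cands:
                        if info.kind == "stst":
                            new_rib = (TERM, pos, 0, pos, 0)
                        else:
                            new_rib = (E80S, pos, 0, pos, 0)
                        outs.append((rate, norm(others + (new_rib,)), ("init", pos)))
            elif sp == E80S:
                info = track.starts[origin]
                at_stop = info.stop is not None and ps == info.stop
                if at_stop:
                    outs.append(
                        (params.k_term, norm(others + ((TERM, ps, 0, origin, 0),)),
                         ("protein", origin))
                    )
                else:
                    nxt = ps + 3
                    if not (params.exclusion and ahead is not None
                            and nxt + e80_hi >= ahead[1] - up):
                        rate = track.e80_hop(ps)
                        if nxt > L - 2:
                            outs.append((rate, norm(others), ("runoff", origin)))
                        else:
                            outs.append((rate, norm(others + ((E80S, nxt, tc, origin, 0),)), None))
            else:  # TERM
                info = track.starts[origin]
                p_rei = info.p_rei
                if fate == 0:
                    if info.kind == "stst":
                        # protein already counted at initiation in the engine;
                        # count it here on the termination event instead
                        pass
                    if p_rei < 1.0:
                        outs.append((params.k_term * (1 - p_rei), norm(others), ("recycle",)))
                    if p_rei > 0.0:
                        outs.append((params.k_term * p_rei,) + _resume(others, info, ps, up, pic_hi, params, norm))
                else:  # resume pending, retry
                    outs.append((params.k_term,) + _resume(others, info, ps, up, pic_hi, params, norm))
        return outs

    def _resume(others, info, ps, up, pic_hi, params, norm):
        target = info.stop + 3 if info.stop is not None else ps
        lo, hi = target - up, target + pic_hi
        ok = True
        if params.exclusion:
            for rib in others:
                rlo = rib[1] - up
                rhi = rib[1] + (pic_hi if rib[0] == PIC else (params.footprint_80S - 1 - up))
                if not (hi < rlo or lo > rhi):
                    ok = False
                    break
        if ok:
            return (norm(others + ((PIC, target, 0, -1, 0),)), ("resume",))
        return (norm(others + ((TERM, ps, 0, info.position, 1),)), None)

    # BFS over reachable states
    empty = tuple()
    index = {empty: 0}
    order = [empty]
    trans: list[list[tuple[float, int, tuple | None]]] = []
    qi = 0
    while qi < len(order):
        st = order[qi]
        qi += 1
        outs = transitions(st)
        row = []
        for rate, new, tag in outs:
            if rate <= 0:
                continue
            if new not in index:
                if len(index) >= _MAX_STATES:
                    raise MemoryError(
                        f"master-equation state space exceeds {_MAX_STATES} states"
                    )
                index[new] = len(order)
                order.append(new)
            row.append((rate, index[new], tag))
        trans.append(row)

    n = len(order)
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    A = lil_matrix((n, n))
    for i, row in enumerate(trans):
        tot = 0.0
        for rate, j, _ in row:
            A[j, i] += rate
            tot += rate
        A[i, i] -= tot
    # replace last equation with normalisation
    A = A.tocsr()
    A = A.tolil()
    A[n - 1, :] = 1.0
    b = np.zeros(n)
    b[n - 1] = 1.0
    pi = spsolve(A.tocsr(), b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    res = MarkovResult(n_states=n)
    flux: dict = {}
    for i, row in enumerate(trans):
        for rate, j, tag in row:
            if tag is None:
                continue
            f = pi[i] * rate
            flux[tag] = flux.get(tag, 0.0) + f
    load = sum(v for k, v in flux.items() if k == ("load",))
    res.load_rate = load
    if load > 0:
        for tag, f in flux.items():
            if tag[0] == "init":
                res.initiation[tag[1]] = f / load
            elif tag[0] in ("protein", "runoff"):
                res.protein[tag[1]] = res.protein.get(tag[1], 0.0) + f / load
            elif tag[0] == "scan_off":
                res.scanned_off += f / load
        # start-stop events count as products, mirroring the engine
        for pos, frac in res.initiation.items():
            if track.starts[pos].kind == "stst":
                res.protein[pos] = frac
    return res
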