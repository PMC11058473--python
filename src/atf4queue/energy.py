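"""Hairpin-only RNA folding with a packaged nearest-neighbour energy table.

The object of interest is a single local hairpin (one stem, bulges and
internal loops allowed, no multiloops or pseudoknots), so the model is a
restricted secondary-structure DP rather than a full Zuker fold:

    V(i, j) = min( hairpin_loop(i, j),
                   min over inner pairs (k, l):
                       pair_interior(i, j, k, l) + V(k, l) )

over Watson-Crick + G.U pairs, and the best hairpin in a window is the
minimum of V over all closing pairs.  Energies are 37 degC Turner-style
stack and loop-initiation values (kcal/mol) stored as data below; the
table is deliberately compact, so predicted minima carry a ~2 kcal/mol
model tolerance relative to full-parameter folders.
"""

from __future__ import annotations

import math
from functools import lru_cache

from .types import StemLoop

CANONICAL_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})

# Watson-Crick / wobble stack free energies, kcal/mol at 37 degC.
# Key: (closing pair i.j, inner pair i+1.j-1), pairs written 5'->3' base
# then its partner.  Turner-style values.
STACK = {
    ("AU", "AU"): -0.93, ("AU", "CG"): -2.24, ("AU", "GC"): -2.08,
    ("AU", "UA"): -1.10, ("AU", "GU"): -0.55, ("AU", "UG"): -1.36,
    ("CG", "AU"): -2.11, ("CG", "CG"): -3.26, ("CG", "GC"): -2.36,
    ("CG", "UA"): -2.08, ("CG", "GU"): -1.41, ("CG", "UG"): -2.11,
    ("GC", "AU"): -2.35, ("GC", "CG"): -3.42, ("GC", "GC"): -3.26,
    ("GC", "UA"): -2.24, ("GC", "GU"): -1.53, ("GC", "UG"): -2.51,
    ("UA", "AU"): -1.33, ("UA", "CG"): -2.35, ("UA", "GC"): -2.11,
    ("UA", "UA"): -0.93, ("UA", "GU"): -1.00, ("UA", "UG"): -1.27,
    ("GU", "AU"): -1.27, ("GU", "CG"): -2.51, ("GU", "GC"): -2.11,
    ("GU", "UA"): -1.36, ("GU", "GU"): -0.50, ("GU", "UG"): 1.29,
    ("UG", "AU"): -1.00, ("UG", "CG"): -1.41, ("UG", "GC"): -1.53,
    ("UG", "UA"): -0.55, ("UG", "GU"): 0.30, ("UG", "UG"): -0.50,
}

# Loop initiation penalties by loop size (unpaired nt), kcal/mol.
HAIRPIN_LOOP = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
BULGE_LOOP = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
INTERNAL_LOOP = {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0, 7: 2.2, 8: 2.3}

#: Jacobson-Stockmayer extrapolation beyond the tabulated sizes
_RT = 0.616  # kcal/mol at 37 degC
#: penalty for a terminal A-U or G-U pair closing the outermost stack
TERMINAL_AU = 0.45

MAX_INTERIOR = 12  # largest bulge/internal loop considered


def _extrapolate(table: dict[int, float], n: int) -> float:
    if n in table:
        return table[n]
    m = max(table)
    return table[m] + 1.75 * _RT * math.log(n / m)


def hairpin_loop_energy(n: int) -> float:
    if n < 3:
        return math.inf
    return _extrapolate(HAIRPIN_LOOP, n)


def interior_energy(n5: int, n3: int) -> float:
    """Energy of the loop between consecutive stem pairs: 0 unpaired on
    both sides = a stack (handled separately); one side = bulge; both =
    internal loop."""
    if n5 == 0 and n3 == 0:
        return 0.0  # caller adds the stack term
    if n5 == 0 or n3 == 0:
        return _extrapolate(BULGE_LOOP, n5 + n3)
    return _extrapolate(INTERNAL_LOOP, n5 + n3)


def can_pair(a: str, b: str) -> bool:
    return a + b in CANONICAL_PAIRS


def pair_label(seq: str, i: int, j: int) -> str:
    """Pair string for 1-based positions i < j."""
    return seq[i - 1] + seq[j - 1]


def hairpin_energy_from_pairs(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Hand-summable energy of a concrete hairpin given its pair list
    (outermost first).  Independent of the DP: used as the internal
    consistency oracle and for re-scoring mutated sequences."""
    if not pairs:
        return 0.0
    e = 0.0
    for (i, j), (k, l) in zip(pairs, pairs[1:]):
        n5, n3 = k - i - 1, j - l - 1
        if n5 == 0 and n3 == 0:
            e += STACK[(pair_label(seq, i, j), pair_label(seq, k, l))]
        else:
            e += interior_energy(n5, n3)
    ii, jj = pairs[-1]
    e += hairpin_loop_energy(jj - ii - 1)
    outer = pair_label(seq, *pairs[0])
    if outer in ("AU", "UA", "GU", "UG"):
        e += TERMINAL_AU
    return e


def _fold_window(seq: str, min_stem: int, min_loop: int = 3):
    """DP over one window (0-based internally).  Returns (V, choice) where
    V[i][j] is the best energy of a hairpin closed by pair (i, j)."""
    n = len(seq)
    NEG = math.inf
    V = [[NEG] * n for _ in range(n)]
    choice = [[None] * n for _ in range(n)]
    # iterate by increasing span so inner pairs are ready
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not can_pair(seq[i], seq[j]):
                continue
            best = hairpin_loop_energy(j - i - 1)
            bc = None
            kmax = min(i + MAX_INTERIOR + 2, j - min_loop - 1)
            for k in range(i + 1, kmax + 1):
                for l in range(j - 1, max(k + min_loop, j - (MAX_INTERIOR - (k - i - 1)) - 2), -1):
                    if V[k][l] == NEG:
                        continue
                    n5, n3 = k - i - 1, j - l - 1
                    if n5 == 0 and n3 == 0:
                        e = STACK[(seq[i] + seq[j], seq[k] + seq[l])] + V[k][l]
                    else:
                        e = interior_energy(n5, n3) + V[k][l]
                    if e < best:
                        best, bc = e, (k, l)
            V[i][j] = best
            choice[i][j] = bc
    return V, choice


def _backtrack(choice, i, j):
    pairs = [(i, j)]
    while choice[i][j] is not None:
        i, j = choice[i][j]
        pairs.append((i, j))
    return pairs


def predict_hairpins(
    sequence: str,
    min_stem: int = 3,
    max_loop: int = 30,
    window: int = 60,
    max_results: int = 20,
    offset: int = 0,
) -> list[StemLoop]:
    """Best local hairpins of ``sequence``, sorted by delta_G (most stable
    first).  ``window`` bounds the span of a single hairpin; overlapping
    candidates are suppressed in favour of the better one.  ``offset``
    shifts reported coordinates (for folding a sub-region of a larger
    transcript).  Raises ValueError if window < 2*min_stem + 3.
    """
    if min_stem < 3:
        raise ValueError("min_stem must be >= 3")
    if window < 2 * min_stem + 3:
        raise ValueError("window shorter than 2*min_stem + 3")
    n = len(sequence)
    if n < 2 * min_stem + 3:
        return []
    seq = sequence.upper().replace("T", "U")

    candidates: list[tuple[float, list[tuple[int, int]]]] = []
    step = max(window // 2, 1)
    seen_spans = set()
    for w0 in range(0, max(n - window, 0) + 1, step):
        sub = seq[w0 : w0 + window]
        V, choice = _fold_window(sub, min_stem)
        m = len(sub)
        for i in range(m):
            for j in range(i + 1, m):
                if V[i][j] >= 0 or V[i][j] == math.inf:
                    continue
                pairs0 = _backtrack(choice, i, j)
                if len(pairs0) < min_stem:
                    continue
                li, lj = pairs0[-1]
                if lj - li - 1 > max_loop:
                    continue
                pairs = [(w0 + a + 1 + offset, w0 + b + 1 + offset) for a, b in pairs0]
                span = (pairs[0][0], pairs[0][1])
                if span in seen_spans:
                    continue
                seen_spans.add(span)
                e = V[i][j]
                outer = sub[i] + sub[j]
                if outer in ("AU", "UA", "GU", "UG"):
                    e += TERMINAL_AU
                candidates.append((e, pairs))

    candidates.sort(key=lambda c: c[0])
    out: list[StemLoop] = []
    taken: list[tuple[int, int]] = []
    for e, pairs in candidates:
        if e >= 0:
            continue
        lo, hi = pairs[0]
        if any(not (hi < a or lo > b) for a, b in taken):
            continue
        li, lj = pairs[-1]
        out.append(
            StemLoop(
                five_prime_base=lo,
                three_prime_end=hi,
                loop_interval=(li + 1, lj - 1),
                delta_G=round(e, 2),
                pairs=tuple(pairs),
            )
        )
        taken.append((lo, hi))
        if len(out) >= max_results:
            break
    return out


@lru_cache(maxsize=512)
def best_hairpin_energy(sequence: str, lo: int = None, hi: int = None) -> float:
    """Minimum hairpin free energy in (a region of) a sequence; +inf when
    no hairpin forms.  ``lo``/``hi`` are 1-based inclusive bounds."""
    if lo is not None:
        sequence = sequence[lo - 1 : hi]
    hps = predict_hairpins(sequence, max_results=1)
    return hps[0].delta_G if hps else math.inf
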