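"""Feature detection on transcript leaders and ribosome-queuing geometry.

Detectors: ORFs/start-stops, Kozak context classification, near-cognate
start sites, DRACH/RRACH methylation motifs, local hairpins, slippery /
C-tract frameshift signals.  Geometry: how many 30-nt 80S footprints fit
between a start codon and a stalling hairpin, and which start codons a
stalled scanning 48S PIC can reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import energy
from .types import (
    NEAR_COGNATE_CODONS,
    STOP_CODONS,
    ContextClass,
    FrameshiftSignal,
    LeaderAnnotation,
    MethylSite,
    StartSite,
    StemLoop,
    StStElement,
    UORF,
    frame_between,
)

#: a uORF is treated as reinitiation-permissive when it is short and does
#: not overlap the main ORF (packaged rule; the canonical example is the
#: 3-codon uORF1 of the ATF4 leader)
REI_PERMISSIVE_MAX_CODONS = 10

#: hairpins reported as annotation elements must be at least this stable
HAIRPIN_REPORT_DG = -10.0


@dataclass(frozen=True)
class PICFootprintModel:
    """mRNA extent protected by a scanning 48S pre-initiation complex.

    ``upstream_of_psite`` nt are covered 5' of the P site (P site
    excluded); ``downstream_of_psite`` nt from the P site (included) to
    the mRNA entry channel.  ``migration_window`` is the +/- range over
    which a queue-blocked PIC can migrate while selecting a start codon.
    """

    upstream_of_psite: int = 12
    downstream_of_psite: int = 20
    migration_window: int = 15

    def __post_init__(self):
        if min(self.upstream_of_psite, self.downstream_of_psite, self.migration_window) < 0:
            raise ValueError("footprint extents must be >= 0")

    @property
    def length(self) -> int:
        return self.upstream_of_psite + self.downstream_of_psite

    def footprint(self, psite: int) -> tuple[int, int]:
        return (psite - self.upstream_of_psite, psite + self.downstream_of_psite - 1)


@dataclass(frozen=True)
class QueueGeometry:
    """A fully packed 80S queue between an upstream start and a stall."""

    upstream_start: int
    stall_pos: int
    footprint_80S: int
    capacity: int
    psite_positions: tuple[int, ...]
    remainder: int


def classify_start_context(sequence: str, pos: int) -> ContextClass:
    """Kozak class of the start codon whose first base is ``pos``
    (1-based): strong if -3 in {A,G} AND +4 == G; medium if exactly one
    holds; weak if neither.  Starts lacking a -3 or +4 base are weak with
    a truncation flag."""
    if pos - 3 < 1 or pos + 3 > len(sequence):
        m3 = sequence[pos - 4] if pos - 3 >= 1 else ""
        p4 = sequence[pos + 2] if pos + 3 <= len(sequence) else ""
        return ContextClass(label="weak", minus3=m3, plus4=p4, truncated=True)
    m3 = sequence[pos - 4]
    p4 = sequence[pos + 2]
    good = (m3 in "AG") + (p4 == "G")
    label = {2: "strong", 1: "medium", 0: "weak"}[good]
    return ContextClass(label=label, minus3=m3, plus4=p4)


def find_orfs(
    sequence: str, region: tuple[int, int], cds_start: int | None = None
) -> list[StStElement | UORF]:
    """Every AUG whose first base lies in ``region`` opens an ORF, closed
    at the first in-frame stop anywhere downstream in the sequence (or
    flagged stop-less at the sequence end).  A start-stop element is
    emitted when zero sense codons precede the stop."""
    lo, hi = region
    n = len(sequence)
    if not (1 <= lo <= hi <= n):
        raise ValueError("region out of bounds")
    out: list[StStElement | UORF] = []
    for pos in range(lo, hi + 1):
        if sequence[pos - 1 : pos + 2] != "AUG":
            continue
        ctx = classify_start_context(sequence, pos)
        stop = None
        p = pos + 3
        while p + 2 <= n:
            if sequence[p - 1 : p + 2] in STOP_CODONS:
                stop = p
                break
            p += 3
        frame = frame_between(pos, cds_start) if cds_start else 0
        if stop is None:
            out.append(
                UORF(start=pos, stop=0, n_codons=(n - pos - 2) // 3, frame_vs_cds=frame,
                     rei_permissive=False, context=ctx, stopless=True)
            )
            continue
        n_codons = (stop - pos) // 3 - 1
        if n_codons == 0:
            out.append(StStElement(start=pos, stop=stop, context=ctx))
        else:
            permissive = (
                n_codons <= REI_PERMISSIVE_MAX_CODONS
                and (cds_start is None or stop + 2 < cds_start)
            )
            out.append(
                UORF(start=pos, stop=stop, n_codons=n_codons, frame_vs_cds=frame,
                     rei_permissive=permissive, context=ctx)
            )
    return out


def find_near_cognate_starts(
    sequence: str,
    region: tuple[int, int],
    cds_start: int | None = None,
    codons: frozenset = NEAR_COGNATE_CODONS,
) -> list[StartSite]:
    """All 3-mers at Hamming distance 1 from AUG starting in ``region``.
    AUG itself is excluded by definition; restrict ``codons`` to report a
    subset (e.g. only CUG/GUG)."""
    lo, hi = region
    out = []
    for pos in range(lo, min(hi, len(sequence) - 2) + 1):
        codon = sequence[pos - 1 : pos + 2]
        if codon in codons:
            out.append(
                StartSite(
                    position=pos,
                    codon=codon,
                    is_cognate=False,
                    context=classify_start_context(sequence, pos),
                    frame_vs_cds=frame_between(pos, cds_start) if cds_start else 0,
                )
            )
    return out


_D = set("AGU")
_R = set("AG")
_H = set("ACU")


def scan_methylation_motifs(sequence: str, region: tuple[int, int] | None = None) -> list[MethylSite]:
    """Every DRACH 5-mer (D=A/G/U, R=A/G, A, C, H=A/C/U); the modifiable A
    is the 3rd base.  Sites whose D is also an R are flagged with the
    RRACH subclass too."""
    lo, hi = region if region else (1, len(sequence))
    out = []
    for a_pos in range(max(lo, 3), min(hi, len(sequence) - 2) + 1):
        i = a_pos - 1  # 0-based index of the central A
        if sequence[i] != "A":
            continue
        d, r, c, h = sequence[i - 2], sequence[i - 1], sequence[i + 1], sequence[i + 2]
        if d in _D and r in _R and c == "C" and h in _H:
            classes = {"DRACH"}
            if d in _R:
                classes.add("RRACH")
            out.append(MethylSite(position=a_pos, motif_class=frozenset(classes)))
    return out


def predict_hairpins(
    sequence: str, min_stem: int = 3, max_loop: int = 30, window: int = 60, **kw
) -> list[StemLoop]:
    """Best local hairpins under the packaged nearest-neighbour table,
    sorted by delta_G.  See :mod:`atf4queue.energy` for the model."""
    return energy.predict_hairpins(sequence, min_stem=min_stem, max_loop=max_loop,
                                   window=window, **kw)


def queue_capacity(
    upstream_start: int, stall_pos: int, footprint_80S: int = 30
) -> QueueGeometry:
    """How many 80S ribosomes fit nose-to-tail between ``upstream_start``
    (P site of the 5'-most ribosome) and ``stall_pos`` (5' base of the
    stalling structure)."""
    if stall_pos <= upstream_start:
        raise ValueError("stall_pos must be downstream of upstream_start")
    d = stall_pos - upstream_start
    capacity = d // footprint_80S
    remainder = d % footprint_80S
    psites = tuple(upstream_start + k * footprint_80S for k in range(capacity))
    return QueueGeometry(
        upstream_start=upstream_start,
        stall_pos=stall_pos,
        footprint_80S=footprint_80S,
        capacity=capacity,
        psite_positions=psites,
        remainder=remainder,
    )


def stalled_psite_window(
    leader: LeaderAnnotation,
    stall_pos: int,
    pic_model: PICFootprintModel = PICFootprintModel(),
) -> tuple[tuple[int, int], list[StartSite]]:
    """P-site interval reachable by a 48S PIC stalled with its leading
    edge abutting ``stall_pos``, and the start codons (cognate and
    near-cognate) whose first base lies in that window.

    The stalled P site sits ``downstream_of_psite`` nt upstream of the
    stall; back-and-forth migration widens it by +/- migration_window.
    """
    psite = stall_pos - pic_model.downstream_of_psite
    lo = max(1, psite - pic_model.migration_window)
    hi = min(len(leader.sequence) - 2, psite + pic_model.migration_window)
    sites: list[StartSite] = []
    for pos in range(lo, hi + 1):
        codon = leader.codon_at(pos)
        if codon == "AUG":
            sites.append(
                StartSite(
                    position=pos, codon="AUG", is_cognate=True,
                    context=classify_start_context(leader.sequence, pos),
                    frame_vs_cds=frame_between(pos, leader.cds_start),
                )
            )
        elif codon in NEAR_COGNATE_CODONS:
            sites.append(
                StartSite(
                    position=pos, codon=codon, is_cognate=False,
                    context=classify_start_context(leader.sequence, pos),
                    frame_vs_cds=frame_between(pos, leader.cds_start),
                )
            )
    return (lo, hi), sites


# ---------------------------------------------------------------------------
# frameshift signals

#: C-tract rule (packaged heuristic): a 12-nt window starting on a C with
#: >= 7 C total and a run of >= 4 consecutive C
CTRACT_WINDOW = 12
CTRACT_MIN_TOTAL = 7
CTRACT_MIN_RUN = 4
#: slippery rule: >= 3 consecutive codons sharing their first two bases
#: (tRNA re-pairing after a -2/+1 slip only needs the P/A-site codons to
#: agree at those positions, e.g. the glycine run GGC-GGG-GGA), or a G/A
#: homopolymer run of >= 6 nt
SLIPPERY_MIN_CODONS = 3
HOMOPOLYMER_MIN = 6
OPTIMAL_CTRACT_SPACING = 8


def _ctracts(sequence: str, lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    n = len(sequence)
    pos = lo
    while pos + CTRACT_WINDOW - 1 <= min(hi, n):
        w = sequence[pos - 1 : pos - 1 + CTRACT_WINDOW]
        if w[0] == "C" and w.count("C") >= CTRACT_MIN_TOTAL and "C" * CTRACT_MIN_RUN in w:
            out.append((pos, pos + CTRACT_WINDOW - 1))
            pos += CTRACT_WINDOW  # non-overlapping reporting
        else:
            pos += 1
    return out


def find_frameshift_signals(
    sequence: str, region: tuple[int, int] | None = None, frame_anchor: int | None = None
) -> list[FrameshiftSignal]:
    """Candidate slippery runs and C-rich tracts in ``region``.

    Slippery runs are >= 3 consecutive codons sharing their first two
    bases (in the frame anchored at ``frame_anchor``, default the region
    start) or G/A homopolymer runs; for each, the gap to the nearest
    downstream C-tract is reported and a gap of exactly 8 nt is flagged
    optimal.
    """
    lo, hi = region if region else (1, len(sequence))
    anchor = frame_anchor if frame_anchor is not None else lo
    out: list[FrameshiftSignal] = []
    ctracts = _ctracts(sequence, lo, hi)

    slippery: list[tuple[int, int]] = []
    # repeated identical codons in the anchored frame
    off = (lo - anchor) % 3
    p = lo if off == 0 else lo + (3 - off)
    while p + 2 <= hi:
        duplet = sequence[p - 1 : p + 1]
        run = 1
        q = p + 3
        while q + 2 <= hi and sequence[q - 1 : q + 1] == duplet:
            run += 1
            q += 3
        if run >= SLIPPERY_MIN_CODONS:
            slippery.append((p, q - 1))
            p = q
        else:
            p += 3
    # homopolymeric G/A runs
    for base in "GA":
        i = lo
        while i <= hi:
            if sequence[i - 1] == base:
                j = i
                while j < hi and sequence[j] == base:
                    j += 1
                if j - i + 1 >= HOMOPOLYMER_MIN:
                    if not any(a <= i and j <= b for a, b in slippery):
                        slippery.append((i, j))
                i = j + 1
            else:
                i += 1

    slippery.sort()
    for a, b in slippery:
        # runs abutting the region's 3' end mimic +1-PRF candidates at a
        # stop codon (FS-B); spacing to a C-tract is an FS-A property only
        if b >= hi - 14:
            out.append(FrameshiftSignal(kind="FS-B", interval=(a, b)))
            continue
        downstream = [c for c in ctracts if c[0] > b]
        spacing = downstream[0][0] - b - 1 if downstream else None
        out.append(
            FrameshiftSignal(
                kind="FS-A",
                interval=(a, b),
                spacing_to_ctract=spacing,
                optimal_spacing=(spacing == OPTIMAL_CTRACT_SPACING),
            )
        )
    for a, b in ctracts:
        out.append(FrameshiftSignal(kind="C-tract", interval=(a, b)))
    out.sort(key=lambda f: f.interval)
    return out


# ---------------------------------------------------------------------------
# orchestration

def annotate_leader(
    sequence: str,
    cds_start: int,
    name: str = "leader",
    overlap_extent: int = 120,
    hairpin_min_dg: float = HAIRPIN_REPORT_DG,
    allow_non_aug_cds: bool = False,
) -> LeaderAnnotation:
    """Run every detector on ``sequence`` and assemble a LeaderAnnotation.

    Upstream ORFs are sought 5' of the main AUG; near-cognate starts,
    methylation motifs and hairpins in the leader plus the first
    ``overlap_extent`` nt of the main ORF (the uORF2/CDS overlap region).
    """
    sequence = sequence.upper().replace("T", "U")
    leader = LeaderAnnotation(name=name, sequence=sequence, cds_start=cds_start,
                              allow_non_aug_cds=allow_non_aug_cds)
    n = len(sequence)

    orfs = find_orfs(sequence, (1, cds_start - 1), cds_start=cds_start) if cds_start > 1 else []
    leader.st_st = [o for o in orfs if isinstance(o, StStElement)]
    leader.uorfs = [o for o in orfs if isinstance(o, UORF)]

    # the scanned region covers the leader, the early main ORF, and the
    # whole of any uORF overlapping the main ORF (so a stall element deep
    # inside an extended overlap is still seen)
    scan_hi = min(n, cds_start + overlap_extent)
    for u in leader.uorfs:
        if not u.stopless and u.end >= cds_start:
            scan_hi = min(n, max(scan_hi, u.end + 30))

    # cognate starts in the early main ORF (AUG1/2/3 and in-frame internal)
    sites: list[StartSite] = []
    for pos in range(cds_start, min(n - 2, cds_start + overlap_extent) + 1):
        if sequence[pos - 1 : pos + 2] == "AUG" and frame_between(pos, cds_start) == 0:
            sites.append(
                StartSite(
                    position=pos, codon="AUG", is_cognate=True,
                    context=classify_start_context(sequence, pos),
                    frame_vs_cds=0,
                )
            )
    sites += find_near_cognate_starts(sequence, (1, scan_hi), cds_start=cds_start)
    leader.start_sites = sorted(sites, key=lambda s: s.position)

    leader.methyl_sites = scan_methylation_motifs(sequence, (1, scan_hi))
    # hairpins are scanned over the whole track: a stall element acts on
    # elongating ribosomes wherever it sits
    leader.stem_loops = [
        h for h in predict_hairpins(sequence) if h.delta_G <= hairpin_min_dg
    ]

    overlap_uorfs = [u for u in leader.uorfs if not u.stopless and u.end >= cds_start]
    if overlap_uorfs:
        u = overlap_uorfs[0]
        leader.frameshift_signals = find_frameshift_signals(
            sequence, (u.start, u.end), frame_anchor=u.start
        )

    leader.manifest = build_manifest(leader)
    leader.validate()
    return leader


def build_manifest(leader: LeaderAnnotation) -> dict:
    """Realised architectural constraints, keyed by convention names."""
    m: dict = {"cds_start": leader.cds_start, "length": len(leader.sequence)}
    if leader.st_st:
        m["StSt_start"] = leader.st_st[0].start
    uorfs = sorted(leader.uorfs, key=lambda u: u.start)
    for i, u in enumerate(uorfs, start=1):
        m[f"uORF{i}_start"] = u.start
        m[f"uORF{i}_n_codons"] = u.n_codons
        m[f"uORF{i}_frame_vs_cds"] = u.frame_vs_cds
    main_augs = [s for s in leader.start_sites
                 if s.is_cognate and s.frame_vs_cds == 0 and s.position >= leader.cds_start]
    for i, s in enumerate(main_augs[:3], start=1):
        m[f"AUG{i}_pos"] = s.position
        m[f"AUG{i}_context"] = s.context.label
    if leader.stem_loops:
        sl = min(leader.stem_loops, key=lambda h: h.delta_G)
        m["SL3_five_prime_base"] = sl.five_prime_base
        m["SL3_delta_G"] = sl.delta_G
        if uorfs:
            u2 = max(uorfs, key=lambda u: u.n_codons)
            m["uORF2_AUG_to_SL3_nt"] = sl.five_prime_base - u2.start
        if main_augs:
            m["AUG1_to_SL3_nt"] = sl.five_prime_base - main_augs[0].position
        cugs = [s for s in leader.start_sites
                if s.codon == "CUG" and s.frame_vs_cds == 0
                and 0 < sl.five_prime_base - s.position <= 30]
        if cugs:
            m["CUG_pos"] = cugs[-1].position
            m["CUG_context"] = cugs[-1].context.label
            m["CUG_to_SL3_nt"] = sl.five_prime_base - cugs[-1].position
    m["methyl_positions"] = tuple(s.position for s in leader.methyl_sites)
    return m
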