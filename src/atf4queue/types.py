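"""Domain types for annotated transcript leaders.

All coordinates are 1-based and intervals are inclusive on both ends,
matching GenBank-style transcript numbering so that a real transcript's
printed positions (e.g. the modifiable adenines A235/A326 of the human
ATF4 variant-2 mRNA) can be used directly.  Conversion to 0-based
half-open coordinates happens only at the BED/bedGraph I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

RNA_ALPHABET = frozenset("ACGU")
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

#: the nine codons at Hamming distance 1 from AUG
NEAR_COGNATE_CODONS = frozenset(
    {"CUG", "GUG", "UUG", "ACG", "AGG", "AAG", "AUA", "AUC", "AUU"}
)


def frame_between(pos: int, cds_start: int) -> int:
    """Reading frame of ``pos`` relative to the main ORF.

    Returns 0 (in frame), +1 or -1.  A -1 frame means the main ORF is
    shifted one base 3' of the element's frame, the convention used for
    the uORF2 / main-ORF overlap.
    """
    d = (pos - cds_start) % 3
    return {0: 0, 1: 1, 2: -1}[d]


@dataclass(frozen=True)
class ContextClass:
    """Kozak initiation context of a start codon.

    The class label is a pure function of the -3 and +4 bases (relative
    to the A of the start codon at +1): strong if -3 in {A, G} and
    +4 == G, medium if exactly one determinant holds, weak if neither.
    ``truncated`` flags starts too close to an end for a -3/+4 lookup
    (classified weak).
    """

    label: str  # strong | medium | weak
    minus3: str
    plus4: str
    truncated: bool = False


@dataclass(frozen=True)
class StStElement:
    """Start-stop element: an initiation codon immediately followed by a
    termination codon.  ``stop`` is the first base of the stop codon."""

    start: int
    stop: int
    context: ContextClass | None = None

    def __post_init__(self):
        if self.stop != self.start + 3:
            raise ValueError(
                f"start-stop must have stop = start + 3, got {self.start}, {self.stop}"
            )

    @property
    def end(self) -> int:
        return self.stop + 2


@dataclass(frozen=True)
class UORF:
    """Upstream open reading frame.

    ``start`` is the first base of the initiation codon, ``stop`` the
    first base of the stop codon; ``n_codons`` counts sense codons only.
    ``stopless`` marks ORFs that run off the annotated region.
    """

    start: int
    stop: int
    n_codons: int
    frame_vs_cds: int
    rei_permissive: bool = False
    context: ContextClass | None = None
    stopless: bool = False

    def __post_init__(self):
        if not self.stopless:
            if (self.stop - self.start) % 3 != 0:
                raise ValueError("stop codon out of frame with start")
            if self.n_codons != (self.stop - self.start) // 3 - 1:
                raise ValueError("n_codons inconsistent with start/stop")
        if self.n_codons < 0:
            raise ValueError("n_codons must be >= 0")

    @property
    def end(self) -> int:
        return self.stop + 2


@dataclass(frozen=True)
class StartSite:
    """A cognate or near-cognate initiation site."""

    position: int
    codon: str
    is_cognate: bool
    context: ContextClass
    frame_vs_cds: int

    def __post_init__(self):
        if self.codon != "AUG":
            mismatches = sum(a != b for a, b in zip(self.codon, "AUG"))
            if mismatches != 1:
                raise ValueError(f"{self.codon} is not AUG nor a single-mismatch variant")


@dataclass(frozen=True)
class StemLoop:
    """A single hairpin: one (possibly interrupted) stem closed by a loop.

    ``pairs`` are (i, j) base-pair positions, nested, outermost first.
    ``delta_G`` is the nearest-neighbour free energy in kcal/mol under
    the packaged energy table (negative = stable).
    """

    five_prime_base: int
    three_prime_end: int
    loop_interval: tuple[int, int]
    delta_G: float
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.delta_G > 0:
            raise ValueError("reported hairpins must have delta_G <= 0")
        lo, hi = self.loop_interval
        if hi - lo + 1 < 3:
            raise ValueError("loop length must be >= 3")
        # nestedness (no pseudoknots): pairs sorted outer-to-inner
        prev = None
        for i, j in self.pairs:
            if prev is not None:
                pi, pj = prev
                if not (pi < i < j < pj):
                    raise ValueError("pairs must be nested")
            prev = (i, j)

    @property
    def span(self) -> tuple[int, int]:
        return (self.five_prime_base, self.three_prime_end)


@dataclass(frozen=True)
class MethylSite:
    """A DRACH/RRACH adenine, the canonical m6A deposition motif.

    ``position`` is the modifiable A (3rd base of the 5-mer).  The
    functional effect is either a scanning roadblock (``roadblock_strength``,
    a dimensionless slow-down factor >= 1) or a destabilisation of a
    hairpin stem it sits in (``stem_destabilization``, kcal/mol added to
    the hairpin delta_G while the site is modified).
    """

    position: int
    motif_class: frozenset  # subset of {"DRACH", "RRACH"}
    modified_nonstress: bool = False
    modified_stress: bool = False
    roadblock_strength: float = 1.0
    stem_destabilization: float = 0.0

    def __post_init__(self):
        if self.roadblock_strength < 1.0:
            raise ValueError("roadblock_strength must be >= 1")

    def modified(self, stress: bool) -> bool:
        return self.modified_stress if stress else self.modified_nonstress


@dataclass(frozen=True)
class FrameshiftSignal:
    """Candidate programmed-frameshift element: a slippery run (FS-A/FS-B
    style repeated codons or homopolymer) or a C-rich tract; for slippery
    runs the spacing to the nearest downstream C-tract is reported and a
    gap of exactly 8 nt is flagged optimal."""

    kind: str  # "FS-A" | "FS-B" | "C-tract"
    interval: tuple[int, int]
    spacing_to_ctract: int | None = None
    optimal_spacing: bool = False


@dataclass
class LeaderAnnotation:
    """A leader sequence plus every typed regulatory element in one
    coordinate frame; the simulator's track.

    ``manifest`` maps named architectural constraints (e.g.
    ``"uORF2_AUG_to_SL3_nt"``) to realised values.
    """

    name: str
    sequence: str
    cds_start: int
    allow_non_aug_cds: bool = False
    st_st: list[StStElement] = field(default_factory=list)
    uorfs: list[UORF] = field(default_factory=list)
    start_sites: list[StartSite] = field(default_factory=list)
    stem_loops: list[StemLoop] = field(default_factory=list)
    methyl_sites: list[MethylSite] = field(default_factory=list)
    frameshift_signals: list[FrameshiftSignal] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
        if not (1 <= self.cds_start <= len(self.sequence) - 2):
            raise ValueError("cds_start out of range")
        if self.codon_at(self.cds_start) != "AUG" and not self.allow_non_aug_cds:
            raise ValueError(
                f"cds_start codon is {self.codon_at(self.cds_start)}, expected AUG"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        return self.sequence[pos - 1]

    def codon_at(self, pos: int) -> str:
        return self.sequence[pos - 1 : pos + 2]

    def slice(self, start: int, end: int) -> str:
        """Inclusive 1-based slice."""
        return self.sequence[start - 1 : end]

    def validate(self) -> None:
        """Check element/sequence consistency invariants."""
        n = len(self.sequence)
        for st in self.st_st:
            assert self.codon_at(st.start) == "AUG", "St-st does not read AUG"
            assert self.codon_at(st.stop) in STOP_CODONS
        for u in self.uorfs:
            assert 1 <= u.start and u.end <= n, "uORF outside sequence"
            assert self.codon_at(u.start) == "AUG", "uORF start does not read AUG"
            if not u.stopless:
                assert self.codon_at(u.stop) in STOP_CODONS
        for s in self.start_sites:
            assert self.codon_at(s.position) == s.codon
        for m in self.methyl_sites:
            assert self.base(m.position) == "A", "methyl site not on an A"
        for sl in self.stem_loops:
            assert 1 <= sl.five_prime_base and sl.three_prime_end <= n

    def with_sequence(self, sequence: str, name: str | None = None) -> "LeaderAnnotation":
        """A bare copy carrying a new sequence (elements dropped; callers
        re-annotate)."""
        return LeaderAnnotation(
            name=name or self.name, sequence=sequence, cds_start=self.cds_start
        )


@dataclass(frozen=True)
class Edit:
    """One declarative construct edit."""

    kind: str  # substitution | insertion | start_knockout
    position: int = 0
    old: str = ""
    new: str = ""
    element: str = ""  # for start_knockout: manifest key of the AUG


@dataclass(frozen=True)
class ConstructSpec:
    """A named mutant construct as an ordered list of edits applied to the
    reference leader."""

    construct_id: str
    edits: tuple[Edit, ...]
    description: str = ""


def reverse_edits(spec: ConstructSpec) -> tuple[Edit, ...]:
    """Reverse substitution-only constructs (used for the involution
    property); insertions are not reversible through this path."""
    rev = []
    for e in reversed(spec.edits):
        if e.kind != "substitution":
            raise ValueError(f"cannot reverse {e.kind} edit")
        rev.append(replace(e, old=e.new, new=e.old))
    return tuple(rev)
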