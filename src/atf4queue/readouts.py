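"""Experimental observables computed from simulation output: reporter
fold changes, footprint/P-site/frame profiles, disome histograms, and
the in-silico RNase-protection assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import PIC, SimulationResult
from .scanner import PICFootprintModel
from .types import LeaderAnnotation, frame_between


# ---------------------------------------------------------------------------
# protein tables and fold changes

def protein_outputs(result: SimulationResult, leader: LeaderAnnotation) -> pd.DataFrame:
    """Per-start synthesis table with element labels and product size
    classes (ordinal labels by remaining ORF length; no molecular-weight
    physics)."""
    rows = []
    stst = {s.start for s in leader.st_st}
    uorf = {u.start: u for u in leader.uorfs}
    n = len(leader)
    for pos, count in sorted(result.initiation_counts.items()):
        if pos in stst:
            label, size = "St-st", "none"
        elif pos in uorf:
            label = f"uORF@{pos}"
            size = f"{uorf[pos].n_codons}aa"
        elif frame_between(pos, leader.cds_start) == 0 and pos >= leader.cds_start:
            rank = sum(
                1 for q in result.initiation_counts
                if q >= leader.cds_start and q < pos
                and frame_between(q, leader.cds_start) == 0
            )
            label = "main-ORF"
            size = f"FL-{(pos - leader.cds_start) // 3}aa" if pos > leader.cds_start else "FL"
        else:
            label, size = "other-frame", "n/a"
        rows.append(
            {
                "start": pos,
                "codon": leader.codon_at(pos),
                "element": label,
                "size_class": size,
                "initiations": count,
                "completed": result.protein_outputs.get(pos, 0),
            }
        )
    return pd.DataFrame(rows, columns=["start", "codon", "element", "size_class",
                                       "initiations", "completed"])


def atf4_output(result: SimulationResult) -> int:
    """Reporter signal: completed synthesis from all main-frame starts."""
    return result.main_orf_output()


@dataclass(frozen=True)
class FoldChange:
    estimate: float
    ci_low: float
    ci_high: float
    n_num: int
    n_den: int

    def __float__(self):
        return self.estimate


def fold_change(
    results_num: list[SimulationResult],
    results_den: list[SimulationResult],
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> FoldChange:
    """Ratio of mean reporter outputs with a percentile-bootstrap CI.

    The two replicate sets play the roles of the comparison's numerator
    and denominator (mutant vs WT at one condition, or stress vs
    non-stress for one construct)."""
    x = np.array([atf4_output(r) for r in results_num], dtype=float)
    y = np.array([atf4_output(r) for r in results_den], dtype=float)
    my, mx = y.mean(), x.mean()
    if my == 0:
        warnings.warn("denominator ensemble has zero output; fold change infinite")
        return FoldChange(float("inf"), float("inf"), float("inf"), len(x), len(y))
    est = mx / my
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bx = x[rng.integers(0, len(x), len(x))].mean()
        by = y[rng.integers(0, len(y), len(y))].mean()
        if by > 0:
            boots.append(bx / by)
    if boots:
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:  # pragma: no cover
        lo = hi = est
    return FoldChange(float(est), float(lo), float(hi), len(x), len(y))


# ---------------------------------------------------------------------------
# footprint profiles

@dataclass
class FootprintProfile:
    coverage: dict                      # species -> per-nt array (1-based index 0 unused)
    psite_hist: dict                    # species -> per-nt counts
    frame_fractions: dict               # region frame fractions (may be None)
    disome_5p_hist: np.ndarray
    length: int


def _footprints(snapshot, fp: PICFootprintModel, f80: int):
    up = fp.upstream_of_psite
    for species, psite, origin in snapshot:
        if species == PIC:
            yield species, psite, psite - up, psite + fp.downstream_of_psite - 1
        else:
            yield species, psite, psite - up, psite + f80 - 1 - up


def footprint_profile(
    result: SimulationResult,
    fp_model: PICFootprintModel | None = None,
    disome_pairing: str = "adjacent",
) -> FootprintProfile:
    """Coverage and P-site histograms over the stored snapshots.

    P-site assignment uses the known per-species footprint geometry (the
    simulation knows the truth; no offset inference).  The disome
    histogram records 5' ends of stacked-80S pairs; see
    :func:`disome_profile` for pairing semantics.
    """
    fp = fp_model or result.pic_footprint or PICFootprintModel()
    L = max(result.occupancy["PIC"].size if result.occupancy else 0,
            max((ps for _, snap in result.snapshots for _, ps, _ in snap), default=0) + 60)
    cov = {"PIC": np.zeros(L + 1), "80S": np.zeros(L + 1)}
    psite = {"PIC": np.zeros(L + 1), "80S": np.zeros(L + 1)}
    dis = np.zeros(L + 1)
    for _, snap in result.snapshots:
        for species, ps, lo, hi in _footprints(snap, fp, result.footprint_80S):
            key = "PIC" if species == PIC else "80S"
            cov[key][max(1, lo) : min(L, hi) + 1] += 1
            if 1 <= ps <= L:
                psite[key][ps] += 1
        for p5 in _disome_5p(snap, result.footprint_80S, fp.upstream_of_psite,
                             pairing=disome_pairing):
            if 1 <= p5 <= L:
                dis[p5] += 1
    return FootprintProfile(
        coverage={k: v[1:] for k, v in cov.items()},
        psite_hist={k: v[1:] for k, v in psite.items()},
        frame_fractions={},
        disome_5p_hist=dis[1:],
        length=L,
    )


def _disome_5p(snapshot, f80: int, up: int, pairing: str = "digest", slack: int = 0):
    """5' ends of stacked-80S pairs in one snapshot.

    pairing="adjacent": every adjacent pair with P-site gap == f80 (+/-
    slack) is reported (three stacked ribosomes give two pairs).
    pairing="digest": ribosomes are paired greedily from the 5' end into
    non-overlapping duos, emulating nuclease digestion of a packed queue
    into disome fragments; a trailing monosome is dropped.
    """
    e80 = sorted(ps for sp, ps, _ in snapshot if sp != PIC)
    out = []
    i = 0
    while i + 1 < len(e80):
        gap = e80[i + 1] - e80[i]
        if abs(gap - f80) <= slack:
            out.append(e80[i] - up)
            i += 2 if pairing == "digest" else 1
        else:
            i += 1
    return out


def disome_profile(
    result: SimulationResult,
    region: tuple[int, int] | None = None,
    pairing: str = "digest",
    slack: int = 0,
) -> tuple[np.ndarray, int | None]:
    """Disome 5'-end histogram and the modal peak-to-peak spacing.

    The spacing is the mode over distances between successive disome
    calls *within* one snapshot: the exact register of a queue drifts
    between snapshots (anchored at the stall or at the upstream start),
    so pooling 5' ends first would blur the periodicity.  None when no
    snapshot carries two calls."""
    L = max((ps for _, snap in result.snapshots for _, ps, _ in snap), default=0) + 60
    hist = np.zeros(L + 1)
    up = (result.pic_footprint or PICFootprintModel()).upstream_of_psite
    spacings: list[int] = []
    for _, snap in result.snapshots:
        calls = [
            p5 for p5 in _disome_5p(snap, result.footprint_80S, up,
                                    pairing=pairing, slack=slack)
            if not region or region[0] <= p5 <= region[1]
        ]
        for p5 in calls:
            if 1 <= p5 <= L:
                hist[p5] += 1
        spacings.extend(b - a for a, b in zip(calls, calls[1:]))
    if not spacings:
        return hist[1:], None
    vals, counts = np.unique(spacings, return_counts=True)
    return hist[1:], int(vals[np.argmax(counts)])


def _peak_positions(hist: np.ndarray, min_frac: float = 0.2) -> list[int]:
    """Local maxima at least ``min_frac`` of the global maximum."""
    if hist.max() <= 0:
        return []
    thr = min_frac * hist.max()
    peaks = []
    for i in range(1, len(hist) - 1):
        if hist[i] >= thr and hist[i] >= hist[i - 1] and hist[i] > hist[i + 1]:
            peaks.append(i)  # 1-based position = index (hist[0] is pos 0 pad)
    return peaks


def frame_distribution(
    result: SimulationResult, region: tuple[int, int]
) -> dict[int, float] | None:
    """Fractions of elongating-80S dwell time by origin reading frame
    (relative to the main ORF) within ``region``.  None when the region
    has no 80S coverage."""
    if result.occupancy_80s_frame is None:
        raise ValueError("run the simulation with record_occupancy=True")
    lo, hi = region
    sums = result.occupancy_80s_frame[:, lo - 1 : hi].sum(axis=1)
    total = sums.sum()
    if total <= 0:
        warnings.warn("no 80S coverage in region; frame fractions undefined")
        return None
    return {0: sums[0] / total, 1: sums[1] / total, -1: sums[2] / total}


# ---------------------------------------------------------------------------
# RNase-protection assay

@dataclass(frozen=True)
class Amplicon:
    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def default_amplicons(leader: LeaderAnnotation) -> list[Amplicon]:
    """A1 spans the uORF2 AUG to just before SL3 (132 nt on the
    reference); A2 sits immediately downstream of SL3, A3 in the middle
    of the main ORF; both control amplicons have A1's length."""
    m = leader.manifest
    u2 = m["uORF2_start"]
    sl = m["SL3_five_prime_base"]
    a1 = Amplicon("A1", u2, u2 + 131)
    a2_start = sl + 31
    a3_start = leader.cds_start + (len(leader) - leader.cds_start) // 2
    return [
        a1,
        Amplicon("A2", a2_start, a2_start + 131),
        Amplicon("A3", a3_start, a3_start + 131),
    ]


@dataclass
class ProtectionResult:
    mode: str                       # "HCHO" | "CHX"
    survival: dict                  # amplicon name -> surviving fraction
    enrichment: dict                # "A1/A2" -> ratio
    n_snapshots: int


def protection_assay(
    result_or_snapshots,
    amplicons: list[Amplicon],
    mode: str = "HCHO",
    fp_model: PICFootprintModel | None = None,
    footprint_80S: int = 30,
    pseudocount: float = 0.5,
    chx_retention: float = 0.8,
    seed: int = 0,
) -> ProtectionResult:
    """Fraction of snapshots in which each amplicon survives RNase
    digestion, and pairwise enrichment ratios.

    An amplicon survives iff every nucleotide of its interval is covered
    by a protected footprint: formaldehyde cross-linking (HCHO) preserves
    both PIC and 80S footprints; cycloheximide (CHX) preserves 80S only,
    and being non-cross-linking it retains each 80S only with probability
    ``chx_retention`` through the digestion (a nuisance parameter of the
    emulated chemistry).  Ratios are guarded with a pseudocount so an
    all-or-nothing survival pattern yields a finite enrichment.
    """
    if mode not in ("HCHO", "CHX"):
        raise ValueError("mode must be HCHO or CHX")
    if not (0.0 <= chx_retention <= 1.0):
        raise ValueError("chx_retention must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(result_or_snapshots, SimulationResult):
        snaps = [s for _, s in result_or_snapshots.snapshots]
        fp = fp_model or result_or_snapshots.pic_footprint or PICFootprintModel()
        f80 = result_or_snapshots.footprint_80S
    else:
        snaps = list(result_or_snapshots)
        fp = fp_model or PICFootprintModel()
        f80 = footprint_80S
    if not snaps:
        raise ValueError("empty snapshot ensemble")
    for a in amplicons:
        if a.start < 1:
            raise ValueError(f"amplicon {a.name} outside the leader")

    surv = {a.name: 0 for a in amplicons}
    for snap in snaps:
        intervals = []
        for species, ps, lo, hi in _footprints(snap, fp, f80):
            if mode == "CHX":
                if species == PIC:
                    continue
                if chx_retention < 1.0 and rng.random() > chx_retention:
                    continue
            intervals.append((lo, hi))
        intervals.sort()
        # merge and test full coverage per amplicon
        merged = []
        for lo, hi in intervals:
            if merged and lo <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        for a in amplicons:
            if any(lo <= a.start and a.end <= hi for lo, hi in merged):
                surv[a.name] += 1
    n = len(snaps)
    survival = {k: v / n for k, v in surv.items()}
    enrich = {}
    for a in amplicons:
        for b in amplicons:
            if a.name != b.name:
                enrich[f"{a.name}/{b.name}"] = (surv[a.name] + pseudocount) / (
                    surv[b.name] + pseudocount
                )
    return ProtectionResult(mode=mode, survival=survival, enrichment=enrich, n_snapshots=n)
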