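# Methods

`atf4queue` models translational control of an ATF4-like mRNA leader as a
single-molecule stochastic process on a one-nucleotide-resolution track,
and derives from it the observables a reporter/ribosome-profiling study
would measure. This note documents the model, its assumptions, the
packaged synthetic leader, the parameterisation, and what the tests do
and do not establish.

## The model

**Scanning and initiation.** 43S/48S pre-initiation complexes (PICs) load
at the cap at rate `k_load` whenever the first footprint-width of the
leader is unoccupied, and scan strictly 5'→3' in 1-nt steps with
exponential waiting times (rate `v_scan`). A PIC is initiation-competent
only while carrying the ternary complex (TC = eIF2·GTP·Met-tRNAi). TC is
(re-)acquired at rate `k_tc · tc_level`, where `tc_level ∈ [0, 1]` is the
condition knob: 1.0 under non-stress, a fitted small value under stress
(eIF2α phosphorylation depletes TC). Cap-loaded PICs carry TC with
probability `p_tc_at_load`; the engine default is 1.0, the calibrated set
uses 0.0 so that cap-proximal initiation is also TC-limited — without
this, a leader whose only upstream element is the overlapping inhibitory
uORF has no TC-sensitive step at all and cannot be stress-inducible,
contradicting the measured ~3.2-fold induction of the uORF2-only
construct.

A TC-bound PIC dwelling on a start codon initiates with per-dwell
probability `p` set by codon identity and Kozak class (strong/medium/weak
from the −3/+4 rule). Internally this is an initiation rate
`r = v_scan · p/(1−p)` racing against the hop out of the codon, so at an
unperturbed position the per-visit initiation probability is exactly `p`,
and anything that slows departure (a stall, a roadblock) automatically
raises the realised initiation probability — the mechanism by which a
hairpin-stalled PIC preferentially fires the near-cognate CUG sitting in
its P site.

**Elongation, termination, reinitiation.** 80S ribosomes hop 3 nt at rate
`v_elong`, terminate at their stop codon after an exponential dwell
(`k_term`), and release the mRNA — except after a reinitiation-permissive
uORF (short, not overlapping the main ORF), where the 40S resumes
scanning TC-less with probability `p_rei_uorf`, or after the start-stop,
with its own `p_rei_stst`. The overlapping uORF2 and the main ORF always
recycle fully. A start-stop initiation event converts directly to a
terminating ribosome (roadblock) at the element.

**Exclusion and queuing.** Footprints never overlap: a scanning PIC
covers 12 nt behind its P site (excluded) and 20 nt from the P site
(included) to the entry channel (the configurable midpoint of the
reported 15–25 nt range); an 80S covers 30 nt with the same 12-nt
upstream extent. Any ribosome whose leading edge abuts a folded hairpin
stalls and is released at `k0_unwind · exp(ΔG_eff / dG_scale)`;
elongating 80S release faster by the factor `unwind_mult_80S`,
reflecting their intrinsic helicase activity — this separation is what
lets a construct with all upstream starts removed express at ~23× the
wild-type level (80S traffic drains through the hairpin) while scanning
PICs still stall hard there. A PIC blocked behind another ribosome may
initiate at any start codon within ±`migration_window` (15 nt) of its P
site at `queue_boost ×` the normal rate; this implements queue-assisted
start-codon selection as an initiation-eligibility window rather than
literal diffusion.

**Methylation-site effects.** DRACH/RRACH adenines flagged as modified
under the current condition act in one of two ways, chosen by geometry:
an adenine inside a folded stem adds `a326_destab` kcal/mol to that
hairpin's effective ΔG (destabilisation); any other modified adenine
divides the PIC scanning rate by `m6a_block` at that position (a
roadblock for scanning subunits only — 80S elongate through it). In the
packaged leader the RRACH1 adenine (A235 analog, inside uORF2 but
upstream of the overlap) is a non-stress roadblock that specifically
gates the *leaky-scanning* path toward the main ORF, because TC-replete
PICs initiate at the uORF2 AUG before ever reaching it; the RRACH2
adenine (A326 analog) sits in the SL3 stem and weakens it under
non-stress. Both demethylate under stress.

**Determinism.** One named RNG (`numpy.random.default_rng(seed)`) drives
every stochastic choice; identical (leader, params, seed) give identical
event logs. Event selection is Gillespie-style over the instantaneous
rate list.

## The packaged synthetic leader

The published architecture gives constraints, not a sequence, so the
package assembles one deterministically: elements are pinned at fixed
coordinates — start-stop at 87, 3-codon uORF1 at 121, 60-codon uORF2 at
168 in the −1 frame, main AUG1/AUG2 at 283/289 (medium context), AUG3 at
331 (weak, 17th codon, exposed in the SL3 loop), CUG at 298 (weak, main
frame, 20 nt upstream of SL3), SL3 at 318 (150 nt from the uORF2 AUG,
ΔG = −16.1 kcal/mol under the packaged energy table, within the stated
tolerance of the printed −15.40), DRACH/RRACH adenines at 225/235/286/326
with control adenines at 267/311, a triple-glycine slippery run inside
the SL3 stem and a C-tract 8 nt downstream — and the gaps are filled with
seeded pseudo-random background under rejection rules (no spurious
AUG/CUG anywhere, no stops in the main-ORF or uORF2 frames, no stray
methylation motifs or slippery runs, no competing hairpin ≤ −10 kcal/mol
anywhere on the track, including after every single-edit mutant of the
construct registry). Coordinates are 1-based inclusive throughout;
BED/bedGraph conversion happens only at the I/O boundary.

Two architectural choices the source leaves open: uORF1 is built with 3
sense codons (the figure-legend reading of the "3- vs 4-codon"
discrepancy), and the RRACH2 adenine is placed in the SL3 *stem* (the
methods-section reading; the loop placement is reserved as a constructor
option). The start-stop is given a weak context and `p_rei_stst = 0.3`
because the printed construct series shows removing it costs almost no
flux (d2 ≈ uORF1-only); its roadblock character comes from the
`stst_block` scanning slow-down. uORF2 is given a strong context: the
delayed-reinitiation literature requires it to capture essentially every
TC-bound scanner.

The hairpin model is a hairpin-only dynamic programme (single stem,
bulges/internal loops ≤ 12 nt, no multiloops or pseudoknots) over a
compact Turner-style stack/loop table packaged as code constants.
Because the table is reduced and the published folding tool is
unspecified, ΔG values carry a documented ±2 kcal/mol tolerance.
Candidate hairpins are collected over 60-nt windows stepped by 30 nt;
the canonical re-fold of an edited sequence is the full-sequence scan.

## Calibration

The only quantitative data the study prints for the mechanism are mutant
reporter expression ratios (0.2–22.7×), so the calibration stage fits the
free parameters by weighted mean squared log-ratio error over that
table, simulating every construct/condition per evaluation with
replicate seeds that are stable across evaluations (common random
numbers). Eight parameters are free — `tc_level_stress`, `k_tc`,
`p_AUG_medium`, `p_CUG_weak`, `k0_unwind`, `unwind_mult_80S`,
`queue_boost`, `m6a_block` — the rest are pinned to documented values
(`k_load = 0.18/s`, `v_scan = 5 nt/s`, `v_elong = 4 codons/s`,
`p_rei_uorf = 0.54` from the printed 12.2/22.7 arithmetic,
`p_rei_stst = 0.3`, `stst_block = 4`, `p_AUG_strong = 0.97`,
`a326_destab = 2.2 kcal/mol`, `p_tc_at_load = 0`). The three headline
ratios (WT induction 5.2, d-all/WT 22.7, uORF2-only induction 3.2) carry
triple weight, and fold-change measurements are taken over a 2400-s
horizon so the pre-jam transient (the first few hundred seconds before
the non-stress queue establishes) does not inflate basal expression.
The committed set in `data/calibrated_params.json` is the product of the
staged calibration campaign — bounded coarse exploration followed by
local refinement against the packaged table — and the file records the
exact `fit_parameters` invocation (seed, start, budget) that regenerates
it deterministically.

Known residual misfits, accepted rather than tuned away: the uORF2-only
*absolute* level sits above the printed 0.2× of WT (suppressing it to
0.2 requires a standing 80S queue dense enough to recapture every leaky
scanner, which would simultaneously throttle the d-all construct and
destroy the 22.7× dynamic range — the model cannot satisfy both with a
single unwinding rate, and resolving it in favour of the graded dynamic
range is a deliberate choice); the A326G construct matches the printed
~20% reduction under non-stress (losing the destabilising modification
makes SL3 more inhibitory) but not under stress, where the modification
is absent in both genotypes and the refolded mutant stem is marginally
weaker — the source itself flags this site's behaviour as paradoxical;
the SL3-unfolding mutants relieve queuing (clearly visible in the
protection-assay readout) but gain less reporter expression than the
printed 1.3–1.8× because part of the leak that SL3 suppresses in the
model is re-routed rather than blocked; and the protection assay does
not reproduce a higher absolute formaldehyde enrichment under stress
than under non-stress — in this model the non-stress condition carries
the denser standing 80S queue, and the stress signature appears instead
as near-total 40S-dependence of the protection (the HCHO/CHX contrast
is an order of magnitude larger under stress), which is the
mixed-queue conclusion that figure supports.

## Emulated readouts

Reporter output is the completed synthesis count from all main-frame
starts at/after AUG1 (the tag sits at the protein's C terminus, so every
N-truncated isoform scores). Fold changes are ratios of ensemble means
with percentile-bootstrap CIs over replicates. Footprint profiles place
P sites from the known per-species geometry (truth is known; no offset
inference). Disome calling pairs stacked 80S (P-site gap exactly 30 nt,
optional ±2 slack): the default "digest" mode pairs greedily from the 5'
end into non-overlapping duos, emulating nuclease digestion of a packed
queue into disome fragments and yielding the observed 60-nt peak
spacing; "adjacent" mode reports every stacked pair. The protection
assay scores an amplicon as surviving a snapshot iff every nucleotide is
covered by a protected footprint — formaldehyde mode counts PIC and 80S
footprints, cycloheximide mode 80S only (hence HCHO survival ≥ CHX
survival identically) — with a pseudocount guard on enrichment ratios;
snapshots are sampled at fixed intervals after a 20% burn-in.  Two
further conventions: the cycloheximide mode retains each 80S footprint
only with probability `chx_retention` (default 0.8) per snapshot — a
nuisance parameter standing in for the poorer preservation of
non-cross-linked complexes through digestion, required for the
HCHO-vs-CHX contrast of a pure 80S queue — and the modal disome spacing
is computed over distances between successive disome calls *within* one
snapshot, because the queue's register drifts between snapshots
(anchored alternately at the stall or at the upstream start codon) and
pooling 5' ends first would blur the 60-nt periodicity into 12-nt
artifacts.  Protection-assay comparisons are reported for
queue-promoting unwinding (`k0_unwind = 0.02/s`, as in the disome
readout): at the calibrated release rate, full-amplicon protection
events are too rare for the all-nucleotides survival rule to quantify —
a coarseness of the modeled chemistry (real qPCR also amplifies from
partially protected ensembles), not of the queue itself.

## Verification strategy

Two independent oracles check the engine. The collision-free limit is
evaluated exactly by a forward recursion over (TC-bound, TC-less)
scanning weights with per-position exponential races; the engine with
exclusion disabled must match it on the full reference leader. The full
model with exclusion is solved exactly on short leaders as a
continuous-time Markov chain over all ≤2-ribosome configurations
(stationary flux fractions via the sparse generator); the engine with a
2-ribosome cap must match within Monte-Carlo error. The two oracles must
agree exactly with each other in the 1-ribosome case. Conservation
(loads = scanned-off + recycled + run-off + active) holds exactly for
every run; exclusion and queue geometry (≤5 ribosomes between the uORF2
AUG and SL3, 30-nt packing) are asserted over sampled snapshots.

What the synthetic data do *not* establish: the packaged leader mimics
printed spacings and motif classes, not the real transcript's sequence
content, codon usage, or secondary-structure background; footprints are
generated with known geometry rather than library-prep biases; and no
claim is made that the fitted rates are the physiological ones — the
printed table cannot identify absolute time scales (e.g. `k_load` cancels
from every ratio, which the parameter-recovery harness flags as a flat
loss axis).

## Problem sizes

Default study conditions simulate single mRNA molecules for 1200 s of
model time at `k_load = 0.25/s` (≈100–300 loads per run depending on
jamming), with ≥20 replicates per construct/condition for calibrated
comparisons and ≥100 steady-state snapshots per run for ensemble
readouts. The calibration fit uses 5 replicates of 1000 s per
construct/condition per loss evaluation.
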