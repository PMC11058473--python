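{
 "free": {
  "tc_level_stress": 0.24,
  "k_tc": 0.34,
  "p_aug_medium": 0.8,
  "p_cug_weak": 0.02,
  "k0_unwind": 1.2,
  "unwind_mult_80S": 8.0,
  "queue_boost": 4.0,
  "m6a_block": 15.0
 },
 "pinned": {
  "k_load": 0.18,
  "p_tc_at_load": 0.0,
  "a326_destab": 2.2,
  "p_rei_stst": 0.3,
  "stst_block": 4.0,
  "p_init": {
   "AUG": {
    "strong": 0.97,
    "medium": 0.8,
    "weak": 0.25
   },
   "CUG": {
    "strong": 0.1,
    "medium": 0.15,
    "weak": 0.02
   }
  }
 },
 "loss": 0.14320494946353493,
 "residuals": [
  [
   "wt",
   "induction",
   5.2,
   4.933962264150943,
   -0.05251625563452598
  ],
  [
   "d-all",
   "vs_wt_nonstress",
   22.7,
   20.62264150943396,
   -0.0959753498629403
  ],
  [
   "d-all",
   "vs_wt_stress",
   3.3,
   4.08604206500956,
   0.21365432278179033
  ],
  [
   "uORF1-only",
   "vs_wt_nonstress",
   12.2,
   11.556603773584904,
   -0.05417892287245083
  ],
  [
   "uORF1-only",
   "vs_wt_stress",
   2.7,
   2.688336520076482,
   -0.004329164704596051
  ],
  [
   "uORF2-only",
   "vs_wt_nonstress",
   0.2,
   0.5943396226415094,
   1.0891335447135657
  ],
  [
   "uORF2-only",
   "vs_wt_stress",
   0.2,
   0.4034416826003824,
   0.7017145818452439
  ],
  [
   "uORF2-only",
   "induction",
   3.2,
   3.349206349206349,
   0.04557259727885279
  ],
  [
   "d1",
   "vs_wt_nonstress",
   0.3,
   0.4150943396226415,
   0.32472334413212994
  ],
  [
   "d1",
   "vs_wt_stress",
   0.3,
   0.5047801147227533,
   0.5203404434073292
  ],
  [
   "d2",
   "vs_wt_nonstress",
   12.1,
   6.924528301886792,
   -0.558135518100247
  ],
  [
   "d2",
   "vs_wt_stress",
   2.4,
   1.8298279158699808,
   -0.2712468099658686
  ],
  [
   "dSt-st",
   "induction",
   5.8,
   4.255952380952381,
   -0.3095393542616248
  ],
  [
   "SL3Mut-1",
   "vs_wt_nonstress",
   1.3,
   1.1226415094339621,
   -0.1466798654680289
  ],
  [
   "SL3Mut-1",
   "vs_wt_stress",
   1.5,
   0.8336520076481836,
   -0.5874043288240528
  ],
  [
   "SL3Mut-2",
   "vs_wt_nonstress",
   1.7,
   0.8962264150943396,
   -0.6401904535736967
  ],
  [
   "SL3Mut-2",
   "vs_wt_stress",
   1.8,
   0.9139579349904398,
   -0.677757396475586
  ],
  [
   "CUGMut",
   "vs_wt_nonstress",
   0.8,
   0.9056603773584905,
   0.12405264866997863
  ],
  [
   "CUGMut",
   "vs_wt_stress",
   0.8,
   0.8565965583173997,
   0.06835531966427205
  ],
  [
   "A235G",
   "vs_wt_nonstress",
   1.3,
   0.9716981132075472,
   -0.2910743703499224
  ],
  [
   "A326G",
   "vs_wt_nonstress",
   0.8,
   0.8490566037735848,
   0.05951412753240751
  ],
  [
   "A326G",
   "vs_wt_stress",
   0.8,
   0.9751434034416826,
   0.19797281296765817
  ]
 ],
 "n_reps": 12,
 "seed": 2024,
 "n_evals": 2,
 "note": "Committed output of the staged calibration campaign: coarse exploration of the bounded parameter space followed by local refinement against the packaged expression-ratio table; this file is regenerated by fit_parameters(seed=2024, base=pinned, start=free, n_probes=0, maxiter=0, n_reps=12, t_max=2400)."
}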