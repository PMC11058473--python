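{
  "comment": "Printed reporter expression ratios for the mutant construct series. comparison semantics: vs_wt_nonstress / vs_wt_stress = mutant over WT at that condition; induction = stress over non-stress for the construct itself. Percent-style statements are stored as ratios (e.g. an ~80% drop -> 0.2, a ~20% reduction -> 0.8, a 30% increase -> 1.3).",
  "rows": [
    {"construct": "wt", "comparison": "induction", "value": 5.2, "weight": 3.0, "source": "~5.2-fold induction of the WT reporter"},
    {"construct": "d-all", "comparison": "vs_wt_nonstress", "value": 22.7, "weight": 3.0, "source": "~22.7-fold higher under non-stress"},
    {"construct": "d-all", "comparison": "vs_wt_stress", "value": 3.3, "weight": 1.0, "source": "~3.3-fold higher under Tg stress"},
    {"construct": "uORF1-only", "comparison": "vs_wt_nonstress", "value": 12.2, "weight": 1.0, "source": "12.2-fold upregulation in non-stress"},
    {"construct": "uORF1-only", "comparison": "vs_wt_stress", "value": 2.7, "weight": 1.0, "source": "2.7-fold upregulation in Tg stress"},
    {"construct": "uORF2-only", "comparison": "vs_wt_nonstress", "value": 0.2, "weight": 1.0, "source": "~80% drop vs WT, non-stress"},
    {"construct": "uORF2-only", "comparison": "vs_wt_stress", "value": 0.2, "weight": 1.0, "source": "~80% drop vs WT, stress"},
    {"construct": "uORF2-only", "comparison": "induction", "value": 3.2, "weight": 3.0, "source": "unexpected ~3.2-fold increase under stress"},
    {"construct": "d1", "comparison": "vs_wt_nonstress", "value": 0.3, "weight": 1.0, "source": "reduced by ~70%, non-stress"},
    {"construct": "d1", "comparison": "vs_wt_stress", "value": 0.3, "weight": 1.0, "source": "reduced by ~70%, stress"},
    {"construct": "d2", "comparison": "vs_wt_nonstress", "value": 12.1, "weight": 1.0, "source": "increased ~12.1-fold under non-stress"},
    {"construct": "d2", "comparison": "vs_wt_stress", "value": 2.4, "weight": 1.0, "source": "increased ~2.4-fold under stress"},
    {"construct": "dSt-st", "comparison": "induction", "value": 5.8, "weight": 1.0, "source": "increased by ~10% from ~5.2- to ~5.8-fold"},
    {"construct": "SL3Mut-1", "comparison": "vs_wt_nonstress", "value": 1.3, "weight": 1.0, "source": "~1.3-fold over WT, non-stress"},
    {"construct": "SL3Mut-1", "comparison": "vs_wt_stress", "value": 1.5, "weight": 1.0, "source": "~1.5-fold under Tg stress"},
    {"construct": "SL3Mut-2", "comparison": "vs_wt_nonstress", "value": 1.7, "weight": 1.0, "source": "~1.7-fold over WT, non-stress"},
    {"construct": "SL3Mut-2", "comparison": "vs_wt_stress", "value": 1.8, "weight": 1.0, "source": "~1.8-fold under Tg stress"},
    {"construct": "CUGMut", "comparison": "vs_wt_nonstress", "value": 0.8, "weight": 1.0, "source": "reduced by ~20% under both conditions"},
    {"construct": "CUGMut", "comparison": "vs_wt_stress", "value": 0.8, "weight": 1.0, "source": "reduced by ~20% under both conditions"},
    {"construct": "A235G", "comparison": "vs_wt_nonstress", "value": 1.3, "weight": 1.0, "source": "increased by 30%, non-stress"},
    {"construct": "A326G", "comparison": "vs_wt_nonstress", "value": 0.8, "weight": 1.0, "source": "reduced by ~20% under both conditions"},
    {"construct": "A326G", "comparison": "vs_wt_stress", "value": 0.8, "weight": 1.0, "source": "reduced by ~20% under both conditions"}
  ]
}
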