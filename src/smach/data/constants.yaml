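# Default dosimetry constants: molecular weights (g/mol), urinary excretion
# factors (molar fraction of ingested diester recovered as the measured
# metabolites), and one-compartment toxicokinetic parameters.
version: 1
toxicokinetics:
  t_half_days: 0.4
  v_d_l_per_kg: 0.2
  ce_g_per_kg_day: 0.023
parents:
  dep:
    mw_diester: 222
    f_ue: 0.69
    metabolites:
      mep: 194
  dbp:
    mw_diester: 278
    f_ue: 0.69
    metabolites:
      mbp: 222
  bbzp:
    mw_diester: 312
    f_ue: 0.73
    metabolites:
      mbzp: 256
  dehp:
    mw_diester: 391
    f_ue: 0.452
    metabolites:
      mehp: 278
      mehhp: 294
      meohp: 292
      mecpp: 308
  dinp:
    mw_diester: 419
    f_ue: 0.298
    metabolites:
      mhinp: 308
      moinp: 306
      mciop: 322
  bpa:
    mw_diester: 228
    f_ue: 0.54
    metabolites:
      bpa: 228
  triclosan:
    mw_diester: 290
    f_ue: 0.54
    metabolites:
      triclosan: 290
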