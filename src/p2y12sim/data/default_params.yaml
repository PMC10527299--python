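drugs:
  clopidogrel:
    binding:
      K_T: 0.0
      k_off: 0.0
      k_on: 0.00530901
      mode: competitive_irreversible
    pk:
      CL: 0.0
      Q: 0.0
      V_c: 1.0
      V_p: 1.0
      f_m: 0.3
      k_me: 1.386294
      ka: 0.898309
      lag_h: 0.5
      model: prodrug_metabolite
  prasugrel:
    binding:
      K_T: 0.0
      k_off: 0.0
      k_on: 0.106617
      mode: competitive_irreversible
    pk:
      CL: 0.0
      Q: 0.0
      V_c: 1.0
      V_p: 1.0
      f_m: 0.3
      k_me: 0.231088
      ka: 2.0
      lag_h: 0.25
      model: prodrug_metabolite
  selatogrel:
    binding:
      K_T: 0.0
      k_off: 8.0
      k_on: 38.5556
      mode: competitive_reversible
    pk:
      CL: 0.419362
      Q: 0.0977786
      V_c: 1.0
      V_p: 0.414211
      f_m: 1.0
      k_me: 0.0
      ka: 4.3518
      lag_h: 0.0
      model: two_compartment_sc
  ticagrelor:
    binding:
      K_T: 3.52494
      k_off: 0.0
      k_on: 0.0
      mode: noncompetitive_reversible
    pk:
      CL: 0.0881172
      Q: 0.0
      V_c: 1.0
      V_p: 1.0
      f_m: 1.0
      k_me: 0.0
      ka: 0.798588
      lag_h: 0.5
      model: one_compartment_oral
pdlink:
  PRU0: 200.0
  gamma_pru: 0.4306766
provenance:
  calibration_seed: 20230908
  maxfev: 60
  n_starts: 2
  objective: 3.42552
  residuals:
    clopidogrel_600_peak_ipa: -0.2863
    clopidogrel_maintenance_interval_1: 0.02381
    clopidogrel_maintenance_interval_2: 0.0803
    clopidogrel_maintenance_interval_3: 0.06569
    clopidogrel_metabolite_half_life: 1.302e-06
    clopidogrel_onset: 0.0
    gap_minimum_placebo: -0.2353
    gap_minimum_selatogrel: 0.5178
    prasugrel_after_selatogrel_24h: 0.0
    prasugrel_onset: 0.0
    selatogrel_distribution_half_life: 0.0
    selatogrel_duration_above_85: 0.0
    selatogrel_max_ipa: 0.0
    selatogrel_onset: 0.0
    selatogrel_return_to_baseline_24h: 2.652
    selatogrel_terminal_half_life: 0.0
    selatogrel_tmax: 0.0
    ticagrelor_maintenance_floor: 0.0
    ticagrelor_maintenance_floor_selatogrel: 0.0
    ticagrelor_onset: 0.0
system:
  PRU0: 200.0
  R0: 1.0
  k_out: 0.00423764
  weight_kg: 70.0
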