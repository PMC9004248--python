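# Fixed internal constants of the closed-loop circulation.
# Calibrated once so that the 60-year control subject reproduces normal
# adult hemodynamics (SAP ~140/74, MAP ~103 mmHg, CO ~5.5 l/min,
# LVEF ~58%) together with a realistic peripheral pulse (incisura near
# end-systole, single dicrotic wave, vanishing notch under
# vasodilation) and a stressed-volume reserve that tolerates a 30%
# blood-volume deficit.  Never fitted at run time.
version: 1
arterial:
  # fractions of total systemic arterial compliance (1/sys_art_stiffness)
  f_ao: 0.45
  f_a1: 0.25
  f_a2: 0.30
  r_seg1: 0.03         # mmHg*s/ml, aorta -> conduit artery
  r_seg2: 0.06         # conduit -> peripheral artery
  l_av: 0.0004         # mmHg*s^2/ml, aortic valve inertance
  l_seg1: 0.004
  l_seg2: 0.006
  v0_ao: 60.0          # ml, unstressed volumes
  v0_a1: 120.0
  v0_a2: 60.0
  b_nonlin: 60.0       # mmHg, exponential wall law P = B*(exp(dV/Vs)-1)
  p_anchor: 100.0      # mmHg, pressure where compliance matches the table
valves:
  r_mitral: 0.004      # mmHg*s/ml
  r_aortic: 0.006
  r_tricuspid: 0.003
  r_pulmonary: 0.004
heart:
  lam_lv: 0.011        # 1/ml, exponential end-diastolic P-V curvature
  s_scale_lv: 115.0    # maps tabulated LV stiffness to the exponential scale
  v0_lv: 10.0          # ml
  lam_rv: 0.011
  s_scale_rv: 95.0
  v0_rv: 15.0
  e_la: 0.3            # mmHg/ml, passive atrial elastances
  v0_la: 20.0
  e_ra: 0.2
  v0_ra: 20.0
  ees_anchor_lv: 2.62  # mmHg/ml, contractility index -> elastance anchor
  ees_gamma: 1.3       # power-law exponent of that mapping
venous:
  r_venous_return: 0.14    # mmHg*s/ml, veins -> right atrium
  svr_scale: 0.93          # distal arteriolar share of the tabulated SVR
pulmonary:
  c_pv: 13.0           # ml/mmHg, pulmonary venous compliance
  v0_pa: 60.0
  v0_pv: 300.0
  r_pv_la: 0.012
activation:
  tau1_frac: 0.269     # rise time constant, fraction of cardiac period
  m1: 1.9
  tau2_frac: 0.37      # relaxation onset, fraction of cardiac period
  m2: 25.0
  edv_ref: 145.0       # ml; ejection time scales as (EDV/edv_ref)^edv_exponent
  edv_exponent: 0.5
thorax:
  ppl0: -4.0           # mmHg, resting pleural pressure
  resp_mmhg_per_l: 5.0 # peak-to-trough pleural swing per liter tidal volume
init_pressures:        # start-up distribution targets [mmHg; ventricles ml]
  p_ao: 95.0
  p_a1: 93.0
  p_a2: 92.0
  p_sv: 13.0
  p_pa: 20.0
  p_pv: 12.0
  p_la: 12.0
  p_ra: 7.0
  v_lv_init: 140.0
  v_rv_init: 140.0
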