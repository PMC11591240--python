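# Reference microkinetic parameters for H2 oxidation on Pd(111).
# Energies in J/mol, prefactors in s^-1, site area in m^2, masses in amu.
adsorption:
  O2:
    mass_amu: 32.0
    sticking: 1.0
    site_area: 4.37e-26
    theta_rot: 2.1
    sigma: 2
    e_ads: 0.0
    e_des: 77.0e+3
  H2:
    mass_amu: 2.0
    sticking: 0.5
    site_area: 4.37e-26
    theta_rot: 87.9
    sigma: 2
    e_ads: 0.0
    e_des: 96.0e+3
surface:
  "H*+O*<->OH*+*":
    beta_f: 1.228e+13
    e_f: 94570.0
    beta_b: 1.66e+13
    e_b: 97369.0
  "H*+OH*<->H2O*+*":
    beta_f: 1.03e+13
    e_f: 47285.0
    beta_b: 1.03e+13
    e_b: 95535.0
  "2OH*<->H2O*+O*":
    beta_f: 4.97e+13
    e_f: 4825.0
    beta_b: 5.166e+13
    e_b: 20265.0
  "H2O*->H2O+*":
    beta_f: 7.288e+15
    e_f: 43425.0
    beta_b: 0.0
    e_b: 0.0
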