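{
  "name": "q-TIP4P/F",
  "version": 1,
  "units": {"length": "nm", "energy": "kJ/mol", "charge": "e", "angle": "rad"},
  "stretch": {
    "D_r": 485.72056,
    "alpha_r": 22.87,
    "r_eq": 0.09419
  },
  "bend": {
    "k_theta": 367.5644,
    "theta_eq": 1.8744836134
  },
  "lj": {
    "epsilon": 0.7749168,
    "sigma": 0.31589
  },
  "charges": {
    "q_H": 0.5564,
    "q_M": -1.1128
  },
  "m_site_weight": 0.73612,
  "r_c": 1.0,
  "eps_rf": 78.3,
  "notes": "Flexible 4-site water potential: quartic Morse expansion on the OX stretch, harmonic bend, LJ on O, massless charged M site on the bisector. Energies converted from kcal/mol with 1 kcal = 4.184 kJ. Constants are isotope-independent."
}
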