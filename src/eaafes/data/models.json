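{
  "schema_version": 1,
  "description": "Identified SOPDT parameters per subject (k in N per unit r_E, omega_n in rad/s, zeta fixed at 1, tau in s). 'eq12' is the printed worked-example model, stored verbatim.",
  "subjects": {
    "A": {"schema_version": 1, "k": 11.22, "omega_n": 20.5, "zeta": 1.0, "tau": 0.050},
    "B": {"schema_version": 1, "k": 8.91, "omega_n": 20.5, "zeta": 1.0, "tau": 0.045},
    "C": {"schema_version": 1, "k": 1.73, "omega_n": 31.4, "zeta": 1.0, "tau": 0.090},
    "D": {"schema_version": 1, "k": 1.04, "omega_n": 14.0, "zeta": 1.0, "tau": 0.100},
    "E": {"schema_version": 1, "k": 6.61, "omega_n": 25.1, "zeta": 1.0, "tau": 0.100},
    "F": {"schema_version": 1, "k": 6.96, "omega_n": 18.0, "zeta": 1.0, "tau": 0.095},
    "eq12": {"schema_version": 1, "k": 11.22, "omega_n": 20.5, "zeta": 1.0, "tau": 0.05}
  }
}
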