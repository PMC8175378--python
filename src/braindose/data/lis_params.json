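{
  "id": "burger2000-usoskin2005",
  "comment": "Analytic proton local interstellar spectrum J(P) = c1 * P^-c2 / (1 + c3 * P^-c4), P = sqrt(T(T+2*Tr)) in GeV, J in particles m^-2 sr^-1 s^-1 (GeV/nuc)^-1, T kinetic energy per nucleon in GeV.",
  "c1": 19000.0,
  "c2": 2.78,
  "c3": 0.4866,
  "c4": 2.51,
  "nucleon_rest_energy_GeV": 0.938272,
  "abundance_relative_to_H": {
    "H": 1.0,
    "He": 0.1379,
    "C": 0.00383,
    "N": 0.00383,
    "Fe": 0.00383
  }
}
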