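# Physical and critical properties of empagliflozin (solute) and CO2 (solvent).
# Solute critical constants are group-contribution estimates (Fedors, Joback,
# Lee-Kesler/Klincewicz, Immirzi-Perini, Jain); they are treated as data here.
# Pc values are in Pa; Vs and V2 in m^3/mol; sublimation pressures in Pa.
solute:
  name: empagliflozin
  M: 450.9
  Tm: 426.1
  dHm: 60238.0
  Tc: 870.367
  Pc: 1.87565e+6
  omega: 0.479
  Vs: 1.84397e-4
  V2: 3.2699e-4
  Psub:
    308.0: 0.0034
    318.0: 0.0089
    328.0: 0.022
    338.0: 0.0508
solvent:
  name: carbon dioxide
  M: 44.01
  Tc: 304.18
  Pc: 7.38e+6
  rho_c: 467.6
  omega: 0.225
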