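# Reference model configuration: a 4-compartment Golgi reactor cascade
# (cis, medial, trans, trans-Golgi network) processing N-glycans released
# from the ER as Man9 plus a small inert mono-glucosylated fraction.
#
# Residence times, donor levels, total glycan concentration and enzyme
# localization are order-of-magnitude literature estimates; enzyme activity
# levels (kf_base * Et_total / c_tot, min^-1) default to the fitted
# low-passage LNCaP profile.  See docs/methods.md for rationale.

seeds:
  - "Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN"          # Man9
  - "Ga3Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN"       # Glc1Man9, inert (Ga3 cap)

inlet:
  "Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN": 0.95
  "Ga3Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN": 0.05

mass_cutoff: 4000.0          # permethylated sodiated monoisotopic Da
pruning_enabled: true
prune_threshold: 9.102e-7    # min relative outlet abundance retained (calibrated)
generation_activity_floor: 0.05   # min activity used by the pruning estimator

mass_range: [1400.0, 4000.0]

reactor:
  tau: [7.5, 7.5, 7.5, 7.5]        # residence time per compartment, min
  volumes: [0.25, 0.25, 0.25, 0.25]
  c_tot: 5000.0                    # total N-glycan concentration, uM
  donors:                          # nucleotide-sugar concentrations, uM
    UDP-GlcNAc: 5000.0
    UDP-Gal: 2000.0
    CMP-NeuAc: 200.0
    GDP-Fuc: 100.0
    UDP-GalNAc: 1000.0

# Enzyme activity (min^-1), defined as kf_base * Et_total / c_tot.
enzymes:
  ManI: 3.41
  ManII: 2.93
  a6FucT: 2.07
  GnTI: 0.86
  GnTII: 3.86
  GnTIII: 0.01
  GnTIV: 0.64
  GnTV: 0.97
  iGnT: 0.01
  b4GalT: 8.97
  a3SiaT: 0.002
  IGnT: 1.18
  a6SiaT: 0.0
  b3GalT: 0.46
  FucTLe: 0.0
  a3FucT: 0.03
  FucTH: 0.02
  GalNAcT-A: 0.001
  GalT-B: 0.0

# Fraction of each enzyme's total residing in each compartment (sums to 1).
localization:
  ManI:      [0.70, 0.25, 0.05, 0.00]
  ManII:     [0.10, 0.60, 0.25, 0.05]
  GnTI:      [0.10, 0.60, 0.25, 0.05]
  GnTII:     [0.05, 0.50, 0.40, 0.05]
  GnTIII:    [0.00, 0.40, 0.50, 0.10]
  GnTIV:     [0.00, 0.40, 0.50, 0.10]
  GnTV:      [0.00, 0.40, 0.50, 0.10]
  a6FucT:    [0.00, 0.30, 0.50, 0.20]
  iGnT:      [0.00, 0.20, 0.50, 0.30]
  IGnT:      [0.00, 0.20, 0.50, 0.30]
  b4GalT:    [0.00, 0.10, 0.50, 0.40]
  b3GalT:    [0.00, 0.10, 0.50, 0.40]
  a3SiaT:    [0.00, 0.00, 0.40, 0.60]
  a6SiaT:    [0.00, 0.00, 0.40, 0.60]
  FucTLe:    [0.00, 0.10, 0.40, 0.50]
  a3FucT:    [0.00, 0.10, 0.40, 0.50]
  FucTH:     [0.00, 0.10, 0.40, 0.50]
  GalNAcT-A: [0.00, 0.00, 0.40, 0.60]
  GalT-B:    [0.00, 0.00, 0.40, 0.60]
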