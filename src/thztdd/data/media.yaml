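# Default dielectric model library for the THz-TDD simulator.
#
# These are simulator parameter choices (literature-informed Debye models and
# volume fractions), NOT values measured by or reported in any experiment this
# package analyses.  Frequencies in THz, relaxation times in ps.
#
#   water   : double-Debye fit of liquid water at room temperature
#             (Kindt & Schmuttenmaer, J. Phys. Chem. 1996 parameterization).
#   glycerol: main relaxation near 1 ns plus a fast secondary process; on the
#             0.1-2 THz band the main process is fully relaxed, leaving a low,
#             weakly lossy permittivity -- the mechanism behind the lower |M|
#             of glycerol-based solutions relative to hydrated skin.
#   ethanol : Debye model standing in for the 10% aspirin/ethanol additive of
#             the drug solution (folded into one polar component).
#   biological_background: frequency-flat real permittivity representing the
#             dry protein/lipid matrix of skin.
#   glycerol_water_50wv: 50% w/v glycerol in water; 50 g glycerol
#             (rho = 1.26 g/ml) per 100 ml is ~0.40 glycerol by volume.
#   drug_solution: 90% of the 50% w/v glycerol/water solvent + 10%
#             ethanol-like additive, i.e. 0.54 water / 0.36 glycerol / 0.10
#             ethanol by volume.
mixing_rule: lll
media:
  air:
    constant: {eps: 1.0}
  water:
    debye:
      eps_static: 78.36
      eps_intermediate: 4.93
      eps_inf: 3.48
      tau1_ps: 8.24
      tau2_ps: 0.18
  glycerol:
    debye:
      eps_static: 42.5
      eps_intermediate: 6.0
      eps_inf: 3.3
      tau1_ps: 900.0
      tau2_ps: 2.0
  ethanol:
    debye:
      eps_static: 24.35
      eps_intermediate: 4.2
      eps_inf: 2.5
      tau1_ps: 161.0
      tau2_ps: 3.3
  biological_background:
    constant: {eps: 3.0}
  glycerol_water_50wv:
    mixture:
      components: {water: 0.60, glycerol: 0.40}
  drug_solution:
    mixture:
      components: {water: 0.54, glycerol: 0.36, ethanol: 0.10}
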