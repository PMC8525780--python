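# Temperature-response and Rubisco kinetic constants used to express FvCB
# parameters at the 25 degC reference temperature.
#
# Each entry under `responses` parameterises a (possibly peaked) Arrhenius
# function:
#   Ha  activation energy            [J mol-1]
#   Hd  deactivation energy          [J mol-1]  (omit for pure Arrhenius)
#   dS  entropy term                 [J mol-1 K-1]  (omit with Hd)
#
# Vcmax/Jmax use community-standard peaked parameters (Kattge & Knorr 2007
# means), Tp the Harley et al. (1992) peaked form, Rdark and the Rubisco
# kinetics pure Arrhenius with Bernacchi et al. (2001) activation energies.
# Kinetic constants are mole fractions (not partial pressures).
#
# This file is configuration: edit or replace it to run the pipeline under a
# different temperature parameterisation.

reference_temperature_C: 25.0
gas_constant: 8.314          # J mol-1 K-1

responses:
  Vcmax:
    Ha: 71513.0
    Hd: 200000.0
    dS: 649.12
  Jmax:
    Ha: 49884.0
    Hd: 200000.0
    dS: 646.22
  Tp:
    Ha: 65330.0
    Hd: 149250.0
    dS: 485.0
  Rdark:
    Ha: 46390.0
  Kc:
    Ha: 79430.0
  Ko:
    Ha: 36380.0
  GammaStar:
    Ha: 37830.0

kinetics:
  Kc25: 404.9          # umol mol-1
  Ko25: 278.4          # mmol mol-1
  GammaStar25: 42.75   # umol mol-1
  O: 210.0             # mmol mol-1 (oxygen mole fraction)
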