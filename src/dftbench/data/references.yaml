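# Default reference values for the scored caffeic acid properties.
#
# Thermochemical references come either from gas-phase experiment (the
# experimental O-H bond dissociation enthalpy is the average of two
# literature determinations, 78.7 and 81.2 kcal/mol; the experimental proton
# affinity is 323.3 +/- 2.2 kcal/mol) or from the high-level
# B2PLYP-D3BJ/aug-cc-pVTZ protocol used as the theoretical yardstick where
# no experiment exists.
#
# The three geometry entries (hydroxyl bond lengths and the intramolecular
# hydrogen bond) are SYNTHETIC placeholders at chemically realistic values:
# geometry references are accepted as pre-computed (value, reference) pairs
# and the true reference geometries are not distributed with this package.
properties:
  r_oh_c3:
    value: 0.966
    units: angstrom
    provenance: high_level_theory
    synthetic: true
  r_oh_c4:
    value: 0.963
    units: angstrom
    provenance: high_level_theory
    synthetic: true
  r_hbond:
    value: 2.12
    units: angstrom
    provenance: high_level_theory
    synthetic: true
  bde_c3:
    value: 92.6
    units: kcal/mol
    provenance: high_level_theory
  bde_c4:
    value: 80.0
    units: kcal/mol
    provenance: experimental
    sources: [78.7, 81.2]
  aea:
    value: -12.8
    units: kcal/mol
    provenance: high_level_theory
  aip:
    value: 184.1
    units: kcal/mol
    provenance: high_level_theory
  pa_c3:
    value: 340.3
    units: kcal/mol
    provenance: high_level_theory
  pa_c4:
    value: 323.3
    units: kcal/mol
    provenance: experimental
    uncertainty: 2.2
  vip:
    value: 7.16
    units: eV
    provenance: high_level_theory
  vea:
    value: 0.67
    units: eV
    provenance: high_level_theory
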