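# Catalog of the benchmarked exchange-correlation functionals and basis sets.
#
# Functionals carry the fraction of exact Hartree-Fock exchange at short (SR),
# middle (MR) and long (LR) interelectronic range, in percent.  Global hybrids
# (GH) and the pure GGA apply one constant fraction at every range; range-
# separated hybrids (RSH) vary it.  Basis sets carry the number of basis
# functions (nbf) they assign to the caffeic acid benchmark molecule, the
# valence splitting level (zeta: double or triple) and whether diffuse
# functions are present.
functionals:
  - name: BLYP
    rung: GGA
    meta: false
    hf_sr: 0.0
    hf_mr: 0.0
    hf_lr: 0.0
  - name: TPSSh
    rung: GH
    meta: true
    hf_sr: 10.0
    hf_mr: 10.0
    hf_lr: 10.0
  - name: B3LYP
    rung: GH
    meta: false
    hf_sr: 20.0
    hf_mr: 20.0
    hf_lr: 20.0
  - name: PW6B95
    rung: GH
    meta: true
    hf_sr: 28.0
    hf_mr: 28.0
    hf_lr: 28.0
  - name: MPWB1K
    rung: GH
    meta: true
    hf_sr: 44.0
    hf_mr: 44.0
    hf_lr: 44.0
  - name: M06-2X
    rung: GH
    meta: true
    hf_sr: 54.0
    hf_mr: 54.0
    hf_lr: 54.0
  - name: WB97
    rung: RSH
    meta: false
    hf_sr: 0.0
    hf_mr: 0.0
    hf_lr: 100.0
  - name: WB97X
    rung: RSH
    meta: false
    hf_sr: 15.77
    hf_mr: 0.0
    hf_lr: 100.0
  - name: CAM-B3LYP
    rung: RSH
    meta: false
    hf_sr: 19.0
    hf_mr: 0.0
    hf_lr: 65.0
  - name: M11
    rung: RSH
    meta: true
    hf_sr: 42.8
    hf_mr: 0.0
    hf_lr: 100.0
  - name: HISSbPBE
    rung: RSH
    meta: false
    hf_sr: 0.0
    hf_mr: 60.0
    hf_lr: 0.0
basis_sets:
  - name: 6-31G(d,p)
    family: Pople
    nbf: 235
    zeta: double
    diffuse: false
  - name: 6-31+G(d,p)
    family: Pople
    nbf: 287
    zeta: double
    diffuse: true
  - name: 6-31++G(d,p)
    family: Pople
    nbf: 295
    zeta: double
    diffuse: true
  - name: 6-311G(d,p)
    family: Pople
    nbf: 282
    zeta: triple
    diffuse: false
  - name: 6-311+G(d,p)
    family: Pople
    nbf: 334
    zeta: triple
    diffuse: true
  - name: 6-311++G(d,p)
    family: Pople
    nbf: 342
    zeta: triple
    diffuse: true
  - name: cc-pVDZ
    family: Dunning
    nbf: 222
    zeta: double
    diffuse: false
  - name: aug-cc-pVDZ
    family: Dunning
    nbf: 371
    zeta: double
    diffuse: true
  - name: cc-pVTZ
    family: Dunning
    nbf: 502
    zeta: triple
    diffuse: false
  - name: aug-cc-pVTZ
    family: Dunning
    nbf: 782
    zeta: triple
    diffuse: true
  - name: def2-SVP
    family: Ahlrich
    nbf: 222
    zeta: double
    diffuse: false
  - name: def2-SVPD
    family: Ahlrich
    nbf: 336
    zeta: double
    diffuse: true
  - name: def2-TZVP
    family: Ahlrich
    nbf: 451
    zeta: triple
    diffuse: false
  - name: def2-TZVPD
    family: Ahlrich
    nbf: 565
    zeta: triple
    diffuse: true
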