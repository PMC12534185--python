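# Gradient seed: square Z1 growth segment plus a trapezoid-cross-section Z3
# growth segment whose tilted face a adds 10.9 deg on top of the 2.8 deg
# spacer twist (total 13.7 deg at face a, 2.8 deg at face b).  The spacer
# base-pair length producing the 2.8 deg twist is stored nominally; only the
# twist itself propagates downstream.
name: seed-SG
cross_section:
  array_type: square
  rim_cols: 8
  rim_rows: 8
  pore_cols: 4
  pore_rows: 4
  taper:
    delta_theta_deg: 10.9
    tilted_face: a
rise_nm_per_bp: 0.34
sublattice: square
segments:
  - {id: Z1, role: growth, bp: 128}
  - {id: Z2, role: spacer_twister, bp: 32, twist_deg: 2.8}
  - {id: Z3, role: growth, bp: 128}
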