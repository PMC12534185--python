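# Honeycomb-array seed templating honeycomb SST sublattices.
# 54 helices: 12x6 rim with a central 6x3 pore.  Growth segments are
# 126 bp (42.8 nm); spacers are 36 bp (12.2 nm) with a 1.2 deg twist.
name: seed-H
cross_section:
  array_type: honeycomb
  rim_cols: 12
  rim_rows: 6
  pore_cols: 6
  pore_rows: 3
rise_nm_per_bp: 0.34
sublattice: honeycomb
segments:
  - {id: Z1, role: growth, bp: 126}
  - {id: Z2, role: spacer_twister, bp: 36, twist_deg: 1.2}
  - {id: Z3, role: growth, bp: 126}
  - {id: Z4, role: spacer_twister, bp: 36, twist_deg: 1.2}
  - {id: Z5, role: growth, bp: 126}
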