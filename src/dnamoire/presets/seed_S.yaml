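# Square-array seed templating up to three square SST sublattices.
# 48 helices: 8x8 rim with a central 4x4 pore.  Growth segments Z1/Z3/Z5
# are 128 bp (43.5 nm); spacer/twister segments Z2/Z4 are 32 bp (10.9 nm)
# and imprint a right-handed 3.8 deg twist each.
name: seed-S
cross_section:
  array_type: square
  rim_cols: 8
  rim_rows: 8
  pore_cols: 4
  pore_rows: 4
rise_nm_per_bp: 0.34
sublattice: square
segments:
  - {id: Z1, role: growth, bp: 128}
  - {id: Z2, role: spacer_twister, bp: 32, twist_deg: 3.8}
  - {id: Z3, role: growth, bp: 128}
  - {id: Z4, role: spacer_twister, bp: 32, twist_deg: 3.8}
  - {id: Z5, role: growth, bp: 128}
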