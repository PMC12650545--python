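# Reference pKa ladders at 25 degC (concentration basis, literature values).
# max_charge is the charge of the fully deprotonated form. Editable data,
# not code: add or adjust ladders freely.
hepes:
  pkas: [7.5]
  max_charge: -1
l_cysteine:
  # carboxyl, thiol, ammonium
  pkas: [1.71, 8.33, 10.78]
  max_charge: -2
edta:
  # the two strongest acidities are folded into the salt form as supplied
  pkas: [2.0, 2.66, 6.16, 10.24]
  max_charge: -4
carbonic_acid:
  pkas: [6.35, 10.33]
  max_charge: -2
phosphate:
  pkas: [2.15, 7.20, 12.38]
  max_charge: -3
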