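# A HEPES-buffered stand-in (synthetic) for a CO2-independent neural medium:
# 10 mM HEPES brought near physiological pH with NaOH. The real commercial
# medium's buffer composition is proprietary, so this recipe reproduces the
# acidification-and-restoration workflow qualitatively, not its exact numbers.
volume_ml: 1.0
species:
  - name: hepes
    total_M: 0.010
    pkas: [7.5]
    max_charge: -1
strong_cations_M: 0.00443   # Na+ from NaOH, sets the starting pH near 7.4
strong_anions_M: 0.0
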