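# name	density_g_cm3	inelastic_mfp_A	elastic_mfp_A	reference_voltage_kV
# inelastic_mfp: carbon measured at 300 kV; ice literature value at 300 kV;
# protein calibrated so the 30:70 protein:water mixture reproduces the
# zero-loss fraction 0.44 at 2000 A (see docs/methods.md).
# elastic_mfp: uncalibrated defaults from the ~26/Z cross-section ratio rule;
# supply measured values for quantitative elastic bookkeeping.
carbon	1.7	2400	10400	300
ice	0.93	3140	11000	300
protein	1.35	1600	6200	300
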