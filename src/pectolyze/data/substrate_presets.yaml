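# Substrate presets for the digestion simulator.  DM/DAc are percent of GalA
# residues carrying methyl ester / acetyl groups, measured values for the
# commercial pectins used in pectin-lyase characterization work; pga is
# polygalacturonic acid (fully de-esterified).
apple:
  dm: 69.0
  dac: 2.0
  methyl_pattern: random
citrus:
  dm: 53.0
  dac: 1.0
  methyl_pattern: random
sugarbeet:
  dm: 56.0
  dac: 19.0
  methyl_pattern: random
pga:
  dm: 0.0
  dac: 0.0
  methyl_pattern: random
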