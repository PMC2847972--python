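# dated-tree configuration for the bundled Solanaceae fixture
node_ages:
  ATPt: 7.3
  ATE: 15.5
  ATP: 19.6
  ATN: 23.7
calibration_note: root calibration 86 MY (metadata only)
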