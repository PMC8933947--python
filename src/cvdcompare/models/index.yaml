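# Stable ordering of the shipped risk-model configs.
models:
  - pce.yaml
  - apce.yaml
  - framingham_lipids.yaml
  - framingham_bmi.yaml
  - who_lipids.yaml
  - who_bmi.yaml
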