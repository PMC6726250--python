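# Sustained oscillations: constant IP3 target P_s = 0.3 µM for 900 s.
condition:
  name: control
protocol:
  segments:
    - [0.0, 900.0, 0.3]
solver:
  output_dt: 0.05
analysis:
  window: [300.0, 900.0]
output:
  directory: oscillation_output
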