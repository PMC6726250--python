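# Rising IP3 staircase (oscillation-cessation scan) for the obesity
# condition: P_s steps 0 -> 0.3 -> 0.6 -> 0.9 -> 1.2 µM.
condition:
  name: obesity
protocol:
  segments:
    - [0.0, 500.0, 0.0]
    - [500.0, 1500.0, 0.3]
    - [1500.0, 2500.0, 0.6]
    - [2500.0, 3500.0, 0.9]
    - [3500.0, 4500.0, 1.2]
solver:
  output_dt: 0.1
output:
  directory: staircase_output
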