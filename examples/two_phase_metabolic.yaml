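# Two-phase stimulation used to inspect the mitochondrial variables:
# a small pulse (M = 5 µM/s, 0.2 s at t = 100 s) followed by a constant
# P_s = 0.3 µM plateau on (600, 1400) s.
condition:
  name: control
protocol:
  segments:
    - [0.0, 600.0, 0.0]
    - [600.0, 1400.0, 0.3]
    - [1400.0, 2000.0, 0.0]
  pulses:
    - [5.0, 100.0, 0.2]
solver:
  output_dt: 0.1
output:
  directory: two_phase_output
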