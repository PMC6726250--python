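# Single IP3 pulse from rest (the linker-comparison protocol): M = 10 µM/s
# for 0.2 s starting at t = 60 s, i.e. ~2 µM of IP3 delivered.
condition:
  name: control
protocol:
  segments:
    - [0.0, 200.0, 0.0]
  pulses:
    - [10.0, 60.0, 0.2]
solver:
  output_dt: 0.01
output:
  directory: pulse_output
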