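# Canonical routine-swimming scenario: the statolith presses SRC1, the
# hunting interneuron is inactive, and a posture change moves the pressed
# receptor to SRC6 mid-run.
network:
  builder: full
protocol:
  mode: routine
  pressed_src: SRC1
  I_statolith: 3.0
  switch_events: [[30000.0, SRC6]]
  duration: 60000.0
  seed: 0
engine:
  tol: 1.0e-6
  dt_out: 0.5
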