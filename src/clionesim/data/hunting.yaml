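# Canonical hunting scenario: the cerebral hunting interneuron H is driven
# and excites all six receptors; winnerless competition ensues.
network:
  builder: full
protocol:
  mode: hunting
  I_hunting: 3.0
  duration: 120000.0
  seed: 0
engine:
  tol: 1.0e-6
  dt_out: 0.5
analysis:
  transient_ms: 20000.0
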