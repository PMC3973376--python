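# Canonical declining-regime simulation setup: stem pool shrinking
# (a1 * theta1 = 0.385 < 1/2) with faster net progenitor depletion.
# Times are abstract model time units.
kind: counts
params:
  a1: 0.55
  theta1: 0.7
  p1: 1.0
  kappa: 0.6
  a2: 0.7
  theta2: 0.4
  p2: 2.5
  d2: 0.1
  p3: 1.5
  d3: 0.4
  d4: 0.05
  d5: 0.05
init:
  c1: 10000
  c2: 5000
  c3: 15000
  c4: 350000
  c5: 100000
grid:
  start: 0.0
  stop: 30.0
  num: 3001
delta: 0.1
seed: 0
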