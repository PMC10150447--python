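# Direct-effect estimation error: node randomization vs independent-set design
# on forest-fire graphs, under contagion interference, at desk scale.
dataset:
  synthetic: {model: ff, n: 1000, p_f: 0.3, p_b: 0.3, d: 10}
designs:
  - {method: randomized}
  - {method: causeis}
simulation: {mode: contagion, p_treat: 0.4, p_control: 0.2}
ep: [0.1, 0.5, edge-weight]
S: 10
base_seed: 0
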