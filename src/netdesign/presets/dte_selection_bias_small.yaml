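# Selection bias (covariate distance between arms) of the direct-effect
# designs, interference off; matching variants shine at small n.
dataset:
  synthetic: {model: ff, n: 300, p_f: 0.3, p_b: 0.3, d: 10}
designs:
  - {method: randomized}
  - {method: match}
  - {method: causeis}
  - {method: causeis_match}
simulation: {mode: none, p_treat: 0.4, p_control: 0.2}
ep: [null]
S: 10
base_seed: 0
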