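# Total-effect estimation error under one-pass direct interference.
dataset:
  synthetic: {model: ba, n: 400, m: 3, d: 10}
designs:
  - {method: randomized}
  - {method: cbr, k: 8}
  - {method: cmatch, cluster_algo: reldg, k: 8,
     node_rule: tnm2, weight: c, cluster_rule: tcm2}
simulation: {mode: direct, p_treat: 0.4, p_control: 0.2}
ep: [edge-weight]
S: 10
base_seed: 0
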