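# Potential spillover: cross-arm edge and edge-weight fractions per design.
dataset:
  synthetic: {model: ba, n: 400, m: 3, d: 10}
designs:
  - {method: randomized}
  - {method: cbr, k: 8}
  - {method: cmatch, cluster_algo: mcl,
     node_rule: tnm2, weight: c, cluster_rule: tcm2}
simulation: {mode: none, p_treat: 0.4, p_control: 0.2}
ep: [edge-weight]
S: 10
base_seed: 0
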