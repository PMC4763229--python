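# 1:1 HeLa/MCF-7 mixture on the dual sensor that compounds the opposing
# miR-24-3p (1.3-fold) and miR-203a (1.5-fold) activity differences.
seed: 1
profiles:
  - name: HeLa
    knockdown: {miR-24-3p: 0.50, miR-203a: 0.90}
  - name: MCF-7
    knockdown: {miR-24-3p: 0.65, miR-203a: 0.60}
sensors:
  denominator: FL1
  channels:
    - {name: FL1, target: miR-24-3p}
    - {name: FL2, target: miR-203a}
simulation:
  n_events: 10000
  background: 5.0
  untransfected_fraction: 0.1
  spillover: [[1.0, 0.08], [0.04, 1.0]]
gates:
  - label: HeLa
    bounds: [[0.05, 1.2]]
  - label: MCF-7
    bounds: [[-1.2, 0.05]]
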