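# Three-channel imaging scene of a three-type mixture, with Fig-style
# pseudo-colour display windows and rectangular cell-type gates.
seed: 2
profiles:
  - name: HeLa
    knockdown: {miR-17-5p: 0.40, miR-127-3p: 0.85, miR-203a: 0.90}
  - name: 293FT
    knockdown: {miR-17-5p: 0.70, miR-127-3p: 0.45, miR-203a: 0.55}
  - name: MCF-7
    knockdown: {miR-17-5p: 0.55, miR-127-3p: 0.70, miR-203a: 0.60}
sensors:
  denominator: CH1
  channels:
    - {name: CH1, target: miR-17-5p}
    - {name: CH2, target: miR-127-3p}
    - {name: CH3, target: miR-203a}
simulation:
  background: 3.0
imaging:
  shape: [300, 300]
  n_nuclei: 24
  radius_range: [6, 10]
  pseudo_color:
    CH2/CH1: [-0.25, 0.75]
    CH3/CH1: [-0.5, 0.5]
gates:
  - label: HeLa
    bounds: [[0.15, 1.0], [0.2, 1.0]]
  - label: 293FT
    bounds: [[-1.0, 0.0], [-1.0, 0.05]]
  - label: MCF-7
    bounds: [[0.0, 0.15], [-0.2, 0.2]]
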