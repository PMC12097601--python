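# Default grid protocol: 25 players, 15 rounds, 5 repetitions,
# k x b/c in {2,4,6} x {2,4,6}, ring and well-mixed structures,
# homogeneous conditional-cooperator population.
grid:
  k_values: [2, 4, 6]
  ratio_values: [2, 4, 6]
designs:
  - {n_players: 25, rounds: 15, repetitions: 5}
topology_modes: [ring, well_mixed]
agents:
  kind: conditional
  params: {alpha: -1.0, beta: 3.0, gamma: 0.5, p0: 1.0}
seed: 0
output_dir: results/grid
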