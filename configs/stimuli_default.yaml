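# Controlled-stimulus protocol: 25 rounds, change after 5 all-C rounds,
# conditions A/B/C (3/2/1 cooperators post-change), 10 runs, strongly
# conditional focal agent.
focal:
  kind: conditional
  params: {alpha: -4.0, beta: 8.0, gamma: 0.0, p0: 1.0}
conditions: [A, B, C]
runs: 10
rounds: 25
change_round: 5
benefit_cost_ratio: 6.0
seed: 0
output_dir: results/stimuli
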