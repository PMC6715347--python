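# Pairwise-invasibility heatmap: two opposite asymmetric mutants introduced
# at p = 0.01 into a symmetric resident, over a grid of mutation sizes.
experiment: grid
seed: 1
out: results/invasion_grid
kinetics: {k_on: 10.0, k_off: 1.0, gamma: 0.1, n_cost: 1}
evolution: {N: 1000, max_generations: 5000}
spec:
  dx_grid: [0.0, 0.25, 0.5, 0.75, 1.0]
  dy_grid: [0.0, 0.25, 0.5, 0.75, 1.0]
  p: 0.01
  replicates: 5
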