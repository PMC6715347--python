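# Deterministic invasion-fitness landscape around the symmetric producer
# (1,1,0,0); every mutant deviation (dx, dy) is disfavored in this regime.
experiment: landscape
out: results/landscape
kinetics: {k_on: 1.0, k_off: 1.0, gamma: 0.5, k_between: 1.0, n_cost: 1}
spec: {resident: [1.0, 1.0, 0.0, 0.0], grid_resolution: 21}
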