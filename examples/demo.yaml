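# Full demo pipeline on the default synthetic survey.
seed: 7
n_points: 252
noise_cv: 0.05
pmf_factors: 4
pmf_n_starts: 20
rf_targets: [Cd, Pb, Hg, As]
rf_trees: 500
mc_iterations: 10000
mc_mode: 1d
outdir: demo_run
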