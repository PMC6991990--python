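# Standard normal target, Gaussian random-walk proposal (variance 4) and
# homogeneous log-normal weights with sigma2 = 5: published construction.
# n_steps, seeds and the N grid are implementation defaults.
example: lognormal_normal
overrides:
  sigma2: 5.0
  proposal_variance: 4.0
N_grid: [10, 100, 1000]
n_steps: 100000
seeds: [1]
out_dir: out/lognormal_normal
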