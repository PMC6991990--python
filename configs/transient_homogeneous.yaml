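# Published transient construction: theta = 0.75, eps = 2 - sqrt(3),
# b = 2 eps theta / (1 - theta), N = 1.  Run sizes are implementation
# defaults.
example: transient_homogeneous
overrides:
  x0: 1
N_grid: [1]
n_steps: 10000
seeds: [1, 2, 3]
out_dir: out/transient_homogeneous
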