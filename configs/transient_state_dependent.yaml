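# Published state-dependent transient construction: theta = 0.5,
# eps_m = m^{-(3 - (m mod 3))}, b = 3 + ((1-theta)/theta)^3, N = 1.
# Set overrides.theta: 0.25 for the downward-biased variant.  Run sizes
# are implementation defaults.
example: transient_state_dependent
overrides:
  theta: 0.5
  x0: 1
N_grid: [1]
n_steps: 10000
seeds: [1, 2, 3]
out_dir: out/transient_state_dependent
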