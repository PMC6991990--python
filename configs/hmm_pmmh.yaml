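# Linear-Gaussian HMM particle-MCMC study.  The model family and samplers
# follow the published example; T, the true parameters, the prior box and
# the proposal scale are unprinted there and are implementation defaults.
example: hmm_pmmh
overrides:
  T: 50
  a: 0.9
  sigma_X2: 1.0
  sigma_Y2: 1.0
  n_particles: 250
  proposal_scale: 0.05
N_grid: [250]
n_steps: 5000
seeds: [1]
out_dir: out/hmm_pmmh
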