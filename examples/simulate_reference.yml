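# In-silico kymograph at the in-vivo reference parameter set, 2-um lattice.
# Run: kip2 simulate --config examples/simulate_reference.yml --out out/sim
params:
  k_on: 6.1e-4      # (nM s)^-1, lattice landing
  k_in: 0.31        # (nM s)^-1, minus-end entry
  k_off: 0.023      # s^-1, lattice detachment
  kip2_total: 35.0  # nM
length_nm: 2000.0
n_frames: 80
frame_interval_s: 1.07
t_burn_s: 600.0
seed: 12
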