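# Likelihood estimation with default ranges (reduced draws for a quick look;
# the full protocol uses n_samples: 20000).
# Run: kip2 fit --config examples/fit_default.yml --input out/profiles --out out/fit
seed: 3
n_samples: 2000
n_walkers: 16
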