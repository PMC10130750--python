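# Synthetic line-scan cohort from the reference set (defaults for the rest).
# Run: kip2 generate --config examples/generate_profiles.yml --out out/profiles
kind: profiles
n_cells: 100
seed: 7
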