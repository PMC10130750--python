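# kip2traffic

Kinesin traffic on astral microtubules in budding yeast: stochastic and
mean-field models of the Kip2 motor on a microtubule lattice, likelihood
estimation of the motor's rate constants from fluorescence line-scan
profiles, and quantification of microtubule dynamic instability from 3-D
end-coordinate tracks. Everything runs on ground-truthed synthetic data, so
each stage of the pipeline is testable end to end without any download.

The package is for quantitative cell biologists and modelers who work on
+TIP/motor traffic: it provides the in-vivo analysis chain — from line-scan
CSVs or plus-end/SPB coordinate tables to rate-constant posteriors and
dynamic-instability statistics — as a tested library with a thin CLI.

## The model

A microtubule is a 1-D lattice of 8-nm sites (site 1 at the SPB-anchored
minus-end). Kip2 motors exclude each other and follow five rate constants:
entry at the minus-end with rate r_in = k_in·[Kip2]_free (site 1 empty),
landing on any empty lattice site with r_on = k_on·[Kip2]_free, stepping
toward the plus-end with k_step when the next site is free, detachment from
the lattice with k_off, and detachment from the plus-end with a different
rate k_out. A finite cytoplasmic pool closes the model: [Kip2]_free =
[Kip2]_total − n_bound·n_MT/(0.602·V), so [Kip2]_free < [Kip2]_total
whenever motors are bound.

The same process is implemented as an exact Gillespie simulation, an exact
2ⁿ-state master-equation solution (the small-lattice oracle), and a
mean-field steady state with a self-consistent pool (the inference forward
model). Defaults follow the published in-vivo reference set: k_on =
6.1×10⁻⁴ (nM·s)⁻¹, k_in = 0.31 (nM·s)⁻¹, k_off = 2.3×10⁻² s⁻¹,
[Kip2]_total = 35 nM, k_step = 13.125 s⁻¹ (6.3 µm/min ÷ 8 nm), and k_out =
3.3 s⁻¹ (plus-end residence < 0.3 s; the in-vitro scale 1/30 s⁻¹ is provided
for the traffic-jam contrast).

Estimation samples the likelihood of length-binned, SPB-aligned mean GFP
profiles with an affine-invariant ensemble MCMC (20,000 retained draws by
default) over log-uniform ranges, with the fluorescence scale, background
and plus-end spot treated as nuisances; see `docs/methods.md` for the full
statistical model and the design decisions.

## Worked example

Simulate the in-silico kymograph contrast between the in-vivo and in-vitro
plus-end out-rates on a 2-µm microtubule:

```bash
python analysis/01_simulate_traffic.py
```

prints (exactly, at the script's fixed seed):

```
in_vivo: k_out=3.300/s  tip=0.269  interior=0.204  ratio=1.32
in_vitro: k_out=0.033/s  tip=0.977  interior=0.172  ratio=5.69

With the in-vitro-scale out-rate the last 10% of sites carry 5.7x the
interior occupancy (a plus-end traffic jam); at the in-vivo scale the
ratio is 1.3x (no jam).
```

With the ~30-s in-vitro residence the last 10% of lattice sites are nearly
saturated (time-averaged occupancy 0.98 vs 0.17 in the interior): motors
queue at the plus-end. At the in-vivo out-rate the tip clears as fast as
motors arrive and no jam forms — the qualitative argument for why Kip2 must
leave plus-ends much faster in cells than in vitro.

Quantify dynamic instability on 200 synthetic 3-D tracks:

```bash
python analysis/04_quantify_dynamics.py
```

```
200 tracks quantified (of 200 generated)
max length: 2.69 +- 0.71 um; detectable fraction 1.00
lifetime: 72.9 +- 21.3 s (window 85.6 s)
growth speed 1.46 um/min (programmed 1.5); shrinkage 2.92 um/min (programmed 3.0)
pooled catastrophe frequency 0.45/min of growth (programmed 0.6/min; 131 programmed events)
```

Growth and shrinkage speeds come back within a few percent of the
programmed values; the pooled catastrophe frequency is biased low by the
events that fall below the detector's stated resolution (short flanking
phases, censored lengths), as with manual annotation of real movies.

The estimation itself (`analysis/02_generate_profiles.py` then
`analysis/03_fit_profiles.py`) generates 500 synthetic cells from the
reference set, bins them by measured peak-to-peak length, and recovers the
generating rate constants and total concentration as marginal posterior
medians with identifiability diagnostics (a few minutes on one CPU).

## Command line

A thin umbrella CLI wraps the library:

```bash
kip2 simulate --config sim.yml --out out/        # kymograph + occupancy CSVs
kip2 generate --config gen.yml --out data/       # synthetic profiles/tracks
kip2 fit      --config fit.yml --input data/ --out fit/   # posterior samples
kip2 quantify --input tracks/ --out dyn/         # dynamics TSV + cohort JSON
```

Configs are YAML (ready-to-run examples under `examples/`); every output
directory receives a `provenance.json` (config hash, seed, version)
sufficient to re-run the command, and is never overwritten without
`--force`.

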