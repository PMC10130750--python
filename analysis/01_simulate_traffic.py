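#!/usr/bin/env python
"""Stochastic traffic on a 2-um astral microtubule: in-vivo vs in-vitro tip release.

Runs the exact stochastic simulation at the in-vivo reference parameter set
twice -- with the plus-end out-rate at its in-vivo scale (residence < 0.3 s)
and at the in-vitro scale (residence ~30 s) -- and writes the in-silico
kymographs and time-averaged occupancy profiles.  The contrast is the
headline qualitative prediction: with the in-vitro out-rate, motors queue at
the plus-end (tip occupancy several-fold above the lattice interior), while
the in-vivo out-rate clears the tip.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from kip2traffic.lattice_model import (
    K_OUT_IN_VITRO,
    K_OUT_IN_VIVO,
    build_lattice,
    gillespie_simulate,
    reference_parameters,
    simulate_kymograph,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "traffic"
OUT.mkdir(parents=True, exist_ok=True)
SCRATCH = ROOT / "scratch" / "traffic"
SCRATCH.mkdir(parents=True, exist_ok=True)
SEED = 12

lattice = build_lattice(2000.0)
summary = {}
for label, k_out in [("in_vivo", K_OUT_IN_VIVO), ("in_vitro", K_OUT_IN_VITRO)]:
    params = reference_parameters(k_out=k_out)
    kymo = simulate_kymograph(
        params, lattice, n_frames=80, frame_interval=1.07, seed=SEED, t_burn=600.0
    )
    pd.DataFrame(kymo).to_csv(SCRATCH / f"kymograph_{label}.csv", index=False)
    res = gillespie_simulate(
        params, lattice, t_end=1600.0, record_interval=20.0, seed=SEED, t_burn=600.0
    )
    occ = res.time_avg_occupancy
    pd.DataFrame({"site": np.arange(1, occ.size + 1), "occupancy": occ}).to_csv(
        OUT / f"occupancy_{label}.csv", index=False
    )
    n_tip = occ.size // 10
    ratio = float(occ[-n_tip:].mean() / occ[:-n_tip].mean())
    summary[label] = dict(
        k_out_per_s=k_out,
        tip_occupancy=float(occ[-n_tip:].mean()),
        interior_occupancy=float(occ[:-n_tip].mean()),
        tip_to_interior_ratio=ratio,
    )
    print(
        f"{label}: k_out={k_out:.3f}/s  tip={summary[label]['tip_occupancy']:.3f}  "
        f"interior={summary[label]['interior_occupancy']:.3f}  ratio={ratio:.2f}"
    )

(OUT / "jam_contrast.json").write_text(json.dumps(summary, indent=1))
print(
    "\nWith the in-vitro-scale out-rate the last 10% of sites carry "
    f"{summary['in_vitro']['tip_to_interior_ratio']:.1f}x the interior occupancy "
    "(a plus-end traffic jam); at the in-vivo scale the ratio is "
    f"{summary['in_vivo']['tip_to_interior_ratio']:.1f}x (no jam)."
)
print(f"outputs in {OUT}")
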