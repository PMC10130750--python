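"""Ground-truthed synthetic inputs for both analysis pipelines.

Two generators emulate the statistical structure of the in-vivo data:

* :func:`generate_profiles` draws microtubule lengths, runs the mean-field
  traffic model forward into expected line scans, and adds the measurement
  structure of spinning-disk line scans: a lognormal cell-to-cell intensity
  scale (expression variability), additive per-pixel Gaussian noise, a
  constant background, and an mCherry SPB reference peak.
* :func:`generate_tracks` runs a two-state dynamic-instability telegraph
  process (growth/shrinkage with exponential switching, reflecting at zero
  length), embeds it in 3D with a pivoting microtubule axis and a fixed SPB
  pair, and adds per-axis Gaussian localization noise -- the structure of
  3D plus-end/SPB coordinate tracks (80 frames at 1.07 s by default).

Both return exact ground truth (a "sidecar" dict, written as JSON next to
the CSVs) and are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice_model import (
    ConvergenceError,
    ModelParameters,
    build_lattice,
    mean_field_steady_state,
    reference_parameters,
)
from .profile_model import (
    DEFAULT_PSF_SIGMA_NM,
    PIXEL_NM,
    LineScanProfile,
    occupancy_to_profile,
)

__all__ = [
    "ProfileGeneratorConfig",
    "TrackGeneratorConfig",
    "generate_profiles",
    "generate_tracks",
    "SIDECAR_SCHEMA_VERSION",
]

SIDECAR_SCHEMA_VERSION = 1


@dataclass
class ProfileGeneratorConfig:
    """Ground truth and noise model for synthetic line-scan profiles.

    Lengths are uniform over ``length_range_um`` (default 0.8-2.4 um, the
    span of the experimental length bins).  The emitted GFP intensity is
    ``s_cell * scale_au_per_motor * (motors per pixel) + background + noise``
    with ``s_cell`` lognormal with mean 1 and coefficient of variation
    ``scale_cv``.
    """

    params: ModelParameters = field(default_factory=reference_parameters)
    n_cells: int = 500
    length_range_um: tuple[float, float] = (0.8, 2.4)
    scale_au_per_motor: float = 1.0
    scale_cv: float = 0.2
    background_au: float = 2.0
    # per-pixel camera/shot noise; small relative to the shaft signal so that
    # single-cell plus-end peak detection works, as it does in the real data
    # where plus-end peaks are conspicuous -- cell-to-cell expression scatter
    # (scale_cv) dominates the per-bin uncertainty
    noise_sd_au: float = 0.1
    mcherry_amplitude_au: float = 50.0
    mcherry_sigma_nm: float = 200.0
    mcherry_background_au: float = 1.0
    # plus-end-retained fluorescence beyond the single-lane lattice tip: a
    # real microtubule has ~13 protofilament tips (plus Bik1-held motors),
    # which is what makes the plus-end peak conspicuous in the images and
    # the peak-to-peak length measurable per cell.  Expressed in motor
    # equivalents placed at the terminal site; scales with the cell's
    # expression level.  The likelihood never uses the tip region.
    tip_marker_motors: float = 12.0
    psf_sigma_nm: float = DEFAULT_PSF_SIGMA_NM
    pixel_nm: float = PIXEL_NM
    margin_px: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("scale_cv", "noise_sd_au", "mcherry_sigma_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.length_range_um
        if not (0 < lo <= hi):
            raise ValueError("length_range_um must satisfy 0 < lo <= hi")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size=None):
    """Lognormal draws with mean exactly 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def generate_profiles(
    config: ProfileGeneratorConfig, out_dir: str | Path | None = None
) -> tuple[list[LineScanProfile], dict]:
    """Synthesize per-cell line scans from the mean-field traffic model.

    Each cell: draw a length, solve the finite-pool mean-field steady state,
    map occupancy to expected intensity per pixel, place the lattice in a
    scan window with the SPB at a random pixel offset, add the mCherry SPB
    peak and per-pixel noise.  Returns the profiles plus a ground-truth
    sidecar; if ``out_dir`` is given, writes one CSV per cell and
    ``ground_truth.json``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.params
    lo_nm, hi_nm = 1e3 * config.length_range_um[0], 1e3 * config.length_range_um[1]
    px = config.pixel_nm

    profiles: list[LineScanProfile] = []
    cells = []
    for i in range(config.n_cells):
        occ = None
        for attempt in range(5):
            length_nm = float(rng.uniform(lo_nm, hi_nm))
            try:
                occ = mean_field_steady_state(p, build_lattice(length_nm))
                break
            except ConvergenceError:  # pragma: no cover - defensive
                warnings.warn(
                    f"forward model failed at length {length_nm:.0f} nm; resampling",
                    RuntimeWarning,
                )
        if occ is None:  # pragma: no cover
            raise ConvergenceError("forward model failed for 5 resampled lengths")

        s_cell = float(_lognormal_unit_mean(rng, config.scale_cv))
        dens = occ.mean_occupancy.copy()
        dens[-1] += config.tip_marker_motors
        signal = occupancy_to_profile(
            dens,
            scale=s_cell * config.scale_au_per_motor,
            background=0.0,
            psf_sigma_nm=config.psf_sigma_nm,
            pixel_size_nm=px,
        )
        # scan window: SPB at pixel index `offset`, margin pixels past the tip;
        # PSF tails falling before the window start are clipped (negligible)
        offset = int(rng.integers(3, 8))
        n_sig = signal.positions_nm.size
        k0 = int(np.round(signal.positions_nm[0] / px))  # first signal pixel
        n_total = offset + k0 + n_sig + config.margin_px
        positions = (np.arange(n_total) - offset) * px
        gfp = np.full(n_total, config.background_au)
        j0 = offset + k0
        i0 = max(0, -j0)
        gfp[j0 + i0 : j0 + n_sig] += signal.gfp[i0:]
        mch = config.mcherry_background_au + config.mcherry_amplitude_au * np.exp(
            -0.5 * (positions / config.mcherry_sigma_nm) ** 2
        )
        if config.noise_sd_au > 0:
            gfp = gfp + rng.normal(0.0, config.noise_sd_au, n_total)
            mch = mch + rng.normal(0.0, config.noise_sd_au, n_total)
        cell_id = f"cell{i:04d}"
        profiles.append(
            LineScanProfile(positions_nm=positions, gfp=gfp, mcherry=mch, cell_id=cell_id)
        )
        cells.append(
            dict(
                cell_id=cell_id,
                length_nm=length_nm,
                scale=s_cell * config.scale_au_per_motor,
                spb_offset_px=offset,
                c_free_nm=occ.c_free,
                total_bound=occ.total_bound,
            )
        )

    sidecar = dict(
        schema_version=SIDECAR_SCHEMA_VERSION,
        kind="profiles",
        seed=config.seed,
        params=asdict(p),
        scale_au_per_motor=config.scale_au_per_motor,
        scale_cv=config.scale_cv,
        background_au=config.background_au,
        noise_sd_au=config.noise_sd_au,
        tip_marker_motors=config.tip_marker_motors,
        psf_sigma_nm=config.psf_sigma_nm,
        length_range_um=list(config.length_range_um),
        pixel_nm=px,
        cells=cells,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for prof in profiles:
            pd.DataFrame(
                {
                    "position_nm": prof.positions_nm,
                    "gfp_au": prof.gfp,
                    "mcherry_au": prof.mcherry,
                }
            ).to_csv(out / f"{prof.cell_id}.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return profiles, sidecar


# --------------------------------------------------------------------------
# Dynamic-instability track generator
# --------------------------------------------------------------------------


@dataclass
class TrackGeneratorConfig:
    """Two-state dynamic-instability ground truth for 3D end-point tracks.

    Speeds in um/min, switching rates in events/min (catastrophe acts during
    growth, rescue during shrinkage), localization noise as an isotropic
    per-axis Gaussian sigma in nm applied to all three tracked points.
    """

    growth_speed_um_min: float = 1.5
    shrink_speed_um_min: float = 3.0
    catastrophe_rate_per_min: float = 0.6
    rescue_rate_per_min: float = 0.6
    noise_sigma_nm: float = 25.0
    frame_interval_s: float = 1.07
    n_frames: int = 80
    n_tracks: int = 100
    initial_length_um: float = 1.2
    initial_state: str = "growth"
    spindle_length_um: float = 1.5
    pivot_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        for name in (
            "growth_speed_um_min",
            "shrink_speed_um_min",
            "catastrophe_rate_per_min",
            "rescue_rate_per_min",
            "noise_sigma_nm",
            "initial_length_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.initial_state not in ("growth", "shrinkage"):
            raise ValueError("initial_state must be 'growth' or 'shrinkage'")


@dataclass
class SyntheticTrack:
    """One generated track: coordinates plus exact ground truth."""

    track_id: str
    times_s: np.ndarray
    plus_end_nm: np.ndarray  # (n_frames, 3)
    spb_proximal_nm: np.ndarray
    spb_distal_nm: np.ndarray
    true_lengths_um: np.ndarray
    switch_times_s: list[float]
    switch_kinds: list[str]  # "catastrophe" | "rescue"
    states: list[str]


def _telegraph_lengths(cfg: TrackGeneratorConfig, rng: np.random.Generator):
    """Exact piecewise-linear length trajectory sampled at frame times.

    Growth and shrinkage phases alternate with exponential waiting times;
    length reflects at 0 (a fully depolymerized microtubule stays at zero
    until a rescue re-nucleates growth).  Switches are only possible in the
    state they act on, so with rate 0 the current phase lasts forever.
    """
    v_g = cfg.growth_speed_um_min / 60.0  # um/s
    v_s = cfg.shrink_speed_um_min / 60.0
    f_c = cfg.catastrophe_rate_per_min / 60.0  # /s
    f_r = cfg.rescue_rate_per_min / 60.0
    T = (cfg.n_frames - 1) * cfg.frame_interval_s

    t = 0.0
    length = cfg.initial_length_um
    state = cfg.initial_state
    seg_t = [0.0]
    seg_len = [length]
    seg_state = []
    switches, kinds = [], []
    while t < T:
        rate = f_c if state == "growth" else f_r
        wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_next = min(t + wait, T)
        v = v_g if state == "growth" else -v_s
        length = max(0.0, length + v * (t_next - t))
        seg_state.append(state)
        seg_t.append(t_next)
        seg_len.append(length)
        if t_next < T:
            switches.append(t_next)
            kinds.append("catastrophe" if state == "growth" else "rescue")
            state = "shrinkage" if state == "growth" else "growth"
        t = t_next

    times = np.arange(cfg.n_frames) * cfg.frame_interval_s
    lengths = np.empty(cfg.n_frames)
    for i, tf in enumerate(times):
        j = int(np.searchsorted(seg_t, tf, side="right") - 1)
        j = min(j, len(seg_state) - 1)
        v = v_g if seg_state[j] == "growth" else -v_s
        lengths[i] = max(0.0, seg_len[j] + v * (tf - seg_t[j]))
    return lengths, switches, kinds, seg_state


def generate_tracks(
    config: TrackGeneratorConfig, out_dir: str | Path | None = None
) -> tuple[list[SyntheticTrack], dict]:
    """Synthesize 3D end-coordinate tracks with exact ground truth.

    The SPB pair is fixed in space; the microtubule axis starts in a random
    direction and pivots by a small random rotation each frame, so the 3D
    end-to-end distance equals the programmed length exactly before noise.
    """
    rng = np.random.default_rng(config.seed)
    tracks: list[SyntheticTrack] = []
    truth_tracks = []
    times = np.arange(config.n_frames) * config.frame_interval_s
    for k in range(config.n_tracks):
        lengths, switches, kinds, states = _telegraph_lengths(config, rng)
        spb_p = np.array([3000.0, 3000.0, 2000.0])
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        spb_d = spb_p + 1e3 * config.spindle_length_um * axis
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        plus = np.empty((config.n_frames, 3))
        for i in range(config.n_frames):
            plus[i] = spb_p + 1e3 * lengths[i] * u
            u = u + config.pivot_sigma * rng.normal(size=3)
            u /= np.linalg.norm(u)
        spbp = np.tile(spb_p, (config.n_frames, 1))
        spbd = np.tile(spb_d, (config.n_frames, 1))
        if config.noise_sigma_nm > 0:
            plus = plus + rng.normal(0, config.noise_sigma_nm, plus.shape)
            spbp = spbp + rng.normal(0, config.noise_sigma_nm, spbp.shape)
            spbd = spbd + rng.normal(0, config.noise_sigma_nm, spbd.shape)
        tid = f"track{k:04d}"
        tracks.append(
            SyntheticTrack(
                track_id=tid,
                times_s=times.copy(),
                plus_end_nm=plus,
                spb_proximal_nm=spbp,
                spb_distal_nm=spbd,
                true_lengths_um=lengths,
                switch_times_s=switches,
                switch_kinds=kinds,
                states=states,
            )
        )
        truth_tracks.append(
            dict(
                track_id=tid,
                true_lengths_um=lengths.tolist(),
                switch_times_s=switches,
                switch_kinds=kinds,
                true_max_length_um=float(lengths.max()),
            )
        )

    sidecar = dict(
        schema_version=SIDECAR_SCHEMA_VERSION,
        kind="tracks",
        seed=config.seed,
        growth_speed_um_min=config.growth_speed_um_min,
        shrink_speed_um_min=config.shrink_speed_um_min,
        catastrophe_rate_per_min=config.catastrophe_rate_per_min,
        rescue_rate_per_min=config.rescue_rate_per_min,
        noise_sigma_nm=config.noise_sigma_nm,
        frame_interval_s=config.frame_interval_s,
        n_frames=config.n_frames,
        tracks=truth_tracks,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for tr in tracks:
            df = pd.DataFrame(
                {
                    "frame": np.arange(config.n_frames),
                    "time_s": tr.times_s,
                    "plus_x_nm": tr.plus_end_nm[:, 0],
                    "plus_y_nm": tr.plus_end_nm[:, 1],
                    "plus_z_nm": tr.plus_end_nm[:, 2],
                    "spbp_x_nm": tr.spb_proximal_nm[:, 0],
                    "spbp_y_nm": tr.spb_proximal_nm[:, 1],
                    "spbp_z_nm": tr.spb_proximal_nm[:, 2],
                    "spbd_x_nm": tr.spb_distal_nm[:, 0],
                    "spbd_y_nm": tr.spb_distal_nm[:, 1],
                    "spbd_z_nm": tr.spb_distal_nm[:, 2],
                }
            )
            df.to_csv(out / f"{tr.track_id}.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return tracks, sidecar
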