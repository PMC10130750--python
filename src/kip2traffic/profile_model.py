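"""Fluorescence line-scan profiles: alignment, length binning, forward map.

Line scans along astral microtubules carry two channels: GFP (the motor,
Kip2-3xsfGFP) and mCherry (the SPB marker Spc42-mCherry, which marks the
microtubule minus-end).  Profiles are aligned so that the mCherry peak sits
at position 0, the GFP peak defines the plus-end, and the peak-to-peak
distance defines the profile length.  Aligned profiles are binned by length
(266.7-nm bins, i.e. two 133.35-nm pixels) and averaged per bin; a weighted
linear regression of the per-bin plus-end intensity against bin length
summarizes how plus-end accumulation scales with microtubule length.

:func:`occupancy_to_profile` is the forward map from a model occupancy
profile to an expected line scan (motors per pixel times a scale, optional
Gaussian PSF, plus background); it connects the lattice model to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lattice_model import SITE_SIZE_NM, OccupancyProfile, njit

__all__ = [
    "PIXEL_NM",
    "BIN_WIDTH_NM",
    "AlignmentError",
    "InsufficientDataError",
    "LineScanProfile",
    "ProfileBin",
    "ProfileDataset",
    "PlusEndRegression",
    "align_to_reference_peak",
    "bin_by_length",
    "occupancy_to_profile",
    "plus_end_regression",
    "read_line_scan_csv",
    "write_line_scan_csv",
]

#: camera pixel projected to the sample, nm (2 pixels = one 266.7-nm bin)
PIXEL_NM = 133.35
#: length-bin width, nm
BIN_WIDTH_NM = 266.7
#: default microscope point-spread sigma, nm (FWHM ~350 nm, spinning disk);
#: washes out site-per-pixel aliasing and makes the plus-end peak visible
DEFAULT_PSF_SIGMA_NM = 150.0


class AlignmentError(ValueError):
    """The mCherry reference channel has no usable peak."""


class InsufficientDataError(ValueError):
    """Not enough usable bins/positions for the requested operation."""


@dataclass
class LineScanProfile:
    """One cell's line scan: uniformly spaced positions and two channels.

    ``positions_nm`` are measured from the minus-end reference once aligned;
    ``profile_length_nm`` (GFP-peak minus mCherry-peak distance) is set by
    :func:`align_to_reference_peak`.
    """

    positions_nm: np.ndarray
    gfp: np.ndarray
    mcherry: np.ndarray
    cell_id: str = ""
    profile_length_nm: float | None = None

    def __post_init__(self):
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        n = self.positions_nm.size
        if self.gfp.size != n or self.mcherry.size != n:
            raise ValueError("positions, gfp and mcherry must have equal length")
        if n >= 2:
            d = np.diff(self.positions_nm)
            if np.any(d <= 0):
                raise ValueError("positions must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-6):
                raise ValueError("positions must be uniformly spaced")
        if not (np.all(np.isfinite(self.gfp)) and np.all(np.isfinite(self.mcherry))):
            raise ValueError("intensities must be finite")

    @property
    def pixel_nm(self) -> float:
        if self.positions_nm.size < 2:
            return PIXEL_NM
        return float(self.positions_nm[1] - self.positions_nm[0])

    @property
    def is_aligned(self) -> bool:
        return self.profile_length_nm is not None


def _subpixel_peak(values: np.ndarray, i: int, baseline_px: int = 0) -> float:
    """Sub-pixel peak offset (in pixels) by quadratic interpolation at index i.

    With ``baseline_px`` > 0, a local linear baseline through the flanking
    pixels at +-baseline_px is subtracted first (standard spot-localization
    practice: it removes the pull that a sloping background exerts on the
    interpolated peak position).
    """
    if i <= 0 or i >= values.size - 1:
        return 0.0
    seg = values[i - 1 : i + 2].astype(float)
    if baseline_px > 1 and i - baseline_px >= 0 and i + baseline_px < values.size:
        vl = values[i - baseline_px]
        vr = values[i + baseline_px]
        frac = (np.arange(i - 1, i + 2) - (i - baseline_px)) / (2 * baseline_px)
        seg = seg - (vl + (vr - vl) * frac)
    denom = seg[0] - 2 * seg[1] + seg[2]
    if denom >= 0:  # not a local maximum of the parabola
        return 0.0
    delta = 0.5 * (seg[0] - seg[2]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def align_to_reference_peak(profile: LineScanProfile) -> LineScanProfile:
    """Shift positions so the mCherry (SPB) peak sits at 0.

    Positions are shifted by a whole number of pixels (the aligned profiles
    of different cells must share the pixel grid for per-position averaging),
    using the mCherry maximum with ties broken toward the scan start.  The
    GFP peak marks the plus-end, and the peak-to-peak distance is stored as
    ``profile_length_nm`` with sub-pixel refinement of both peak positions
    (quadratic interpolation, as in standard spot-localization practice).
    A flat mCherry channel has no reference peak and raises
    :class:`AlignmentError`.  Idempotent.
    """
    mch = profile.mcherry
    if np.ptp(mch) == 0:
        raise AlignmentError(
            f"cell {profile.cell_id!r}: flat mCherry channel, no reference peak"
        )
    px = profile.pixel_nm
    i_ref = int(np.argmax(mch))
    shift = profile.positions_nm[i_ref]
    positions = profile.positions_nm - shift
    i_gfp = int(np.argmax(profile.gfp))
    gfp_peak = (i_gfp + _subpixel_peak(profile.gfp, i_gfp, baseline_px=4)) * px + positions[0]
    ref_peak = _subpixel_peak(mch, i_ref) * px
    return LineScanProfile(
        positions_nm=positions,
        gfp=profile.gfp.copy(),
        mcherry=mch.copy(),
        cell_id=profile.cell_id,
        profile_length_nm=float(gfp_peak - ref_peak),
    )


@dataclass
class ProfileBin:
    """Mean profile of all cells whose length falls in [lo_nm, hi_nm).

    ``member_gfp`` holds the per-cell intensities at the positions common to
    every member (``common_positions_nm``), preserving the between-cell
    covariance structure (a cell's expression level shifts its whole profile
    coherently) that the estimation likelihood exploits.
    """

    lo_nm: float
    hi_nm: float
    n: int
    positions_nm: np.ndarray
    mean_gfp: np.ndarray
    sem_gfp: np.ndarray  # standard error of the mean, 0 where n_per_position < 2
    ci95_gfp: np.ndarray  # 1.96 * sem
    n_per_position: np.ndarray
    member_lengths_nm: np.ndarray
    common_positions_nm: np.ndarray | None = None
    member_gfp: np.ndarray | None = None  # (n members, n common positions)

    @property
    def center_nm(self) -> float:
        return 0.5 * (self.lo_nm + self.hi_nm)

    @property
    def mean_length_nm(self) -> float:
        return float(np.mean(self.member_lengths_nm))


@dataclass
class ProfileDataset:
    """Length-binned, minus-end-aligned mean fluorescence profiles."""

    bins: list[ProfileBin]
    bin_width_nm: float = BIN_WIDTH_NM
    pixel_nm: float = PIXEL_NM
    label: str = ""

    @property
    def n_profiles(self) -> int:
        return sum(b.n for b in self.bins)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.bins:
            for j, pos in enumerate(b.positions_nm):
                rows.append(
                    dict(
                        bin_lo_nm=b.lo_nm,
                        bin_hi_nm=b.hi_nm,
                        position_nm=pos,
                        mean_gfp=b.mean_gfp[j],
                        sem_gfp=b.sem_gfp[j],
                        ci95_gfp=b.ci95_gfp[j],
                        n=int(b.n_per_position[j]),
                    )
                )
        return pd.DataFrame(rows)


def bin_by_length(
    profiles: list[LineScanProfile], bin_width_nm: float = BIN_WIDTH_NM
) -> ProfileDataset:
    """Group aligned profiles into length bins and average them per position.

    Bin edges sit at integer multiples of ``bin_width_nm`` (so a 1.2-um
    profile lands in [1.0668, 1.3335) um).  Aligned positions across cells
    share the pixel grid, so averaging is done per grid index; the 95% CI of
    the mean is 1.96 * SEM (0 where only one profile contributes).  Bins
    without members are omitted.
    """
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be > 0")
    if not profiles:
        return ProfileDataset(bins=[], bin_width_nm=bin_width_nm)
    for p in profiles:
        if not p.is_aligned:
            raise ValueError("all profiles must be aligned (profile_length_nm set)")
    px = profiles[0].pixel_nm
    groups: dict[int, list[LineScanProfile]] = {}
    for p in profiles:
        k = int(np.floor(p.profile_length_nm / bin_width_nm))
        groups.setdefault(k, []).append(p)

    bins = []
    for k in sorted(groups):
        members = groups[k]
        # positions snap onto the shared pixel grid (aligned shifts are
        # integer pixels); key per-position statistics by grid index
        acc: dict[int, list[float]] = {}
        member_maps = []
        for p in members:
            idx = np.round(p.positions_nm / px).astype(int)
            member_maps.append(dict(zip(idx.tolist(), p.gfp.tolist())))
            for i, v in zip(idx, p.gfp):
                acc.setdefault(int(i), []).append(float(v))
        keys = np.array(sorted(acc))
        mean = np.empty(keys.size)
        sem = np.zeros(keys.size)
        npos = np.empty(keys.size, dtype=int)
        for j, i in enumerate(keys):
            vals = np.asarray(acc[int(i)])
            mean[j] = vals.mean()
            npos[j] = vals.size
            if vals.size >= 2:
                sem[j] = vals.std(ddof=1) / np.sqrt(vals.size)
        common = sorted(set.intersection(*(set(m) for m in member_maps)))
        member_gfp = np.array([[m[i] for i in common] for m in member_maps])
        bins.append(
            ProfileBin(
                lo_nm=k * bin_width_nm,
                hi_nm=(k + 1) * bin_width_nm,
                n=len(members),
                positions_nm=keys * px,
                mean_gfp=mean,
                sem_gfp=sem,
                ci95_gfp=1.96 * sem,
                n_per_position=npos,
                member_lengths_nm=np.array([p.profile_length_nm for p in members]),
                common_positions_nm=np.array(common, dtype=float) * px,
                member_gfp=member_gfp,
            )
        )
    return ProfileDataset(bins=bins, bin_width_nm=bin_width_nm, pixel_nm=px)


def occupancy_to_profile(
    profile: OccupancyProfile | np.ndarray,
    scale: float,
    background: float,
    psf_sigma_nm: float = 0.0,
    pixel_size_nm: float = PIXEL_NM,
    site_size_nm: float = SITE_SIZE_NM,
) -> LineScanProfile:
    """Forward map: expected motor density -> expected line-scan intensity.

    Site i occupies [i, i+1) * site_size from the minus-end and carries
    ``scale`` a.u. per expected motor; densities are optionally blurred with
    a Gaussian PSF (sigma in nm) at site resolution, then integrated into
    133.35-nm pixels (pixel k covers k*pixel +- pixel/2) by exact fractional
    overlap -- partial sites are split between neighbouring pixels, so a
    smooth density yields a smooth profile with no site-per-pixel aliasing.
    The pixel grid extends to capture PSF tails past the lattice ends, and
    ``background`` is added everywhere.  Total mass is preserved and the map
    is linear in the occupancy for fixed scale and background.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    if psf_sigma_nm < 0:
        raise ValueError("psf_sigma_nm must be >= 0")
    rho = (
        profile.mean_occupancy
        if isinstance(profile, OccupancyProfile)
        else np.asarray(profile, dtype=float)
    )
    k_min, counts = _occupancy_to_pixels(rho, psf_sigma_nm, pixel_size_nm, site_size_nm)
    return LineScanProfile(
        positions_nm=np.arange(k_min, k_min + counts.size) * pixel_size_nm,
        gfp=scale * counts + background,
        mcherry=np.zeros_like(counts),
        cell_id="forward-model",
    )


@njit(cache=True)
def _pixels_core(rho, psf_sigma_nm, pixel_size_nm, site_size_nm):  # pragma: no cover
    n = rho.shape[0]
    if psf_sigma_nm > 0:
        # pad so the blurred mass stays on the grid, then convolve exactly
        pad = int(np.ceil(6.0 * psf_sigma_nm / site_size_nm))
        nk = 2 * pad + 1
        kern = np.empty(nk)
        ksum = 0.0
        for i in range(nk):
            x = (i - pad) * site_size_nm
            kern[i] = np.exp(-0.5 * (x / psf_sigma_nm) ** 2)
            ksum += kern[i]
        m = n + 2 * pad
        dens = np.zeros(m)
        for i in range(n):
            r = rho[i]
            if r != 0.0:
                for j in range(nk):
                    dens[i + j] += r * kern[j]
        for i in range(m):
            dens[i] /= ksum
        x_lo = -pad * site_size_nm
    else:
        dens = rho.astype(np.float64)
        m = n
        x_lo = 0.0
    # cumulative mass at site edges; linear interpolation = exact integral of
    # the piecewise-constant density
    cum = np.empty(m + 1)
    cum[0] = 0.0
    for i in range(m):
        cum[i + 1] = cum[i] + dens[i]
    e0 = x_lo
    e_last = x_lo + m * site_size_nm
    k_min = int(np.floor(e0 / pixel_size_nm + 0.5))
    k_max = int(np.floor(e_last / pixel_size_nm + 0.5))
    npx = k_max - k_min + 1
    counts = np.empty(npx)
    prev = 0.0
    for k in range(npx):
        edge = (k_min + k + 0.5) * pixel_size_nm  # right edge of pixel
        u = (edge - e0) / site_size_nm
        if u <= 0.0:
            val = 0.0
        elif u >= m:
            val = cum[m]
        else:
            j = int(u)
            val = cum[j] + (u - j) * dens[j]
        counts[k] = val - prev
        prev = val
    return k_min, counts


def _occupancy_to_pixels(
    rho: np.ndarray, psf_sigma_nm: float, pixel_size_nm: float, site_size_nm: float
) -> tuple[int, np.ndarray]:
    """Fast core of the forward map: (first pixel index, motors per pixel)."""
    k_min, counts = _pixels_core(
        np.ascontiguousarray(rho, dtype=np.float64),
        float(psf_sigma_nm),
        float(pixel_size_nm),
        float(site_size_nm),
    )
    return int(k_min), counts


@dataclass
class PlusEndRegression:
    """Weighted least squares of per-bin plus-end intensity vs bin length."""

    slope_au_per_um: float
    intercept_au: float
    slope_se: float
    intercept_se: float
    lengths_um: np.ndarray = field(repr=False)
    values_au: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)


def plus_end_regression(dataset: ProfileDataset) -> PlusEndRegression:
    """Weighted linear regression of plus-end GFP intensity over length bins.

    The per-bin plus-end value is the bin's mean profile at its GFP-peak
    position (positions >= 0 only), weighted by the inverse variance of that
    mean.  Bins where the variance is zero receive the largest finite weight
    present (or equal weights if none).  Requires at least two bins.
    """
    xs, ys, variances = [], [], []
    for b in dataset.bins:
        mask = b.positions_nm >= 0
        if not np.any(mask):
            continue
        sub_mean = b.mean_gfp[mask]
        j = int(np.argmax(sub_mean))
        xs.append(b.center_nm / 1000.0)
        ys.append(float(sub_mean[j]))
        variances.append(float(b.sem_gfp[mask][j] ** 2))
    if len(xs) < 2:
        raise InsufficientDataError(
            f"plus-end regression needs >= 2 usable bins, got {len(xs)}"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    var = np.asarray(variances)
    w = np.empty_like(var)
    pos = var > 0
    if np.any(pos):
        w[pos] = 1.0 / var[pos]
        w[~pos] = w[pos].max()
    else:
        w[:] = 1.0
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return PlusEndRegression(
        slope_au_per_um=float(res.params[1]),
        intercept_au=float(res.params[0]),
        slope_se=float(res.bse[1]) if np.isfinite(res.bse[1]) else 0.0,
        intercept_se=float(res.bse[0]) if np.isfinite(res.bse[0]) else 0.0,
        lengths_um=x,
        values_au=y,
        weights=w,
    )


# --------------------------------------------------------------------------
# CSV I/O (Fiji line-scan export dialect)
# --------------------------------------------------------------------------

REQUIRED_COLUMNS = ("position_nm", "gfp_au", "mcherry_au")


def read_line_scan_csv(path: str | Path, cell_id: str | None = None) -> LineScanProfile:
    """Read one cell's line scan (columns position_nm, gfp_au, mcherry_au)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    return LineScanProfile(
        positions_nm=df["position_nm"].to_numpy(),
        gfp=df["gfp_au"].to_numpy(),
        mcherry=df["mcherry_au"].to_numpy(),
        cell_id=cell_id if cell_id is not None else path.stem,
    )


def write_line_scan_csv(profile: LineScanProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "position_nm": profile.positions_nm,
            "gfp_au": profile.gfp,
            "mcherry_au": profile.mcherry,
        }
    ).to_csv(path, index=False)
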