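"""Stochastic and deterministic models of kinesin traffic on a microtubule lattice.

The model describes the budding-yeast kinesin Kip2 moving along an astral
microtubule, discretized as a 1-D lattice of 8-nm sites (one tubulin dimer,
one motor step) with hard-core exclusion.  Five rate constants govern the
dynamics:

* ``k_in``  -- entry at the SPB-anchored minus-end (site 1), per nM free
  motor and second, active only when site 1 is empty;
* ``k_on``  -- landing on any empty lattice site, per nM free motor/s;
* ``k_off`` -- detachment from any non-terminal occupied site, /s;
* ``k_step``-- hop toward the plus-end when the next site is empty, /s;
* ``k_out`` -- detachment from the plus-end (terminal) site, /s.  It
  *replaces* k_off at the terminal site.

The cytoplasmic pool is finite: ``kip2_total`` (nM) is shared by
``n_microtubules`` identical lattices inside an effective volume
``volume_fl``, and the free concentration is depleted by bound motors
(conservation of matter).  The same process is implemented three ways:

* :func:`gillespie_simulate` -- exact stochastic simulation (direct method);
* :func:`master_equation_stationary` -- exact stationary distribution of the
  2^n-state Markov chain (small lattices, fixed free concentration);
* :func:`mean_field_steady_state` -- site-wise mean-field fixed point with a
  self-consistent free pool (the forward model used for inference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "AVOGADRO",
    "MOLECULES_PER_NM_FL",
    "SITE_SIZE_NM",
    "K_STEP_DEFAULT",
    "K_OUT_IN_VIVO",
    "K_OUT_IN_VITRO",
    "ModelParameters",
    "Lattice",
    "OccupancyProfile",
    "GillespieResult",
    "ConvergenceError",
    "reference_parameters",
    "build_lattice",
    "free_concentration",
    "gillespie_simulate",
    "simulate_kymograph",
    "master_equation_stationary",
    "mean_field_steady_state",
]

AVOGADRO = 6.02214076e23
#: molecules corresponding to 1 nM in 1 fL (= 1e-9 mol/L * 1e-15 L * N_A)
MOLECULES_PER_NM_FL = 1e-9 * 1e-15 * AVOGADRO  # ~0.602

SITE_SIZE_NM = 8.0

#: stepping rate derived from the measured speckle speed of 6.3 um/min
K_STEP_DEFAULT = 6.3e3 / 60.0 / SITE_SIZE_NM  # 13.125 /s

#: plus-end detachment at the in-vivo scale (residence < 0.3 s)
K_OUT_IN_VIVO = 3.3
#: plus-end detachment at the in-vitro scale (residence ~30 s)
K_OUT_IN_VITRO = 1.0 / 30.0


class ConvergenceError(RuntimeError):
    """Raised when the mean-field solver fails to reach the residual tolerance."""

    def __init__(self, message: str, residual: float = np.nan):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, motor pool and geometry of the traffic model.

    Rates in (nM s)^-1 (k_in, k_on) or s^-1 (k_off, k_step, k_out);
    ``kip2_total`` in nM, ``volume_fl`` in femtoliters.  ``n_microtubules``
    lattices share the pool and are assumed statistically identical, so the
    free concentration seen by one lattice with ``n_bound`` motors is
    ``kip2_total - n_bound * n_microtubules / (MOLECULES_PER_NM_FL * volume_fl)``.
    """

    k_in: float
    k_on: float
    k_off: float
    k_step: float = K_STEP_DEFAULT
    k_out: float = K_OUT_IN_VIVO
    kip2_total: float = 35.0
    volume_fl: float = 40.0
    n_microtubules: int = 12

    def __post_init__(self):
        for name in ("k_in", "k_on", "k_off", "k_step", "k_out", "kip2_total"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.volume_fl <= 0:
            raise ValueError(f"volume_fl must be > 0, got {self.volume_fl!r}")
        if self.n_microtubules < 1:
            raise ValueError("n_microtubules must be >= 1")

    @property
    def nm_per_bound_motor(self) -> float:
        """Free-pool depletion (nM) caused by one motor bound to one lattice."""
        return self.n_microtubules / (MOLECULES_PER_NM_FL * self.volume_fl)

    def with_(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


def reference_parameters(**overrides) -> ModelParameters:
    """The in-vivo wild-type reference parameter set.

    On-, in-, off-rate constants and total concentration follow the published
    in-silico set (k_on = 6.1e-4 (nM s)^-1, k_in = 0.31 (nM s)^-1,
    k_off = 2.3e-2 s^-1, 35 nM total); k_step comes from the measured motor
    speed and k_out from the in-vivo plus-end residence bound.
    """
    base = dict(
        k_in=3.1e-1,
        k_on=6.1e-4,
        k_off=2.3e-2,
        k_step=K_STEP_DEFAULT,
        k_out=K_OUT_IN_VIVO,
        kip2_total=35.0,
    )
    base.update(overrides)
    return ModelParameters(**base)


@dataclass
class Lattice:
    """Discretized microtubule: site 1 = minus-end (SPB), site n = plus-end."""

    n_sites: int
    site_size_nm: float = SITE_SIZE_NM
    occupancy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.occupancy is None:
            self.occupancy = np.zeros(self.n_sites, dtype=np.int8)
        else:
            self.occupancy = np.asarray(self.occupancy, dtype=np.int8)
            if self.occupancy.shape != (self.n_sites,):
                raise ValueError("occupancy shape mismatch")
            if np.any((self.occupancy != 0) & (self.occupancy != 1)):
                raise ValueError("occupancy must be 0/1 (exclusion)")

    @property
    def length_nm(self) -> float:
        return self.n_sites * self.site_size_nm

    def site_positions_nm(self) -> np.ndarray:
        """Site-center positions measured from the minus-end (SPB)."""
        return (np.arange(self.n_sites) + 0.5) * self.site_size_nm


@dataclass
class OccupancyProfile:
    """Per-site stationary occupancy with summary quantities."""

    mean_occupancy: np.ndarray
    total_bound: float
    flux_out: float
    c_free: float | None = None

    def __post_init__(self):
        self.mean_occupancy = np.asarray(self.mean_occupancy, dtype=float)
        if np.any(self.mean_occupancy < -1e-9) or np.any(self.mean_occupancy > 1 + 1e-9):
            raise ValueError("mean occupancy must lie in [0, 1]")

    @classmethod
    def from_occupancy(
        cls, rho: np.ndarray, k_out: float, c_free: float | None = None
    ) -> "OccupancyProfile":
        rho = np.clip(np.asarray(rho, dtype=float), 0.0, 1.0)
        return cls(
            mean_occupancy=rho,
            total_bound=float(rho.sum()),
            flux_out=float(k_out * rho[-1]),
            c_free=c_free,
        )


def build_lattice(length_nm: float, site_size_nm: float = SITE_SIZE_NM) -> Lattice:
    """Discretize a microtubule of given length into 8-nm exclusion sites.

    ``n_sites = floor(length_nm / site_size_nm)``, clipped to at least one
    site so that arbitrarily short microtubules remain representable.
    """
    if not np.isfinite(length_nm) or length_nm <= 0:
        raise ValueError(f"length_nm must be > 0, got {length_nm!r}")
    if not np.isfinite(site_size_nm) or site_size_nm <= 0:
        raise ValueError(f"site_size_nm must be > 0, got {site_size_nm!r}")
    return Lattice(n_sites=max(1, int(length_nm // site_size_nm)), site_size_nm=site_size_nm)


def free_concentration(params: ModelParameters, n_bound: float) -> float:
    """Free motor concentration (nM) given ``n_bound`` motors on one lattice.

    Conservation of matter: bound motors on the ``n_microtubules`` lattices
    (assumed identical) deplete the shared pool; the result is floored at 0.
    """
    if n_bound < 0:
        raise ValueError("n_bound must be >= 0")
    return max(0.0, params.kip2_total - n_bound * params.nm_per_bound_motor)


# --------------------------------------------------------------------------
# Gillespie (direct method)
# --------------------------------------------------------------------------

_EVENT_ENTER = 0
_EVENT_LAND = 1
_EVENT_HOP = 2
_EVENT_OFF = 3
_EVENT_OUT = 4

EVENT_NAMES = {0: "enter", 1: "land", 2: "hop", 3: "off", 4: "out"}


@njit(cache=True)
def _gillespie_core(
    occ,
    k_in,
    k_on,
    k_off,
    k_step,
    k_out,
    kip2_total,
    nm_per_motor,
    pool_finite,
    t_end,
    record_times,
    t_burn,
    seed,
    log_events,
    log_cap,
):  # pragma: no cover - exercised through gillespie_simulate
    np.random.seed(seed)
    n = occ.shape[0]
    n_rec = record_times.shape[0]
    frames = np.zeros((n_rec, n), dtype=np.int8)
    tavg = np.zeros(n, dtype=np.float64)
    ev_t = np.empty(log_cap if log_events else 1, dtype=np.float64)
    ev_code = np.empty(log_cap if log_events else 1, dtype=np.int8)
    ev_site = np.empty(log_cap if log_events else 1, dtype=np.int64)
    n_ev = 0
    log_overflow = False

    n_bound = 0
    for i in range(n):
        n_bound += occ[i]

    t = 0.0
    rec_ptr = 0
    tavg_span = t_end - t_burn

    while True:
        if pool_finite:
            c = kip2_total - n_bound * nm_per_motor
            if c < 0.0:
                c = 0.0
        else:
            c = kip2_total

        a_enter = k_in * c if occ[0] == 0 else 0.0
        n_empty = n - n_bound
        a_land = k_on * c * n_empty
        n_mov = 0
        for i in range(n - 1):
            if occ[i] == 1 and occ[i + 1] == 0:
                n_mov += 1
        a_hop = k_step * n_mov
        n_offable = n_bound - occ[n - 1]
        a_off = k_off * n_offable
        a_out = k_out * occ[n - 1]
        a_tot = a_enter + a_land + a_hop + a_off + a_out

        if a_tot <= 0.0:
            # frozen configuration: fill remaining records and averages
            while rec_ptr < n_rec:
                for i in range(n):
                    frames[rec_ptr, i] = occ[i]
                rec_ptr += 1
            lo = t if t > t_burn else t_burn
            if t_end > lo:
                w = t_end - lo
                for i in range(n):
                    tavg[i] += occ[i] * w
            t = t_end
            break

        dt = -np.log(np.random.random()) / a_tot
        t_new = t + dt

        # snapshots of the pre-event state at record times within (t, t_new]
        while rec_ptr < n_rec and record_times[rec_ptr] <= t_new:
            for i in range(n):
                frames[rec_ptr, i] = occ[i]
            rec_ptr += 1

        # time-average accumulation over [t_burn, t_end]
        lo = t if t > t_burn else t_burn
        hi = t_new if t_new < t_end else t_end
        if hi > lo:
            w = hi - lo
            for i in range(n):
                if occ[i] == 1:
                    tavg[i] += w

        if t_new >= t_end:
            t = t_end
            break
        t = t_new

        r = np.random.random() * a_tot
        code = -1
        site = -1
        if r < a_enter:
            code = _EVENT_ENTER
            site = 0
            occ[0] = 1
            n_bound += 1
        elif r < a_enter + a_land:
            k = int((r - a_enter) / (k_on * c)) if k_on * c > 0 else 0
            if k >= n_empty:
                k = n_empty - 1
            cnt = -1
            for i in range(n):
                if occ[i] == 0:
                    cnt += 1
                    if cnt == k:
                        site = i
                        break
            code = _EVENT_LAND
            occ[site] = 1
            n_bound += 1
        elif r < a_enter + a_land + a_hop:
            k = int((r - a_enter - a_land) / k_step)
            if k >= n_mov:
                k = n_mov - 1
            cnt = -1
            for i in range(n - 1):
                if occ[i] == 1 and occ[i + 1] == 0:
                    cnt += 1
                    if cnt == k:
                        site = i
                        break
            code = _EVENT_HOP
            occ[site] = 0
            occ[site + 1] = 1
        elif r < a_enter + a_land + a_hop + a_off:
            k = int((r - a_enter - a_land - a_hop) / k_off)
            if k >= n_offable:
                k = n_offable - 1
            cnt = -1
            for i in range(n - 1):
                if occ[i] == 1:
                    cnt += 1
                    if cnt == k:
                        site = i
                        break
            code = _EVENT_OFF
            occ[site] = 0
            n_bound -= 1
        else:
            code = _EVENT_OUT
            site = n - 1
            occ[n - 1] = 0
            n_bound -= 1

        if log_events:
            if n_ev < log_cap:
                ev_t[n_ev] = t
                ev_code[n_ev] = code
                ev_site[n_ev] = site
                n_ev += 1
            else:
                log_overflow = True

    if tavg_span > 0:
        for i in range(n):
            tavg[i] /= tavg_span
    return frames, tavg, ev_t[:n_ev], ev_code[:n_ev], ev_site[:n_ev], log_overflow


@dataclass
class GillespieResult:
    """Trajectory summary of one exact stochastic simulation."""

    times: np.ndarray  # snapshot times, s
    occupancy: np.ndarray  # (n_frames, n_sites) int8
    time_avg_occupancy: np.ndarray  # averaged over [t_burn, t_end]
    event_times: np.ndarray
    event_codes: np.ndarray
    event_sites: np.ndarray
    t_burn: float
    t_end: float
    seed: int

    def event_log(self):
        """Event log as a list of (time, name, site) tuples."""
        return [
            (float(t), EVENT_NAMES[int(c)], int(s))
            for t, c, s in zip(self.event_times, self.event_codes, self.event_sites)
        ]

    def tip_residence_times(self, n_sites: int) -> np.ndarray:
        """Occupied intervals of the terminal site, from arrival to departure.

        Only intervals that both start and end within the logged window are
        returned.  In the unobstructed limit their mean is 1/k_out.
        """
        tip = n_sites - 1
        arrivals = []
        out = []
        t_arr = None
        for t, c, s in zip(self.event_times, self.event_codes, self.event_sites):
            # hop events log their origin site, so a hop from tip-1 arrives
            # at the tip; landings/entries log the target site directly
            arrived = (c == _EVENT_HOP and s == tip - 1) or (
                c in (_EVENT_LAND, _EVENT_ENTER) and s == tip
            )
            if arrived:
                t_arr = t
            elif s == tip and c == _EVENT_OUT and t_arr is not None:
                arrivals.append(t_arr)
                out.append(t)
                t_arr = None
        return np.asarray(out) - np.asarray(arrivals)


def gillespie_simulate(
    params: ModelParameters,
    lattice: Lattice,
    t_end: float,
    record_interval: float,
    seed: int,
    *,
    t_burn: float = 0.0,
    pool: str = "finite",
    log_events: bool = False,
    log_cap: int = 2_000_000,
) -> GillespieResult:
    """Exact stochastic simulation (Gillespie direct method).

    Snapshots of the occupancy are stored every ``record_interval`` seconds
    (first snapshot at t = record_interval... see :func:`simulate_kymograph`
    for the frame convention); the time-averaged occupancy is accumulated
    over ``[t_burn, t_end]``.  ``pool`` is ``"finite"`` (free concentration
    updated on every binding/unbinding event) or ``"unlimited"`` (constant
    ``kip2_total``).  Reproducible for a fixed ``seed``.
    """
    if not np.isfinite(t_end) or t_end <= 0:
        raise ValueError("t_end must be > 0")
    if record_interval <= 0:
        raise ValueError("record_interval must be > 0")
    if pool not in ("finite", "unlimited"):
        raise ValueError("pool must be 'finite' or 'unlimited'")
    if not (0.0 <= t_burn < t_end):
        raise ValueError("need 0 <= t_burn < t_end")

    record_times = np.arange(record_interval, t_end + 1e-12, record_interval)
    occ0 = np.array(lattice.occupancy, dtype=np.int8, copy=True)
    frames, tavg, ev_t, ev_c, ev_s, overflow = _gillespie_core(
        occ0,
        float(params.k_in),
        float(params.k_on),
        float(params.k_off),
        float(params.k_step),
        float(params.k_out),
        float(params.kip2_total),
        float(params.nm_per_bound_motor),
        pool == "finite",
        float(t_end),
        record_times,
        float(t_burn),
        int(seed),
        bool(log_events),
        int(log_cap),
    )
    if overflow:
        warnings.warn("event log capacity exceeded; log truncated", RuntimeWarning)
    return GillespieResult(
        times=record_times,
        occupancy=frames,
        time_avg_occupancy=tavg,
        event_times=ev_t,
        event_codes=ev_c,
        event_sites=ev_s,
        t_burn=t_burn,
        t_end=t_end,
        seed=seed,
    )


def simulate_kymograph(
    params: ModelParameters,
    lattice: Lattice,
    n_frames: int,
    frame_interval: float,
    seed: int,
    *,
    t_burn: float = 0.0,
    pool: str = "finite",
) -> np.ndarray:
    """Occupancy snapshots from one stochastic run, shaped (n_frames, n_sites).

    Frame k is taken at ``t_burn + k * frame_interval`` for k = 0..n_frames-1,
    so 80 frames at 1.07 s span 84.53 s after the first snapshot (the in-vivo
    acquisition convention).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    # shift by one interval so that frame 0 is the state at t_burn
    res = gillespie_simulate(
        params,
        lattice,
        t_end=t_burn + n_frames * frame_interval,
        record_interval=frame_interval,
        seed=seed,
        t_burn=t_burn,
        pool=pool,
    )
    start = int(np.searchsorted(res.times, t_burn - 1e-9))
    kymo = res.occupancy[start : start + n_frames]
    assert kymo.shape == (n_frames, lattice.n_sites)
    return kymo


# --------------------------------------------------------------------------
# Exact master equation (small lattices)
# --------------------------------------------------------------------------

MASTER_EQUATION_MAX_SITES = 14


def master_equation_stationary(
    params: ModelParameters,
    lattice: Lattice,
    c_free: float | None = None,
) -> OccupancyProfile:
    """Exact stationary per-site occupancies of the 2^n-state Markov chain.

    The pool is treated as unlimited: the free concentration is constant at
    ``c_free`` (default ``kip2_total``), which keeps the chain linear and the
    result exact.  Serves as the oracle for the stochastic and mean-field
    implementations on lattices of up to 14 sites.
    """
    n = lattice.n_sites
    if n > MASTER_EQUATION_MAX_SITES:
        raise ValueError(
            f"master equation limited to {MASTER_EQUATION_MAX_SITES} sites "
            f"(2^n states); got n_sites={n}"
        )
    c = params.kip2_total if c_free is None else float(c_free)
    n_states = 1 << n

    rows, cols, vals = [], [], []

    def add(s_from: int, s_to: int, rate: float):
        if rate <= 0:
            return
        rows.append(s_to)
        cols.append(s_from)
        vals.append(rate)
        rows.append(s_from)
        cols.append(s_from)
        vals.append(-rate)

    for s in range(n_states):
        # entry at minus-end (site 0) if empty
        if not s & 1:
            add(s, s | 1, params.k_in * c)
        for i in range(n):
            bit = 1 << i
            if not s & bit:  # landing on empty site i
                add(s, s | bit, params.k_on * c)
            else:
                if i < n - 1:
                    nxt = 1 << (i + 1)
                    if not s & nxt:  # hop toward plus-end
                        add(s, (s & ~bit) | nxt, params.k_step)
                    add(s, s & ~bit, params.k_off)  # lattice detachment
                else:
                    add(s, s & ~bit, params.k_out)  # plus-end detachment

    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states)).tocsc()
    # stationary distribution: Q pi = 0 (columns sum to 0), sum(pi) = 1
    A = Q.tolil()
    A[n_states - 1, :] = 1.0
    b = np.zeros(n_states)
    b[n_states - 1] = 1.0
    pi = spla.spsolve(A.tocsc(), b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    states = np.arange(n_states)
    rho = np.empty(n)
    for i in range(n):
        rho[i] = pi[(states & (1 << i)) != 0].sum()
    return OccupancyProfile.from_occupancy(rho, params.k_out, c_free=c)


# --------------------------------------------------------------------------
# Mean-field steady state (the inference forward model)
# --------------------------------------------------------------------------


@njit(cache=True)
def _mf_residual(rho, c, k_in, k_on, k_off, k_step, k_out, out):  # pragma: no cover
    n = rho.shape[0]
    if n == 1:
        out[0] = (k_in + k_on) * c * (1.0 - rho[0]) - k_out * rho[0]
        return
    out[0] = (
        (k_in + k_on) * c * (1.0 - rho[0])
        - k_step * rho[0] * (1.0 - rho[1])
        - k_off * rho[0]
    )
    for i in range(1, n - 1):
        out[i] = (
            k_on * c * (1.0 - rho[i])
            + k_step * rho[i - 1] * (1.0 - rho[i])
            - k_step * rho[i] * (1.0 - rho[i + 1])
            - k_off * rho[i]
        )
    out[n - 1] = (
        k_on * c * (1.0 - rho[n - 1])
        + k_step * rho[n - 2] * (1.0 - rho[n - 1])
        - k_out * rho[n - 1]
    )


@njit(cache=True)
def _mf_fixed_c(
    rho, c, k_in, k_on, k_off, k_step, k_out, tol, max_iter
):  # pragma: no cover - exercised through mean_field_steady_state
    """Pseudo-transient continuation on rho with the free concentration fixed.

    Implicit-Euler steps (J - I/dt) drho = -F with an adaptive pseudo-step:
    dt grows on success (approaching full Newton) and shrinks on failure.
    Updates rho in place; returns (residual, converged).
    """
    n = rho.shape[0]
    F = np.empty(n)
    Fnew = np.empty(n)
    lower = np.empty(n)
    diag = np.empty(n)
    upper = np.empty(n)
    cp = np.empty(n)
    x1 = np.empty(n)
    rho_new = np.empty(n)

    dt = 0.1
    _mf_residual(rho, c, k_in, k_on, k_off, k_step, k_out, F)
    res = 0.0
    for i in range(n):
        if abs(F[i]) > res:
            res = abs(F[i])

    for it in range(max_iter):
        if res <= tol:
            return res, True
        shift = 1.0 / dt
        if n == 1:
            diag[0] = -(k_in + k_on) * c - k_out - shift
        else:
            diag[0] = -(k_in + k_on) * c - k_step * (1.0 - rho[1]) - k_off - shift
            upper[0] = k_step * rho[0]
            for i in range(1, n - 1):
                lower[i] = k_step * (1.0 - rho[i])
                diag[i] = (
                    -k_on * c
                    - k_step * rho[i - 1]
                    - k_step * (1.0 - rho[i + 1])
                    - k_off
                    - shift
                )
                upper[i] = k_step * rho[i]
            lower[n - 1] = k_step * (1.0 - rho[n - 1])
            diag[n - 1] = -k_on * c - k_step * rho[n - 2] - k_out - shift

        ok = True
        d0 = diag[0]
        if abs(d0) < 1e-300:
            ok = False
        else:
            x1[0] = -F[0] / d0
            if n > 1:
                cp[0] = upper[0] / d0
                for i in range(1, n):
                    denom = diag[i] - lower[i] * cp[i - 1]
                    if abs(denom) < 1e-300:
                        ok = False
                        break
                    if i < n - 1:
                        cp[i] = upper[i] / denom
                    x1[i] = (-F[i] - lower[i] * x1[i - 1]) / denom
                if ok:
                    for i in range(n - 2, -1, -1):
                        x1[i] -= cp[i] * x1[i + 1]

        if not ok:
            dt *= 0.25
            if dt < 1e-12:
                break
            continue
        for i in range(n):
            v = rho[i] + x1[i]
            if v < 0.0:
                v = 0.0
            elif v > 1.0:
                v = 1.0
            rho_new[i] = v
        _mf_residual(rho_new, c, k_in, k_on, k_off, k_step, k_out, Fnew)
        rn = 0.0
        for i in range(n):
            if abs(Fnew[i]) > rn:
                rn = abs(Fnew[i])
        # accept (implicit Euler follows the relaxation flow even when the
        # residual transiently grows); SER timestep control
        for i in range(n):
            rho[i] = rho_new[i]
            F[i] = Fnew[i]
        if rn > 0.0:
            fac = res / rn
            if fac > 4.0:
                fac = 4.0
            elif fac < 0.25:
                fac = 0.25
            dt *= fac
            # stay in time-integration mode until the residual is small;
            # full Newton steps (huge dt) can two-cycle on shock profiles
            dtmax = 1e10 if rn <= 1e-3 else 200.0
            if dt > dtmax:
                dt = dtmax
            elif dt < 1e-8:
                dt = 1e-8
        else:
            dt = 1e10
        res = rn
    return res, res <= tol


@njit(cache=True)
def _mf_bordered(
    rho,
    c0,
    k_in,
    k_on,
    k_off,
    k_step,
    k_out,
    kip2_total,
    nm_per_motor,
    pool_finite,
    tol,
    max_iter,
    dt0,
):  # pragma: no cover - exercised through mean_field_steady_state
    """Pseudo-transient continuation on the bordered (rho, c) system.

    Used as the final polish after the bisection stage (and as the direct
    solver for well-behaved regimes); returns (rho, c, residual, converged).
    """
    n = rho.shape[0]
    c = c0

    F = np.empty(n)
    Fnew = np.empty(n)
    dFdc = np.empty(n)
    lower = np.empty(n)
    diag = np.empty(n)
    upper = np.empty(n)
    cp = np.empty(n)
    x1 = np.empty(n)
    x2 = np.empty(n)
    rho_new = np.empty(n)

    dt = dt0
    _mf_residual(rho, c, k_in, k_on, k_off, k_step, k_out, F)
    g = c - kip2_total + nm_per_motor * rho.sum() if pool_finite else 0.0
    res = abs(g)
    for i in range(n):
        if abs(F[i]) > res:
            res = abs(F[i])

    for it in range(max_iter):
        if res <= tol:
            return rho, c, res, True

        # tridiagonal Jacobian wrt rho, shifted by -1/dt (implicit Euler)
        shift = 1.0 / dt
        if n == 1:
            diag[0] = -(k_in + k_on) * c - k_out - shift
            dFdc[0] = (k_in + k_on) * (1.0 - rho[0])
        else:
            diag[0] = -(k_in + k_on) * c - k_step * (1.0 - rho[1]) - k_off - shift
            upper[0] = k_step * rho[0]
            dFdc[0] = (k_in + k_on) * (1.0 - rho[0])
            for i in range(1, n - 1):
                lower[i] = k_step * (1.0 - rho[i])
                diag[i] = (
                    -k_on * c
                    - k_step * rho[i - 1]
                    - k_step * (1.0 - rho[i + 1])
                    - k_off
                    - shift
                )
                upper[i] = k_step * rho[i]
                dFdc[i] = k_on * (1.0 - rho[i])
            lower[n - 1] = k_step * (1.0 - rho[n - 1])
            diag[n - 1] = -k_on * c - k_step * rho[n - 2] - k_out - shift
            dFdc[n - 1] = k_on * (1.0 - rho[n - 1])

        # Thomas solves: A x1 = -F and A x2 = -dFdc
        ok = True
        d0 = diag[0]
        if abs(d0) < 1e-300:
            ok = False
        else:
            x1[0] = -F[0] / d0
            x2[0] = -dFdc[0] / d0
            if n > 1:
                cp[0] = upper[0] / d0
                for i in range(1, n):
                    denom = diag[i] - lower[i] * cp[i - 1]
                    if abs(denom) < 1e-300:
                        ok = False
                        break
                    if i < n - 1:
                        cp[i] = upper[i] / denom
                    x1[i] = (-F[i] - lower[i] * x1[i - 1]) / denom
                    x2[i] = (-dFdc[i] - lower[i] * x2[i - 1]) / denom
                if ok:
                    for i in range(n - 2, -1, -1):
                        x1[i] -= cp[i] * x1[i + 1]
                        x2[i] -= cp[i] * x2[i + 1]

        dc = 0.0
        if ok and pool_finite:
            s1 = 0.0
            s2 = 0.0
            for i in range(n):
                s1 += x1[i]
                s2 += x2[i]
            denom = 1.0 + nm_per_motor * s2
            if abs(denom) < 1e-300:
                ok = False
            else:
                dc = (-g - nm_per_motor * s1) / denom

        accepted = False
        if ok:
            for i in range(n):
                v = rho[i] + x1[i] + dc * x2[i]
                if v < 0.0:
                    v = 0.0
                elif v > 1.0:
                    v = 1.0
                rho_new[i] = v
            c_new = c + dc if pool_finite else c
            if pool_finite and c_new < 0.0:
                c_new = 0.0
            _mf_residual(rho_new, c_new, k_in, k_on, k_off, k_step, k_out, Fnew)
            gn = (
                c_new - kip2_total + nm_per_motor * rho_new.sum()
                if pool_finite
                else 0.0
            )
            rn = abs(gn)
            for i in range(n):
                if abs(Fnew[i]) > rn:
                    rn = abs(Fnew[i])
            # accept non-increasing residuals; shrinking dt guarantees progress
            if rn <= res * 1.0001 or rn <= tol:
                for i in range(n):
                    rho[i] = rho_new[i]
                    F[i] = Fnew[i]
                if pool_finite:
                    c = c_new
                g = gn
                res = rn
                dt = dt * 2.0 if dt < 1e8 else dt
                accepted = True
        if not accepted:
            dt *= 0.25
            if dt < 1e-12:
                break

    return rho, c, res, res <= tol


@njit(cache=True)
def _mf_core(
    n,
    k_in,
    k_on,
    k_off,
    k_step,
    k_out,
    kip2_total,
    nm_per_motor,
    pool_finite,
    c_fixed,
    tol,
    max_iter,
):  # pragma: no cover - exercised through mean_field_steady_state
    """Steady-state solve: fixed-c PTC, pool bisection, bordered polish.

    The free concentration is the scalar unknown of the conservation
    relation g(c) = c + nu*sum(rho(c)) - total, which is monotone in c, so
    bisection with warm-started fixed-c solves is globally convergent; a
    bordered Newton polish then drives the coupled residual below tol.
    """
    rho = np.empty(n)

    def _init_langmuir(c):
        u = k_on * c + 1e-12
        v = u / (u + k_off + 1e-12)
        if v < 0.05:
            v = 0.05
        elif v > 0.95:
            v = 0.95
        for i in range(n):
            rho[i] = v

    def _solve_at(c, warm):
        # warm start, then Langmuir re-init, then extended iterations
        if not warm:
            _init_langmuir(c)
        res, ok = _mf_fixed_c(rho, c, k_in, k_on, k_off, k_step, k_out, tol, max_iter)
        if not ok and warm:
            _init_langmuir(c)
            res, ok = _mf_fixed_c(rho, c, k_in, k_on, k_off, k_step, k_out, tol, max_iter)
        if not ok:
            _init_langmuir(c)
            res, ok = _mf_fixed_c(
                rho, c, k_in, k_on, k_off, k_step, k_out, tol, 3 * max_iter
            )
        return res, ok

    if not pool_finite:
        res, ok = _solve_at(c_fixed, False)
        return rho, c_fixed, res, ok

    # bracket: g(0) = -total (empty lattice binds nothing); g(total) >= 0
    c_lo = 0.0
    g_lo = -kip2_total
    c_hi = kip2_total
    res, ok = _solve_at(c_hi, False)
    if not ok:
        return rho, c_hi, res, False
    g_hi = c_hi + nm_per_motor * rho.sum() - kip2_total
    if g_hi <= 0.0:
        # pool effectively unlimited at this occupancy
        return rho, c_hi, res, True
    # Illinois-safeguarded secant on the monotone pool balance g(c); a coarse
    # root usually suffices because the bordered Newton polish finishes the
    # solve, with a tighter second pass when the polish fails
    scale_c = max(1.0, kip2_total)
    for stage in range(2):
        width_exit = 1e-3 * scale_c if stage == 0 else 1e-9 * scale_c
        g_exit = 1e-4 * scale_c if stage == 0 else 0.0
        side = 0
        for it in range(60 if stage == 0 else 48):
            if c_hi - c_lo < width_exit:
                break
            c = c_hi - g_hi * (c_hi - c_lo) / (g_hi - g_lo)
            if not (c_lo < c < c_hi):
                c = 0.5 * (c_lo + c_hi)
            res, ok = _solve_at(c, True)
            if not ok:
                return rho, c, res, False
            g = c + nm_per_motor * rho.sum() - kip2_total
            if g > 0.0:
                c_hi = c
                g_hi = g
                if side == 1:
                    g_lo *= 0.5
                side = 1
            else:
                c_lo = c
                g_lo = g
                if side == -1:
                    g_hi *= 0.5
                side = -1
            if abs(g) < g_exit:
                break
        c_mid = 0.5 * (c_lo + c_hi)
        res, ok = _solve_at(c_mid, True)
        if not ok:
            return rho, c_mid, res, False
        rho_p, c_p, res_p, ok_p = _mf_bordered(
            rho.copy(),
            c_mid,
            k_in,
            k_on,
            k_off,
            k_step,
            k_out,
            kip2_total,
            nm_per_motor,
            True,
            tol,
            max_iter,
            1e6,
        )
        if ok_p:
            return rho_p, c_p, res_p, True
    return rho_p, c_p, res_p, ok_p


def mean_field_steady_state(
    params: ModelParameters,
    lattice: Lattice,
    tol: float = 1e-10,
    max_iter: int = 1000,
    *,
    pool: str = "finite",
    c_free: float | None = None,
    init: tuple[np.ndarray, float] | None = None,
) -> OccupancyProfile:
    """Mean-field stationary occupancy profile with a self-consistent pool.

    Solves the site-wise rate equations (correlations between neighbouring
    sites neglected) for the five-rate model, coupled to the conservation
    relation ``c = kip2_total - nm_per_bound_motor * sum(rho)`` when
    ``pool="finite"``.  With ``pool="unlimited"`` the free concentration is
    held at ``c_free`` (default ``kip2_total``).  Exact in the dilute limit;
    the deterministic forward model used for likelihood inference.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if pool not in ("finite", "unlimited"):
        raise ValueError("pool must be 'finite' or 'unlimited'")
    rho, c = _mean_field_raw(
        params, lattice.n_sites, tol, max_iter, pool == "finite", c_free, init
    )
    return OccupancyProfile.from_occupancy(rho, params.k_out, c_free=float(c))


def _mean_field_raw(
    params: ModelParameters,
    n_sites: int,
    tol: float,
    max_iter: int,
    pool_finite: bool,
    c_free: float | None,
    init: tuple[np.ndarray, float] | None,
) -> tuple[np.ndarray, float]:
    """Solver core without container overhead; raises on non-convergence."""
    c_fixed = params.kip2_total if c_free is None else float(c_free)
    if init is not None and pool_finite:
        rho0, c0 = init
        if rho0.shape == (n_sites,):
            # warm start: Newton-polish from a nearby previous solution
            rho, c, res, ok = _mf_bordered(
                np.array(rho0, dtype=float),
                float(c0),
                float(params.k_in),
                float(params.k_on),
                float(params.k_off),
                float(params.k_step),
                float(params.k_out),
                float(params.kip2_total),
                float(params.nm_per_bound_motor),
                True,
                float(tol),
                60,
                1e4,
            )
            if ok:
                return rho, float(c)
    rho, c, res, ok = _mf_core(
        n_sites,
        float(params.k_in),
        float(params.k_on),
        float(params.k_off),
        float(params.k_step),
        float(params.k_out),
        float(params.kip2_total),
        float(params.nm_per_bound_motor),
        pool_finite,
        c_fixed,
        float(tol),
        int(max_iter),
    )
    if not ok:
        raise ConvergenceError(
            f"mean-field solver did not reach tol={tol:g} within "
            f"{max_iter} Newton iterations (last residual {res:.3e})",
            residual=float(res),
        )
    return rho, float(c)
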