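"""Line-scan alignment, binning, forward map and plus-end regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kip2traffic.lattice_model import build_lattice, mean_field_steady_state
from kip2traffic.profile_model import (
    PIXEL_NM,
    AlignmentError,
    InsufficientDataError,
    LineScanProfile,
    align_to_reference_peak,
    bin_by_length,
    occupancy_to_profile,
    plus_end_regression,
    read_line_scan_csv,
    write_line_scan_csv,
)


def make_profile(n=20, mch_peak=3, gfp_peak=9, start_px=0):
    positions = (np.arange(n) + start_px) * PIXEL_NM
    gfp = np.ones(n)
    gfp[gfp_peak] = 10.0
    mch = np.ones(n)
    mch[mch_peak] = 50.0
    return LineScanProfile(positions_nm=positions, gfp=gfp, mcherry=mch, cell_id="c")


class TestAlignment:
    def test_reference_already_at_zero_is_unchanged(self):
        p = make_profile(mch_peak=0)
        a = align_to_reference_peak(p)
        assert np.allclose(a.positions_nm, p.positions_nm)

    def test_shift_by_reference_peak(self):
        a = align_to_reference_peak(make_profile(mch_peak=3))
        assert a.positions_nm[3] == pytest.approx(0.0)
        assert a.positions_nm[0] == pytest.approx(-3 * PIXEL_NM)

    def test_peak_to_peak_length(self):
        a = align_to_reference_peak(make_profile(mch_peak=3, gfp_peak=12))
        # isolated single-pixel peaks: sub-pixel refinement is zero
        assert a.profile_length_nm == pytest.approx(9 * PIXEL_NM)

    def test_flat_reference_channel_raises(self):
        p = make_profile()
        p.mcherry[:] = 1.0
        with pytest.raises(AlignmentError):
            align_to_reference_peak(p)

    def test_idempotent(self):
        a1 = align_to_reference_peak(make_profile(mch_peak=5, gfp_peak=11))
        a2 = align_to_reference_peak(a1)
        assert np.allclose(a1.positions_nm, a2.positions_nm)
        assert a1.profile_length_nm == pytest.approx(a2.profile_length_nm)

    def test_subpixel_refinement_recovers_off_grid_peak(self):
        # a Gaussian spot centred between pixels is located to < 15 nm
        true_center = 9.4 * PIXEL_NM
        pos = np.arange(20) * PIXEL_NM
        gfp = 1.0 + 10 * np.exp(-0.5 * ((pos - true_center) / 150.0) ** 2)
        mch = np.ones(20)
        mch[0] = 50.0
        a = align_to_reference_peak(
            LineScanProfile(positions_nm=pos, gfp=gfp, mcherry=mch)
        )
        assert a.profile_length_nm == pytest.approx(true_center, abs=15.0)


class TestBinning:
    def test_single_profile_single_bin(self):
        a = align_to_reference_peak(make_profile(mch_peak=0, gfp_peak=9))
        ds = bin_by_length([a])
        assert len(ds.bins) == 1
        b = ds.bins[0]
        # 9 px = 1200.15 nm falls in [1066.8, 1333.5)
        assert b.lo_nm == pytest.approx(4 * 266.7)
        assert b.n == 1
        assert np.allclose(b.mean_gfp, a.gfp)
        assert np.allclose(b.ci95_gfp, 0.0)

    def test_identical_profiles_zero_ci(self):
        a = align_to_reference_peak(make_profile())
        ds = bin_by_length([a, a])
        assert ds.bins[0].n == 2
        assert np.allclose(ds.bins[0].ci95_gfp, 0.0, atol=1e-12)

    def test_partition_preserves_profile_count(self):
        rng = np.random.default_rng(1)
        profiles = [
            align_to_reference_peak(
                make_profile(gfp_peak=int(g), mch_peak=2)
            )
            for g in rng.integers(6, 18, size=25)
        ]
        ds = bin_by_length(profiles)
        assert ds.n_profiles == 25
        for b in ds.bins:
            assert np.all(b.member_lengths_nm >= b.lo_nm)
            assert np.all(b.member_lengths_nm < b.hi_nm)

    def test_ci_follows_clt(self):
        rng = np.random.default_rng(7)
        sigma = 0.5
        profiles = []
        for _ in range(100):
            p = make_profile(mch_peak=2, gfp_peak=10)
            p.gfp = p.gfp + rng.normal(0, sigma, p.gfp.size)
            profiles.append(align_to_reference_peak(p))
        ds = bin_by_length(profiles)
        b = max(ds.bins, key=lambda b: b.n)
        interior = (b.n_per_position == b.n) & (b.sem_gfp > 0)
        expected = 1.96 * sigma / np.sqrt(b.n)
        med = np.median(b.ci95_gfp[interior])
        assert med == pytest.approx(expected, rel=0.25)

    def test_rejects_unaligned_profiles(self):
        with pytest.raises(ValueError, match="aligned"):
            bin_by_length([make_profile()])

    def test_rejects_nonpositive_bin_width(self):
        with pytest.raises(ValueError):
            bin_by_length([], bin_width_nm=0.0)


class TestForwardMap:
    def test_zero_occupancy_is_flat_background(self):
        prof = occupancy_to_profile(np.zeros(300), scale=2.0, background=1.5)
        assert np.allclose(prof.gfp, 1.5)

    def test_uniform_occupancy_level(self):
        rho = 0.3
        prof = occupancy_to_profile(np.full(400, rho), scale=2.0, background=1.0)
        sites_per_pixel = PIXEL_NM / 8.0
        interior = prof.gfp[2:-2]
        assert np.allclose(interior, 1.0 + 2.0 * rho * sites_per_pixel, rtol=1e-9)

    def test_delta_at_tip_with_psf_preserves_mass(self):
        dens = np.zeros(250)
        dens[-1] = 1.0
        prof = occupancy_to_profile(dens, scale=1.0, background=0.2, psf_sigma_nm=150.0)
        mass = (prof.gfp - 0.2).sum()
        assert mass == pytest.approx(1.0, rel=0.01)
        # bump peaks near the tip position
        tip = 249.5 * 8.0
        assert abs(prof.positions_nm[np.argmax(prof.gfp)] - tip) < PIXEL_NM

    def test_linear_in_occupancy(self, rng):
        a = rng.uniform(0, 0.5, 200)
        b = rng.uniform(0, 0.5, 200)
        f = lambda x: occupancy_to_profile(x, scale=3.0, background=1.0).gfp - 1.0
        assert np.allclose(f(a + b), f(a) + f(b), atol=1e-9)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            occupancy_to_profile(np.ones(10), scale=0.0, background=0.0)
        with pytest.raises(ValueError):
            occupancy_to_profile(np.ones(10), scale=1.0, background=0.0, psf_sigma_nm=-1)

    def test_matches_model_total_bound(self, ref_params):
        occ = mean_field_steady_state(ref_params, build_lattice(1600.0))
        prof = occupancy_to_profile(occ, scale=1.0, background=0.0)
        assert prof.gfp.sum() == pytest.approx(occ.total_bound, rel=1e-9)


def _dataset_with_plus_end_values(values, lengths_px):
    profiles = []
    for v, L in zip(values, lengths_px):
        for _ in range(2):
            p = make_profile(n=30, mch_peak=0, gfp_peak=L)
            p.gfp[L] = v
            profiles.append(align_to_reference_peak(p))
    return bin_by_length(profiles)


class TestPlusEndRegression:
    def test_two_points_slope_and_intercept(self):
        # plus-end means 10 a.u. at ~1 um and 20 a.u. at ~2 um
        ds = _dataset_with_plus_end_values([10.0, 20.0], [8, 15])
        reg = plus_end_regression(ds)
        x1, x2 = reg.lengths_um
        slope = (20.0 - 10.0) / (x2 - x1)
        assert reg.slope_au_per_um == pytest.approx(slope, rel=1e-9)
        assert reg.intercept_au == pytest.approx(10.0 - slope * x1, rel=1e-6)

    def test_constant_bins_zero_slope(self):
        ds = _dataset_with_plus_end_values([7.0, 7.0, 7.0], [6, 10, 14])
        reg = plus_end_regression(ds)
        assert reg.slope_au_per_um == pytest.approx(0.0, abs=1e-9)
        assert reg.intercept_au == pytest.approx(7.0, rel=1e-9)

    def test_recovers_generating_slope_within_2_se(self, rng):
        slope_true, intercept_true = 4.0, 2.0
        profiles = []
        for _ in range(120):
            # even pixel positions: one peak position per 2-pixel length bin,
            # so the bin-mean profile's peak is an unbiased plus-end value
            L = 2 * int(rng.integers(3, 9))
            p = make_profile(n=30, mch_peak=0, gfp_peak=L)
            x_um = L * PIXEL_NM / 1000.0
            p.gfp[L] = intercept_true + slope_true * x_um + rng.normal(0, 0.4)
            profiles.append(align_to_reference_peak(p))
        reg = plus_end_regression(bin_by_length(profiles))
        assert abs(reg.slope_au_per_um - slope_true) < 2 * reg.slope_se

    def test_requires_two_bins(self):
        ds = _dataset_with_plus_end_values([5.0], [9])
        with pytest.raises(InsufficientDataError):
            plus_end_regression(ds)


def test_csv_round_trip(tmp_path):
    p = make_profile()
    write_line_scan_csv(p, tmp_path / "cell.csv")
    q = read_line_scan_csv(tmp_path / "cell.csv")
    assert np.allclose(q.positions_nm, p.positions_nm)
    assert np.allclose(q.gfp, p.gfp)
    assert q.cell_id == "cell"


def test_csv_missing_column_cited(tmp_path):
    (tmp_path / "bad.csv").write_text("position_nm,gfp_au\n0,1\n133.35,2\n")
    with pytest.raises(ValueError, match="mcherry_au"):
        read_line_scan_csv(tmp_path / "bad.csv")


@given(st.integers(min_value=1, max_value=8))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_alignment_shift_is_integer_pixels(shift_px):
    a = align_to_reference_peak(make_profile(mch_peak=shift_px, gfp_peak=12))
    k = a.positions_nm / PIXEL_NM
    assert np.allclose(k, np.round(k), atol=1e-9)
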