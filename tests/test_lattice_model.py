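"""Exclusion-process traffic model: oracles, closed forms, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kip2traffic.lattice_model import (
    AVOGADRO,
    ConvergenceError,
    K_OUT_IN_VITRO,
    Lattice,
    ModelParameters,
    build_lattice,
    free_concentration,
    gillespie_simulate,
    master_equation_stationary,
    mean_field_steady_state,
    reference_parameters,
    simulate_kymograph,
)


@pytest.mark.parametrize(
    "length_nm, site_nm, expected",
    [(2400.0, 8.0, 300), (666.7, 8.0, 83), (4.0, 8.0, 1), (8.0, 8.0, 1)],
)
def test_build_lattice_discretization(length_nm, site_nm, expected):
    lat = build_lattice(length_nm, site_nm)
    assert lat.n_sites == expected
    assert not lat.occupancy.any()


@pytest.mark.parametrize("bad", [0.0, -5.0, np.nan])
def test_build_lattice_rejects_nonpositive_length(bad):
    with pytest.raises(ValueError):
        build_lattice(bad)


@given(st.floats(min_value=1.0, max_value=1e5), st.floats(min_value=0.5, max_value=50))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_build_lattice_floor_property(length_nm, site_nm):
    lat = build_lattice(length_nm, site_nm)
    assert lat.n_sites == max(1, int(length_nm // site_nm))
    assert lat.n_sites * site_nm <= length_nm or lat.n_sites == 1


class TestFreeConcentration:
    def test_untouched_pool_returns_total(self):
        p = reference_parameters()
        assert free_concentration(p, 0) == p.kip2_total  # 35 nM

    def test_floors_at_zero_when_pool_exceeded(self):
        p = reference_parameters()
        assert free_concentration(p, 10_000_000) == 0.0

    def test_conservation_arithmetic(self):
        # 602 molecules in 1 pL are 602 / (N_A * 1e-12 L) mol/L = 1 nM
        p = reference_parameters(kip2_total=35.0).with_(
            volume_fl=1000.0, n_microtubules=1
        )
        c = free_concentration(p, 602)
        expected = 35.0 - 602 / (AVOGADRO * 1e-12) / 1e-9
        assert c == pytest.approx(expected, rel=1e-9)
        assert c == pytest.approx(34.0, abs=2e-3)

    def test_invalid_volume_rejected(self):
        with pytest.raises(ValueError):
            reference_parameters().with_(volume_fl=0.0)


class TestMasterEquation:
    def test_no_entry_paths_gives_empty_lattice(self, ref_params):
        p = ref_params.with_(k_in=0.0, k_on=0.0)
        prof = master_equation_stationary(p, build_lattice(32.0))
        assert np.allclose(prof.mean_occupancy, 0.0, atol=1e-12)
        assert prof.total_bound == pytest.approx(0.0, abs=1e-12)

    def test_single_site_closed_form(self, ref_params):
        # one site: entry (k_in + k_on)c vs exit k_out, two-state birth-death
        c = 10.0
        prof = master_equation_stationary(ref_params, build_lattice(8.0), c_free=c)
        r_in = (ref_params.k_in + ref_params.k_on) * c
        assert prof.mean_occupancy[0] == pytest.approx(
            r_in / (r_in + ref_params.k_out), rel=1e-10
        )

    def test_uncoupled_sites_are_independent_langmuir(self, ref_params):
        # no stepping, no minus-end entry: each site is an independent
        # two-state site, the terminal one exiting with k_out
        p = ref_params.with_(k_step=0.0, k_in=0.0)
        c = 5.0
        prof = master_equation_stationary(p, build_lattice(24.0), c_free=c)
        langmuir = p.k_on * c / (p.k_on * c + p.k_off)
        terminal = p.k_on * c / (p.k_on * c + p.k_out)
        assert np.allclose(prof.mean_occupancy[:-1], langmuir, rtol=1e-10)
        assert prof.mean_occupancy[-1] == pytest.approx(terminal, rel=1e-10)

    def test_size_guard(self, ref_params):
        with pytest.raises(ValueError, match="2\\^n"):
            master_equation_stationary(ref_params, build_lattice(8.0 * 20))


class TestMeanField:
    def test_langmuir_isotherm_without_transport(self, ref_params):
        p = ref_params.with_(k_step=0.0, k_in=0.0, k_out=ref_params.k_off)
        c = 8.0
        prof = mean_field_steady_state(p, build_lattice(800.0), pool="unlimited", c_free=c)
        langmuir = p.k_on * c / (p.k_on * c + p.k_off)
        assert np.allclose(prof.mean_occupancy, langmuir, rtol=1e-8)

    def test_terminal_flux_balance(self, ref_params):
        prof = mean_field_steady_state(ref_params, build_lattice(1600.0))
        rho = prof.mean_occupancy
        c = prof.c_free
        influx = ref_params.k_on * c * (1 - rho[-1]) + ref_params.k_step * rho[-2] * (
            1 - rho[-1]
        )
        assert influx == pytest.approx(ref_params.k_out * rho[-1], abs=1e-8)
        assert prof.flux_out == pytest.approx(ref_params.k_out * rho[-1], rel=1e-12)

    def test_dilute_limit_matches_master_equation(self, ref_params):
        # scale the binding rates down so all occupancies are < 5%: pair
        # correlations vanish and mean field becomes exact
        p = ref_params.with_(k_in=1e-3, k_on=1e-6)
        lat = build_lattice(32.0)
        c = 10.0
        mf = mean_field_steady_state(p, lat, pool="unlimited", c_free=c)
        me = master_equation_stationary(p, lat, c_free=c)
        assert np.all(me.mean_occupancy < 0.05)
        assert np.allclose(mf.mean_occupancy, me.mean_occupancy, rtol=0.05)

    def test_pool_conservation_self_consistent(self, ref_params):
        prof = mean_field_steady_state(ref_params, build_lattice(2000.0))
        assert prof.c_free == pytest.approx(
            ref_params.kip2_total - prof.total_bound * ref_params.nm_per_bound_motor,
            abs=1e-6,
        )
        assert 0.0 < prof.c_free < ref_params.kip2_total

    def test_increasing_k_out_decreases_terminal_occupancy(self, ref_params):
        lat = build_lattice(400.0)
        tips_mf = []
        tips_me = []
        small = build_lattice(48.0)
        for k_out in (0.5, 1.5, 3.3, 10.0):
            p = ref_params.with_(k_out=k_out)
            tips_mf.append(
                mean_field_steady_state(p, lat, pool="unlimited", c_free=5.0)
                .mean_occupancy[-1]
            )
            tips_me.append(
                master_equation_stationary(p, small, c_free=5.0).mean_occupancy[-1]
            )
        assert np.all(np.diff(tips_mf) < 0)
        assert np.all(np.diff(tips_me) < 0)

    def test_invalid_tolerance(self, ref_params):
        with pytest.raises(ValueError):
            mean_field_steady_state(ref_params, build_lattice(80.0), tol=-1.0)


def _timeavg(params, lattice, t_end, seed, t_burn, pool="unlimited"):
    return gillespie_simulate(
        params, lattice, t_end=t_end, record_interval=t_end / 10, seed=seed,
        t_burn=t_burn, pool=pool,
    ).time_avg_occupancy


class TestGillespie:
    def test_no_entry_paths_stays_empty(self, ref_params):
        p = ref_params.with_(k_in=0.0, k_on=0.0)
        res = gillespie_simulate(
            p, build_lattice(160.0), t_end=50.0, record_interval=1.0, seed=1
        )
        assert not res.occupancy.any()
        assert np.allclose(res.time_avg_occupancy, 0.0)

    def test_single_site_birth_death_mean(self, ref_params):
        # long-run mean occupancy of one site = r_in / (r_in + k_out)
        c = 10.0
        p = ref_params.with_(kip2_total=c)
        r_in = (p.k_in + p.k_on) * c
        expected = r_in / (r_in + p.k_out)
        occ = _timeavg(p, build_lattice(8.0), t_end=4000.0, seed=11, t_burn=50.0)
        # Monte-Carlo standard error from the number of ~independent cycles
        n_cycles = 4000.0 * r_in * p.k_out / (r_in + p.k_out) ** 2 * (r_in + p.k_out)
        se = np.sqrt(expected * (1 - expected) / max(n_cycles, 1))
        assert abs(occ[0] - expected) < 3 * max(se, 0.01)

    @pytest.mark.parametrize("n_sites", [2, 4, 6])
    def test_matches_master_equation_oracle(self, ref_params, n_sites):
        c = 10.0
        p = ref_params.with_(kip2_total=c)
        lat = build_lattice(8.0 * n_sites)
        exact = master_equation_stationary(p, lat, c_free=c).mean_occupancy
        occ = _timeavg(p, lat, t_end=3000.0, seed=100 + n_sites, t_burn=100.0)
        # conservative MC error: binomial variance over ~independent residence
        # periods of length ~1/k_out each
        se = np.sqrt(exact * (1 - exact) / (3000.0 * p.k_out / 4))
        assert np.all(np.abs(occ - exact) < 3 * np.maximum(se, 0.012))

    def test_exclusion_and_conservation_from_event_log(self, ref_params):
        res = gillespie_simulate(
            ref_params,
            build_lattice(400.0),
            t_end=60.0,
            record_interval=1.0,
            seed=5,
            log_events=True,
        )
        assert res.occupancy.max() <= 1  # exclusion in every snapshot
        # replay the event log: occupancy stays 0/1, bound count matches
        occ = np.zeros(50, dtype=int)
        for t, name, site in res.event_log():
            if name in ("enter", "land"):
                assert occ[site] == 0
                occ[site] = 1
            elif name == "hop":
                assert occ[site] == 1 and occ[site + 1] == 0
                occ[site], occ[site + 1] = 0, 1
            else:
                assert occ[site] == 1
                occ[site] = 0
        assert occ.sum() == res.occupancy[-1].sum()

    def test_tip_residence_time_is_inverse_k_out(self, ref_params):
        # terminal site departs only via k_out, so residence is Exp(k_out)
        p = ref_params.with_(k_out=2.0, kip2_total=10.0)
        res = gillespie_simulate(
            p, build_lattice(80.0), t_end=2000.0, record_interval=50.0, seed=3,
            pool="unlimited", log_events=True,
        )
        tau = res.tip_residence_times(10)
        assert tau.size > 100
        se = tau.std(ddof=1) / np.sqrt(tau.size)
        assert abs(tau.mean() - 1.0 / p.k_out) < 3 * se


class TestKymograph:
    def test_shape_and_time_span(self, ref_params):
        lat = build_lattice(666.7)
        kymo = simulate_kymograph(ref_params, lat, n_frames=80, frame_interval=1.07, seed=9)
        assert kymo.shape == (80, lat.n_sites)
        # 80 frames span 79 * 1.07 s = 84.53 s after the first snapshot
        assert 79 * 1.07 == pytest.approx(84.53)

    def test_zero_rates_all_zero(self, ref_params):
        p = ref_params.with_(k_in=0.0, k_on=0.0)
        kymo = simulate_kymograph(p, build_lattice(160.0), 10, 1.07, seed=2)
        assert not kymo.any()

    def test_in_vitro_k_out_queues_at_the_tip(self, ref_params):
        """Low plus-end detachment (30-s residence) piles motors at the tip."""
        lat = build_lattice(2000.0)
        p = ref_params.with_(k_out=K_OUT_IN_VITRO)
        res = gillespie_simulate(
            p, lat, t_end=1100.0, record_interval=20.0, seed=4, t_burn=500.0
        )
        occ = res.time_avg_occupancy
        ntip = lat.n_sites // 10
        assert occ[-ntip:].mean() > 5 * occ[:-ntip].mean()


def test_lattice_rejects_double_occupancy():
    with pytest.raises(ValueError):
        Lattice(n_sites=3, occupancy=np.array([0, 2, 0]))


def test_parameters_reject_negative_rates():
    with pytest.raises(ValueError):
        ModelParameters(k_in=-0.1, k_on=1e-4, k_off=0.02)
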