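"""Per-hepatocyte ODE systems: steady states, oracle accuracy, fate rules."""

import numpy as np
import pytest

from lobulesim import geometry as geo
from lobulesim.intracellular import (EVENT_NECROSIS, EVENT_NONE,
                                     EVENT_PROLIFERATION, EVENT_SENESCENCE,
                                     HepatocyteCohort, check_fate,
                                     reference_trajectory, step_cohort,
                                     step_cyclin, step_ddr, step_metabolism,
                                     step_receptor)
from lobulesim.params import ModelParams


def make_cohort(params, gsh=(4.0, 20.61, 37.22), p450=(1.65, 1.15, 0.65)):
    return HepatocyteCohort(np.array(gsh), np.array(p450), params)


class TestSteadyStates:
    def test_gsh_fixed_point_without_apap(self, params):
        c = make_cohort(params)
        g0 = c["G"].copy()
        step_metabolism(c, 0.0, dt=6.0, substeps=360)
        assert np.allclose(c["G"], g0, rtol=1e-9)
        assert np.allclose(c["S"], params.metabolism.paps_steady_state, rtol=1e-9)

    def test_ddr_basal_state_is_stationary_over_24h(self, params):
        c = make_cohort(params)
        before = c.y.copy()
        step_ddr(c, dt=24.0, substeps=1440)
        for var in ("P53", "P53p", "MDM2", "P21"):
            assert np.allclose(c[var], before[list(
                ("P_in", "S", "N", "G", "C", "P53", "P53p", "MDM2", "P21",
                 "R", "RT", "K")).index(var)], atol=1e-9)

    def test_cyclin_fixed_point_at_basal_p21(self, params):
        c = make_cohort(params)
        step_cyclin(c, 0.0, dt=24.0, substeps=1440)
        assert np.allclose(c["K"], params.fate.K_initial, rtol=1e-12)


class TestReceptor:
    def test_conservation_every_step(self, params):
        c = make_cohort(params)
        c["RT"] = 0.3
        c["R"] = 0.7
        for _ in range(50):
            step_receptor(c, 1.7, dt=0.1, substeps=5)
            assert np.allclose(c["R"] + c["RT"], 1.0, atol=1e-12)

    def test_unbinding_rate_without_ligand(self, params):
        c = make_cohort(params)
        c["RT"] = 0.8
        c["R"] = 0.2
        step_receptor(c, 0.0, dt=0.5, substeps=100)
        assert np.allclose(c["RT"], 0.8 * np.exp(-6.0 * 0.5), rtol=1e-6)

    def test_equilibrium_occupancy_closed_form(self, params):
        c = make_cohort(params)
        step_receptor(c, 2.0, dt=10.0, substeps=600)
        # RT* = (kon/koff*T) / (1 + kon/koff*T) = 0.5 at T = 2
        assert np.allclose(c["RT"], 0.5, atol=1e-6)


class TestOracleAccuracy:
    def test_full_system_matches_adaptive_integrator(self, params):
        c = make_cohort(params)
        ref = make_cohort(params)
        P, T, M = 450.0, 0.5, 0.3
        for _ in range(72):  # 6 h at the driver's 5-min / 20-substep setting
            step_cohort(c, 5 / 60, P, T, M, substeps=20)
        sol = reference_trajectory(ref, (0.0, 6.0), P, T, M, rtol=1e-10,
                                   atol=1e-12)
        y_ref = sol.y[: 12 * 3].reshape(12, 3, -1)[..., -1]
        assert np.allclose(c.y, y_ref, rtol=1e-6, atol=1e-9)

    def test_cyclin_accuracy_within_fate_window_resolution(self, params):
        # the fate window is 7.25e-5 wide, so K needs ~1e-8 relative accuracy
        c = make_cohort(params)
        ref = make_cohort(params)
        for _ in range(72):
            step_cohort(c, 5 / 60, 450.0, 0.5, 0.3, substeps=20)
        sol = reference_trajectory(ref, (0.0, 6.0), 450.0, 0.5, 0.3,
                                   rtol=1e-12, atol=1e-14)
        k_ref = sol.y[: 12 * 3].reshape(12, 3, -1)[11, :, -1]
        assert np.allclose(c["K"], k_ref, rtol=1e-8)


class TestMetabolismBehaviour:
    def test_mass_accounting(self, params):
        c = make_cohort(params)
        for _ in range(96):
            step_cohort(c, 5 / 60, 450.0 * np.exp(-0.34657 * 0), 0.0, 0.0,
                        substeps=20)
        uptaken = c.route("uptaken")
        inside = c["P_in"] + c["N"] + c.route("glucuronidated") \
            + c.route("sulfated") + c.route("gsh_conjugated") \
            + c.route("adduct_formed")
        assert np.allclose(uptaken, inside, rtol=1e-6)

    def test_peak_adducts_monotone_in_dose(self, params):
        ktot = params.plasma.k_e + 600 * params.plasma.k_u
        peaks = []
        for dose in [250, 350, 450, 550, 650]:
            c = make_cohort(params, gsh=(4.0,), p450=(1.65,))
            peak = 0.0
            t = 0.0
            for _ in range(int(16 * 12)):
                step_cohort(c, 5 / 60, dose * np.exp(-ktot * t), 0.0, 0.0,
                            substeps=10)
                t += 5 / 60
                peak = max(peak, float(c["C"][0]))
            peaks.append(peak)
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_pericentral_adducts_exceed_periportal_at_450(self, params):
        ktot = params.plasma.k_e + 600 * params.plasma.k_u
        c = make_cohort(params)  # pericentral, mid, periportal
        t = 0.0
        for _ in range(int(14 * 12)):
            step_cohort(c, 5 / 60, 450.0 * np.exp(-ktot * t), 0.0, 0.0,
                        substeps=10)
            t += 5 / 60
        assert c["C"][0] > c["C"][2]
        assert c["C"][0] > 4.0 > c["C"][1]  # necrosis only pericentrally

    def test_ddr_pulse_and_sustained_p21_under_tgfb(self, params):
        c = make_cohort(params, gsh=(20.61,), p450=(1.15,))
        c["C"] = 5.0
        p53p_peak = 0.0
        for _ in range(12 * 12):
            step_ddr(c, dt=5 / 60, substeps=10)
            c["C"] *= np.exp(-0.3 * 5 / 60)  # decaying insult
            p53p_peak = max(p53p_peak, float(c["P53p"][0]))
        assert p53p_peak > 10 * c["P53p"][0]  # pulse returned toward basal
        # receptor occupancy keeps p21 above basal after the pulse
        basal_p21 = params.ddr.basal_state()["P21"]
        c["RT"] = 0.5
        p21_before = float(c["P21"][0])
        step_ddr(c, dt=24.0, substeps=1440)
        assert c["P21"][0] > p21_before or c["P21"][0] > basal_p21


class TestFateRules:
    def test_necrosis_frequency(self, params, rng):
        n = 10_000
        events = check_fate(np.full(n, 4.5), np.full(n, params.fate.K_initial),
                            rng, params.fate)
        frac = (events == EVENT_NECROSIS).mean()
        sigma = np.sqrt(0.8 * 0.2 / n)
        assert abs(frac - 0.8) < 4 * sigma

    def test_dead_zone_is_inert(self, params, rng):
        events = check_fate(np.full(100, 1.0),
                            np.full(100, params.fate.K_initial), rng,
                            params.fate)
        assert (events == EVENT_NONE).all()

    def test_rule_table_branches(self, params, rng):
        n = 100_000
        C = rng.uniform(0, 8, n)
        K = params.fate.K_initial + rng.uniform(-1e-4, 1e-4, n)
        events = check_fate(C, K, rng, params.fate)
        fate = params.fate
        necro_zone = C > fate.necrosis_threshold
        prolif_zone = ~necro_zone & (K > fate.prolif_threshold)
        senesc_zone = ~necro_zone & (K < fate.senesc_threshold)
        assert (events[events == EVENT_NECROSIS] >= 0).all()
        assert not (events[~necro_zone] == EVENT_NECROSIS).any()
        assert (events[senesc_zone] == EVENT_SENESCENCE).all()
        assert not (events[~prolif_zone] == EVENT_PROLIFERATION).any()
        # stochastic branches hit their zones at the stated rates
        assert (events[necro_zone] == EVENT_NECROSIS).mean() == pytest.approx(
            0.8, abs=0.02)
        assert (events[prolif_zone] == EVENT_PROLIFERATION).mean() == pytest.approx(
            0.001, abs=0.001)

    def test_necrosis_probability_override(self, params, rng):
        events = check_fate(np.full(2000, 5.0),
                            np.full(2000, params.fate.K_initial), rng,
                            params.fate, p_necrosis=0.0)
        assert not (events == EVENT_NECROSIS).any()
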