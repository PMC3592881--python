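"""Membrane-model tests: Nernst potentials, current formulas, charge
bookkeeping, oscillatory attractors and co-transport effects."""

import math

import numpy as np
import pytest

from betacell.electro import (
    CURRENT_NAMES,
    ELECTRO_STATE_NAMES,
    ElectroParameters,
    FARADAY,
    GAS_CONSTANT,
    G_NAALA_10MM,
    K_ATP_BASAL,
    K_ATP_STIM,
    channel_currents,
    default_electro_state,
    electro_rhs,
    mean_state_scan,
    na_ala_current,
    nernst_potential,
    simulate_electro,
)
from betacell.metabolic import ParameterError
from betacell.scans import oscillation_summary


class TestNernst:
    def test_symmetric_bath_is_zero(self):
        assert nernst_potential(1, 5.0, 5.0) == 0.0

    def test_valence_scaling(self):
        e1 = nernst_potential(1, 20.0, 2.0)
        e2 = nernst_potential(2, 20.0, 2.0)
        assert e1 == pytest.approx(2.0 * e2)

    def test_against_rt_over_f_log10_oracle(self):
        expected = 1e3 * GAS_CONSTANT * 310.0 / FARADAY * math.log(10.0)
        assert nernst_potential(1, 10.0, 1.0, T=310.0) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            nernst_potential(1, 0.0, 1.0)
        with pytest.raises(ValueError):
            nernst_potential(1, 1.0, -2.0)

    def test_calcium_reversal_positive_at_defaults(self):
        p = ElectroParameters()
        e_ca = nernst_potential(2, p["Ca_o"] * 1e3, 0.1, p["T"])
        assert e_ca > 0


class TestCurrents:
    def test_zero_driving_force_for_potassium_currents(self):
        p = ElectroParameters()
        e_k = nernst_potential(1, p["K_o"], 130.0, p["T"])
        I = channel_currents([e_k, 0.5, 0.3, 10.0, 130.0, 1.5], p)
        assert I["I_KDr"] == pytest.approx(0.0, abs=1e-9)
        assert I["I_KCa"] == pytest.approx(0.0, abs=1e-9)

    def test_katp_monotone_decreasing_in_atp(self):
        p = ElectroParameters()
        state = list(default_electro_state())
        vals = []
        for atp in (0.05, 0.2, 0.6, 1.5, 4.0):
            state[5] = atp
            vals.append(channel_currents(state, p)["I_KATP"])
        # outward current at V > E_K shrinks monotonically as ATP rises
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_katp_limits(self):
        p = ElectroParameters()
        state = list(default_electro_state())
        state[5] = 1e6
        tiny = channel_currents(state, p)["I_KATP"]
        state[5] = 0.0
        ceiling = channel_currents(state, p)["I_KATP"]
        e_k = nernst_potential(1, p["K_o"], state[4], p["T"])
        assert abs(tiny) < 1e-6 * abs(ceiling)
        assert ceiling == pytest.approx(p["g_KATP"] * (state[0] - e_k), rel=1e-12)

    def test_kca_monotone_increasing_in_ca(self):
        p = ElectroParameters()
        state = list(default_electro_state())
        vals = []
        for ca in (0.05, 0.2, 0.5, 1.0, 3.0):
            state[2] = ca
            vals.append(abs(channel_currents(state, p)["I_KCa"]))
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_formula_level_double_entry_oracle(self):
        # every current re-derived independently at one reference state
        p = ElectroParameters()
        V, n, Ca, Na, K, ATP = -50.0, 0.2, 0.4, 12.0, 128.0, 1.2
        I = channel_currents([V, n, Ca, Na, K, ATP], p)
        RT_F = 1e3 * GAS_CONSTANT * p["T"] / FARADAY
        e_k = RT_F * math.log(p["K_o"] / K)
        e_na = RT_F * math.log(p["Na_o"] / Na)
        e_ca = RT_F / 2 * math.log(p["Ca_o"] * 1e3 / Ca)
        f_atp = ATP / (ATP + p["K_pump_atp"])
        assert I["I_KDr"] == pytest.approx(p["g_KDr"] * n * (V - e_k), rel=1e-12)
        assert I["I_KATP"] == pytest.approx(
            p["g_KATP"] / (1 + (ATP / p["K_katp"]) ** p["h_katp"]) * (V - e_k), rel=1e-12)
        assert I["I_KCa"] == pytest.approx(
            p["g_KCa"] * Ca**4 / (Ca**4 + p["K_KCa"] ** 4) * (V - e_k), rel=1e-12)
        assert I["I_CaV"] == pytest.approx(
            p["g_CaV"]
            / (1 + math.exp((p["V_mca"] - V) / p["S_mca"]))
            / (1 + (Ca / p["K_CaInact"]) ** 2)
            * (V - e_ca), rel=1e-12)
        assert I["I_CaPump"] == pytest.approx(
            f_atp * p["P_CaPump"] * Ca**2 / (Ca**2 + p["K_CaPump"] ** 2), rel=1e-12)
        assert I["I_NaK"] == pytest.approx(
            f_atp * p["P_NaK"] * Na**1.5 / (Na**1.5 + p["K_NaK"] ** 1.5), rel=1e-12)
        assert I["I_NaCa"] == pytest.approx(
            -p["P_NaCa"] * Ca / (Ca + p["K_NaCa"]), rel=1e-12)
        assert I["I_NaAla"] == pytest.approx(p["g_NaAla"] * (V - e_na), rel=1e-12)


class TestNaAlaCurrent:
    def test_zero_conductance_gives_zero(self):
        assert na_ala_current(-60.0, ElectroParameters(), g_NaAla=0.0) == 0.0

    def test_linear_scaling(self):
        p = ElectroParameters()
        i1 = na_ala_current(-60.0, p, g_NaAla=25.0)
        i2 = na_ala_current(-60.0, p, g_NaAla=50.0)
        assert i2 == pytest.approx(2.0 * i1)
        assert i1 < 0  # inward below E_Na

    def test_negative_conductance_rejected(self):
        with pytest.raises(ParameterError):
            na_ala_current(-60.0, ElectroParameters(), g_NaAla=-1.0)


class TestRhs:
    def test_charge_bookkeeping_voltage_equation(self):
        # the V equation carries exactly the nine currents, once each
        p = ElectroParameters()
        p["g_NaAla"] = 30.0
        for state in ([-60.0, 0.1, 0.3, 11.0, 130.0, 1.0],
                      [-20.0, 0.6, 1.5, 20.0, 120.0, 2.5]):
            I = channel_currents(state, p)
            dv = electro_rhs(0.0, state, p)[0]
            assert dv == pytest.approx(-sum(I.values()) / p["C_m"], rel=1e-12)

    def test_dead_membrane_fixed_point(self):
        # all conductances and pumps off, production balancing hydrolysis
        p = ElectroParameters()
        for name in ("g_KDr", "g_KATP", "g_KCa", "g_CaV", "g_NaV", "g_NaAla",
                     "P_CaPump", "P_NaK", "P_NaCa"):
            p[name] = 0.0
        atp = 1.0
        p["k_ATP"] = p["k_hyd"] * atp
        state = [-60.0, 1.0 / (1.0 + math.exp((p["V_n"] + 60.0) / p["S_n"])),
                 0.3, 10.0, 130.0, atp]
        dy = electro_rhs(0.0, state, p)
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_frozen_potassium_mode(self):
        p = ElectroParameters()
        p["dynamic_K"] = 0.0
        dy = electro_rhs(0.0, default_electro_state(), p)
        assert dy[ELECTRO_STATE_NAMES.index("K_i")] == 0.0

    def test_gating_variable_stays_in_unit_interval(self):
        p = ElectroParameters()
        p["k_ATP"] = K_ATP_STIM
        tc = simulate_electro(p, t_end=60000.0)
        assert tc["n"].min() >= 0.0
        assert tc["n"].max() <= 1.0


@pytest.fixture(scope="module")
def stim_run():
    p = ElectroParameters()
    p["k_ATP"] = K_ATP_STIM
    return simulate_electro(p, t_end=480000.0)


@pytest.fixture(scope="module")
def stim_ala_run():
    p = ElectroParameters()
    p["k_ATP"] = K_ATP_STIM
    p["g_NaAla"] = G_NAALA_10MM
    return simulate_electro(p, t_end=480000.0)


def _means(tc, burn_in=0.5):
    t = tc["t"].to_numpy()
    sel = t >= t[0] + burn_in * (t[-1] - t[0])
    tt = t[sel]
    span = tt[-1] - tt[0]
    return {c: float(np.trapezoid(tc[c].to_numpy()[sel], tt) / span)
            for c in tc.columns if c != "t"}


class TestAttractor:
    def test_stimulatory_katp_oscillates(self, stim_run):
        # V and Ca ride the fast burst cycle; the slow Na/K pools need the
        # late, fully stationary window for their small periodic ripple
        for col, burn in (("V", 0.5), ("Ca_i", 0.5), ("Na_i", 0.9), ("K_i", 0.9)):
            s = oscillation_summary(stim_run["t"].to_numpy(),
                                    stim_run[col].to_numpy(), burn_in=burn)
            assert s["oscillatory"], col
        v = oscillation_summary(stim_run["t"].to_numpy(),
                                stim_run["V"].to_numpy(), burn_in=0.5)
        assert v["amplitude"] > 10.0
        assert np.isfinite(v["period"])

    def test_period_stable_under_tolerance_halving(self, stim_run):
        p = ElectroParameters()
        p["k_ATP"] = K_ATP_STIM
        fine = simulate_electro(p, t_end=480000.0, rtol=5e-7)
        per_a = oscillation_summary(stim_run["t"].to_numpy(),
                                    stim_run["V"].to_numpy(), 0.5)["period"]
        per_b = oscillation_summary(fine["t"].to_numpy(),
                                    fine["V"].to_numpy(), 0.5)["period"]
        assert per_b == pytest.approx(per_a, rel=0.05)

    def test_step_increase_in_katp_stimulates(self, stim_run):
        p = ElectroParameters()
        p["k_ATP"] = K_ATP_BASAL
        basal = simulate_electro(p, t_end=240000.0)
        mb, ms = _means(basal), _means(stim_run)
        assert ms["ATP_c"] > mb["ATP_c"]
        assert ms["V"] > mb["V"] - 5.0 or ms["Ca_i"] > mb["Ca_i"]
        assert ms["Ca_i"] > mb["Ca_i"]

    def test_co_transport_shifts_means(self, stim_run, stim_ala_run):
        m0, m1 = _means(stim_run), _means(stim_ala_run)
        assert m1["Na_i"] > m0["Na_i"]
        assert m1["Ca_i"] > m0["Ca_i"]
        assert m1["K_i"] < m0["K_i"]
        assert abs(m1["I_KCa"]) > abs(m0["I_KCa"])

    def test_means_two_quadratures_agree(self, stim_run):
        # trapezoid on solver output vs resampled uniform grid
        t = stim_run["t"].to_numpy()
        sel = t >= t[0] + 0.5 * (t[-1] - t[0])
        tt, ca = t[sel], stim_run["Ca_i"].to_numpy()[sel]
        m_trap = np.trapezoid(ca, tt) / (tt[-1] - tt[0])
        tu = np.linspace(tt[0], tt[-1], 200001)
        m_uni = np.mean(np.interp(tu, tt, ca))
        assert m_uni == pytest.approx(m_trap, rel=1e-3)


class TestMeanStateScan:
    def test_basal_point_near_rest(self):
        tab = mean_state_scan([K_ATP_BASAL], [0.0], t_end=120000.0)
        row = tab.iloc[0]
        assert row["bounded"]
        assert row["mean_Ca_i"] < 0.3
        assert not row["oscillatory"]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            mean_state_scan([], [0.0])
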