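"""Plasma-membrane electrophysiology and Ca²⁺ handling (model 2).

A Hodgkin–Huxley-type current-balance model of the β-cell plasma membrane
driven by metabolism-derived ATP.  Nine currents are carried: delayed
rectifier K⁺, ATP-inhibited K⁺ (K_ATP), Ca²⁺-activated K⁺, voltage-gated
Ca²⁺, plasma-membrane Ca²⁺ pump, a small voltage-gated Na⁺ background,
the Na⁺/K⁺ pump, the Na⁺/Ca²⁺ exchanger, and an ohmic Na⁺ current standing
for electrogenic Na⁺/L-alanine co-transport (conductance ``g_NaAla``).

The endoplasmic-reticulum Ca²⁺ compartment is deliberately absent: the
model tracks a single bulk intracellular Ca²⁺ pool.  Intracellular K⁺ can
be integrated or held constant (``dynamic_K``).

Sign convention: outward current positive; inward currents are negative.
Units: mV, ms, pS, fA, fF; Na⁺/K⁺/ATP in mmol/l; Ca²⁺ in µmol/l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .metabolic import ParameterError

__all__ = [
    "ELECTRO_STATE_NAMES",
    "CURRENT_NAMES",
    "ElectroParameters",
    "nernst_potential",
    "channel_currents",
    "na_ala_current",
    "electro_rhs",
    "default_electro_state",
]

#: Integrated state: membrane potential, K-channel activation, intracellular
#: free Ca²⁺ (µmol/l), Na⁺ and K⁺ (mmol/l), cytosolic ATP (mmol/l).
ELECTRO_STATE_NAMES: Tuple[str, ...] = ("V", "n", "Ca_i", "Na_i", "K_i", "ATP_c")

CURRENT_NAMES: Tuple[str, ...] = (
    "I_KDr", "I_KATP", "I_KCa", "I_CaV", "I_CaPump",
    "I_NaV", "I_NaK", "I_NaCa", "I_NaAla",
)

#: Physical constants (not adjustable).
FARADAY = 96485.0        # C/mol
GAS_CONSTANT = 8.314     # J/(mol·K)

_ELECTRO_TABLE: Tuple[Tuple[str, float, str], ...] = (
    ("C_m",     5310.0, "membrane capacitance (fF)"),
    ("T",        310.0, "absolute temperature (K)"),
    ("Vol_c", 1.15e-12, "cytosolic volume (l)"),
    ("f_i",       0.01, "free fraction of cytosolic Ca²⁺"),
    ("Ca_o",       2.6, "extracellular Ca²⁺ (mmol/l)"),
    ("Na_o",     140.0, "extracellular Na⁺ (mmol/l)"),
    ("K_o",        5.4, "extracellular K⁺ (mmol/l)"),
    # delayed rectifier
    ("g_KDr",   3500.0, "delayed-rectifier K⁺ conductance (pS)"),
    ("V_n",      -16.0, "n-gate half-activation voltage (mV)"),
    ("S_n",        5.6, "n-gate activation slope (mV)"),
    ("tau_n",     20.0, "n-gate relaxation time (ms)"),
    # K_ATP
    ("g_KATP",     24000.0, "max K_ATP conductance (pS)"),
    ("K_katp",     0.15,  "ATP half-inhibition of K_ATP (mmol/l)"),
    ("h_katp",     2.0,  "K_ATP ATP-inhibition Hill exponent"),
    ("K_pump_atp", 0.01, "ATP half-saturation of the ATP-driven pumps (mmol/l)"),
    # K_Ca
    ("g_KCa",    300.0, "Ca²⁺-activated K⁺ conductance (pS)"),
    ("K_KCa",      0.5, "K_Ca half-activation Ca²⁺ (µmol/l)"),
    # voltage-gated Ca²⁺
    ("g_CaV",   1000.0, "voltage-gated Ca²⁺ conductance (pS)"),
    ("V_mca",    -20.0, "Ca channel half-activation voltage (mV)"),
    ("S_mca",     12.0, "Ca channel activation slope (mV)"),
    ("K_CaInact",  2.0, "Ca²⁺-dependent inactivation half-point (µmol/l)"),
    # plasma-membrane Ca²⁺ pump
    ("P_CaPump", 4000.0, "Ca²⁺ pump maximal current (fA)"),
    ("K_CaPump",   0.4,  "Ca²⁺ pump half-saturation (µmol/l)"),
    # background/voltage-gated Na⁺
    ("g_NaV",    250.0, "voltage-gated Na⁺ background conductance (pS)"),
    # Na⁺/K⁺ pump
    ("P_NaK",   6000.0, "Na⁺/K⁺ pump maximal current (fA)"),
    ("K_NaK",     20.0, "pump Na⁺ half-saturation (mmol/l)"),
    # Na⁺/Ca²⁺ exchanger
    ("P_NaCa",  1500.0, "Na⁺/Ca²⁺ exchanger maximal current (fA)"),
    ("K_NaCa",     1.5, "exchanger Ca²⁺ half-saturation (µmol/l)"),
    # Na⁺/L-alanine co-transport
    ("g_NaAla",    0.0, "Na⁺/L-alanine co-transport conductance (pS)"),
    # cytosolic ATP balance
    ("k_ATP",    4.0e-5, "metabolic ATP production rate (mmol/l/ms)"),
    ("k_hyd",    1.0e-4, "basal ATP hydrolysis rate constant (1/ms)"),
    # switches
    ("dynamic_K",  1.0,  "integrate K_i (1) or hold it constant (0)"),
)

_ELECTRO_DEFAULTS = {row[0]: row[1] for row in _ELECTRO_TABLE}
_ELECTRO_DESCRIPTION = {row[0]: row[2] for row in _ELECTRO_TABLE}

#: Basal (unstimulated) ATP production rate, mmol/l/ms.
K_ATP_BASAL = 4.0e-5
#: Stimulatory ATP production rate used for limit-cycle examples.
K_ATP_STIM = 1.8e-4
#: Co-transport conductance standing for 10 mmol/l L-alanine.
G_NAALA_10MM = 50.0


@dataclass
class ElectroParameters:
    """Conductances, pump rates and cell constants of the membrane model."""

    values: Dict[str, float] = field(default_factory=lambda: dict(_ELECTRO_DEFAULTS))

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_ELECTRO_DEFAULTS)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        merged = dict(_ELECTRO_DEFAULTS)
        merged.update(self.values)
        self.values = merged
        self.validate()

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ParameterError(
                f"unknown parameter {name!r}; valid names: {sorted(self.values)}"
            ) from None

    def __setitem__(self, name: str, value: float) -> None:
        if name not in self.values:
            raise ParameterError(
                f"unknown parameter {name!r}; valid names: {sorted(self.values)}"
            )
        self.values[name] = float(value)

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def copy(self) -> "ElectroParameters":
        return ElectroParameters(dict(self.values))

    @staticmethod
    def names() -> Tuple[str, ...]:
        return tuple(_ELECTRO_DEFAULTS)

    @staticmethod
    def describe(name: str) -> str:
        return _ELECTRO_DESCRIPTION[name]

    def validate(self) -> None:
        for name in ("g_KDr", "g_KATP", "g_KCa", "g_CaV", "g_NaV", "g_NaAla",
                     "P_CaPump", "P_NaK", "P_NaCa"):
            if self.values[name] < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("Ca_o", "Na_o", "K_o", "T", "Vol_c", "C_m", "f_i"):
            if not self.values[name] > 0:
                raise ParameterError(f"{name} must be > 0")

    def as_dict(self) -> Dict[str, float]:
        return dict(self.values)


def nernst_potential(z: float, C_out: float, C_in: float, T: float = 310.0) -> float:
    """Equilibrium (Nernst) potential in mV for an ion of valence ``z``.

    ``C_out`` and ``C_in`` must be in the same units and strictly positive.
    """
    if C_out <= 0 or C_in <= 0:
        raise ValueError("concentrations must be strictly positive")
    if z == 0:
        raise ValueError("valence must be nonzero")
    return 1e3 * GAS_CONSTANT * T / (z * FARADAY) * math.log(C_out / C_in)


def na_ala_current(
    V: float,
    params: ElectroParameters,
    g_NaAla: float | None = None,
    Na_i: float = 10.0,
) -> float:
    """Ohmic Na⁺ current of the electrogenic Na⁺/L-alanine co-transport.

    ``I = g_NaAla·(V − E_Na)`` — inward (negative) at physiological
    potentials, linear in the coupling conductance, and zero without
    alanine (``g_NaAla = 0``).
    """
    g = params["g_NaAla"] if g_NaAla is None else g_NaAla
    if g < 0:
        raise ParameterError(f"g_NaAla must be >= 0, got {g}")
    E_Na = nernst_potential(1, params["Na_o"], _na_floor(Na_i), params["T"])
    return g * (V - E_Na)


def _na_floor(x: float) -> float:
    return max(x, 1e-6)


def channel_currents(
    state: Sequence[float],
    params: ElectroParameters,
) -> Dict[str, float]:
    """All nine membrane currents (fA) at one state, outward positive."""
    V, n, Ca_i, Na_i, K_i, ATP_c = (float(x) for x in state)
    p = params
    T = p["T"]
    Ca_i = _na_floor(Ca_i)
    Na_i = _na_floor(Na_i)
    K_i = _na_floor(K_i)
    ATP_c = max(ATP_c, 0.0)

    E_K = nernst_potential(1, p["K_o"], K_i, T)
    E_Na = nernst_potential(1, p["Na_o"], Na_i, T)
    E_Ca = nernst_potential(2, p["Ca_o"] * 1e3, Ca_i, T)  # Ca_i is µmol/l

    # delayed rectifier
    I_KDr = p["g_KDr"] * n * (V - E_K)
    # K_ATP: open probability falls with ATP
    o_katp = 1.0 / (1.0 + (ATP_c / p["K_katp"]) ** p["h_katp"])
    I_KATP = p["g_KATP"] * o_katp * (V - E_K)
    # Ca-activated K
    a_kca = Ca_i ** 4 / (Ca_i ** 4 + p["K_KCa"] ** 4)
    I_KCa = p["g_KCa"] * a_kca * (V - E_K)
    # voltage-gated Ca (instantaneous activation, Ca-dependent inactivation)
    m_inf = 1.0 / (1.0 + math.exp((p["V_mca"] - V) / p["S_mca"]))
    h_ca = 1.0 / (1.0 + (Ca_i / p["K_CaInact"]) ** 2)
    I_CaV = p["g_CaV"] * m_inf * h_ca * (V - E_Ca)
    # ATP-driven pumps stall as cytosolic ATP is depleted
    f_atp = ATP_c / (ATP_c + p["K_pump_atp"])
    # plasma-membrane Ca pump (outward, saturating in Ca_i)
    I_CaPump = f_atp * p["P_CaPump"] * Ca_i ** 2 / (Ca_i ** 2 + p["K_CaPump"] ** 2)
    # small voltage-gated Na background (shallow activation)
    m_na = 1.0 / (1.0 + math.exp((-50.0 - V) / 10.0))
    I_NaV = p["g_NaV"] * m_na * (V - E_Na)
    # Na/K pump: net +1 charge out per cycle (3 Na out, 2 K in)
    f_nak = Na_i ** 1.5 / (Na_i ** 1.5 + p["K_NaK"] ** 1.5)
    I_NaK = f_atp * p["P_NaK"] * f_nak
    # Na/Ca exchanger: forward mode, net +1 charge in per Ca extruded
    I_NaCa = -p["P_NaCa"] * Ca_i / (Ca_i + p["K_NaCa"])
    # Na/L-alanine co-transport (ohmic, inward below E_Na)
    I_NaAla = p["g_NaAla"] * (V - E_Na)

    return {
        "I_KDr": I_KDr, "I_KATP": I_KATP, "I_KCa": I_KCa,
        "I_CaV": I_CaV, "I_CaPump": I_CaPump, "I_NaV": I_NaV,
        "I_NaK": I_NaK, "I_NaCa": I_NaCa, "I_NaAla": I_NaAla,
    }


def electro_rhs(
    t: float,
    state: Sequence[float],
    params: ElectroParameters,
) -> np.ndarray:
    """Time derivative of (V, n, Ca_i, Na_i, K_i, ATP_c).

    Charge bookkeeping: every current appears once in the voltage equation
    and once (scaled by its ion stoichiometry) in the matching ion balance;
    the Na⁺/K⁺ pump moves 3 Na⁺ out / 2 K⁺ in and the exchanger imports
    3 Na⁺ per Ca²⁺ extruded.  The ATP balance is production ``k_ATP``
    minus basal hydrolysis and the ATP consumed by the Na⁺/K⁺ and Ca²⁺
    pumps, so a Na⁺ load directly accelerates ATP consumption.
    """
    V, n, Ca_i, Na_i, K_i, ATP_c = (float(x) for x in state)
    p = params
    I = channel_currents(state, p)

    # fA → mmol/l/ms per unit charge
    conv = 1e-18 / (FARADAY * p["Vol_c"]) * 1e3
    conv_ca = conv * 1e3 / 2.0  # fA → µmol/l/ms for a divalent ion

    dV = -sum(I.values()) / p["C_m"]
    n_inf = 1.0 / (1.0 + math.exp((p["V_n"] - V) / p["S_n"]))
    dn = (n_inf - n) / p["tau_n"]

    dCa = p["f_i"] * (
        -(I["I_CaV"] + I["I_CaPump"]) * conv_ca
        + I["I_NaCa"] * conv * 1e3       # one Ca out per net charge in
    )
    dNa = (
        -(I["I_NaV"] + I["I_NaAla"]) * conv
        - 3.0 * I["I_NaK"] * conv
        - 3.0 * I["I_NaCa"] * conv
    )
    if p["dynamic_K"] != 0.0:
        dK = -(I["I_KDr"] + I["I_KATP"] + I["I_KCa"]) * conv + 2.0 * I["I_NaK"] * conv
    else:
        dK = 0.0
    dATP = (
        p["k_ATP"]
        - p["k_hyd"] * max(ATP_c, 0.0)
        - (I["I_NaK"] + 0.5 * I["I_CaPump"]) * conv
    )
    return np.array([dV, dn, dCa, dNa, dK, dATP])


def default_electro_state() -> np.ndarray:
    """A hyperpolarised resting state used to start simulations."""
    return np.array([-65.0, 0.0, 0.1, 10.0, 132.0, 1.0])


# ---------------------------------------------------------------------------
# Simulation helpers
# ---------------------------------------------------------------------------

def simulate_electro(
    params: "ElectroParameters",
    t_end: float = 60000.0,
    x0: Sequence[float] | None = None,
    rtol: float = 1e-6,
    max_step: float = 50.0,
):
    """Integrate the membrane model and return a tidy time-course table.

    Columns: t (ms), the six state quantities, then the nine currents
    evaluated along the trajectory.  Uses a stiff-capable solver with
    per-variable absolute tolerances matched to each quantity's scale.
    """
    import pandas as pd
    from scipy.integrate import solve_ivp

    if x0 is None:
        x0 = default_electro_state()
    atol = [1e-6, 1e-8, 1e-6, 1e-6, 1e-6, 1e-8]
    sol = solve_ivp(
        lambda t, y: electro_rhs(t, y, params), (0.0, t_end), np.asarray(x0, float),
        method="LSODA", rtol=rtol, atol=atol, max_step=max_step,
    )
    if not sol.success:
        raise RuntimeError(f"membrane integration failed: {sol.message}")
    data = {"t": sol.t}
    for i, nm in enumerate(ELECTRO_STATE_NAMES):
        data[nm] = sol.y[i]
    currents = {nm: np.empty(sol.t.size) for nm in CURRENT_NAMES}
    for j in range(sol.t.size):
        I = channel_currents(sol.y[:, j], params)
        for nm in CURRENT_NAMES:
            currents[nm][j] = I[nm]
    data.update(currents)
    return pd.DataFrame(data)


def mean_state_scan(
    k_ATP_grid: Sequence[float],
    g_NaAla_values: Sequence[float],
    params: "ElectroParameters" | None = None,
    t_end: float = 60000.0,
    burn_in: float = 0.5,
):
    """Time-averaged states and currents over a (k_ATP, g_NaAla) grid.

    Each grid point is integrated past its transient and the post-burn-in
    trapezoidal time means of Ca_i, Na_i, K_i, V, ATP_c and the main
    currents are tabulated.  Rows whose trajectory leaves physical bounds
    (negative concentrations beyond solver noise) are flagged.
    """
    import pandas as pd
    from .scans import oscillation_summary

    if len(k_ATP_grid) == 0 or len(g_NaAla_values) == 0:
        raise ValueError("grids must be non-empty")
    base = params or ElectroParameters()
    rows = []
    for g in g_NaAla_values:
        for k in k_ATP_grid:
            p = base.copy()
            p["k_ATP"] = float(k)
            p["g_NaAla"] = float(g)
            tc = simulate_electro(p, t_end=t_end)
            sel = tc["t"] >= tc["t"].iloc[0] + burn_in * (tc["t"].iloc[-1] - tc["t"].iloc[0])
            tail = tc[sel]
            tt = tail["t"].to_numpy()
            span = tt[-1] - tt[0]
            row = {"k_ATP": float(k), "g_NaAla": float(g)}
            for col in list(ELECTRO_STATE_NAMES) + list(CURRENT_NAMES):
                row[f"mean_{col}"] = float(np.trapezoid(tail[col].to_numpy(), tt) / span)
            vsum = oscillation_summary(tc["t"].to_numpy(), tc["V"].to_numpy(), burn_in=burn_in)
            row["oscillatory"] = bool(vsum["oscillatory"])
            row["V_amplitude"] = float(vsum["amplitude"])
            row["bounded"] = bool(
                np.isfinite(tail[list(ELECTRO_STATE_NAMES)].to_numpy()).all()
                and (tail[["Ca_i", "Na_i", "K_i"]].to_numpy() > -1e-6).all()
            )
            rows.append(row)
    return pd.DataFrame(rows)
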