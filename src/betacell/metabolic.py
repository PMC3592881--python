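"""Core metabolic network of the pancreatic β-cell (model 1).

A single-compartment kinetic model of ATP production from D-glucose and/or
L-alanine: glycolysis, lactate dehydrogenase, a condensed TCA cycle,
alanine/glutamate/aspartate transamination, the respiratory chain, proton
leak and ATP synthase.  The model integrates 18 state quantities — 15
metabolite concentrations, free ATP, free NADH and the mitochondrial
membrane potential ΔΨ_m — with the conserved pairs ADP = A_tot − ATP and
NAD = N_tot − NADH computed algebraically.

Units: concentrations mmol/l, fluxes mmol/l/min, time min, ΔΨ_m mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "STATE_NAMES",
    "REACTION_IDS",
    "MetabolicParameters",
    "ParameterError",
    "StateError",
    "reversible_mass_action_rate",
    "reaction_fluxes",
    "metabolic_rhs",
    "stoichiometry_matrix",
    "default_initial_state",
    "alanine_specific_reactions",
]


class ParameterError(ValueError):
    """Raised for invalid (non-positive, unknown) kinetic parameters."""


class StateError(ValueError):
    """Raised when a state vector violates its physical bounds."""


# ---------------------------------------------------------------------------
# State layout
# ---------------------------------------------------------------------------

#: The 18 integrated state quantities, in canonical order.
STATE_NAMES: Tuple[str, ...] = (
    "GLC", "F6P", "FBP", "GAP", "DPG", "PEP", "PYR", "LAC",
    "AcCoA", "OAA", "CTT", "aKG", "GLU", "ASP", "ALA",
    "ATP", "NADH", "dPsi_m",
)

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: Reaction identifiers 1–24 plus the two nutrient input fluxes.
REACTION_IDS: Tuple[str, ...] = tuple(f"v{i}" for i in range(1, 25)) + (
    "J_GLC", "J_ALA",
)

#: Reactions present only because of L-alanine handling (input flux plus
#: reactions 17–20: alanine dehydrogenase, glutamate dehydrogenase,
#: alanine transaminase, alanine/aspartate transaminase).
ALANINE_REACTIONS: Tuple[str, ...] = ("J_ALA", "v17", "v18", "v19", "v20")


def alanine_specific_reactions() -> Tuple[str, ...]:
    """Reactions added to the glucose-only base network for L-alanine."""
    return ALANINE_REACTIONS


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

# (name, default, adjustable, provenance, description)
_PARAM_TABLE: Tuple[Tuple[str, float, bool, str, str], ...] = (
    ("k1",  0.8,   True,  "base-model default", "glucokinase fwd const (1/(mmol/l·min))"),
    ("k2",  1.0,   True,  "base-model default", "phosphofructokinase fwd const"),
    ("k3",  0.05,  True,  "base-model default", "FBP drain const (1/min)"),
    ("k4",  2.0,   True,  "base-model default", "aldolase fwd const (1/min)"),
    ("k5",  10.0,  True,  "base-model default", "GAPDH fwd const"),
    ("k6",  10.0,  True,  "base-model default", "PGK fwd const"),
    ("k7",  10.0,  True,  "base-model default", "pyruvate kinase fwd const"),
    ("k8",  8.0,   True,  "fitted",             "lactate dehydrogenase fwd const"),
    ("k9",  1.0,   True,  "base-model default", "lactate export const (1/min)"),
    ("k10", 4.0,   True,  "base-model default", "pyruvate dehydrogenase Vmax-like const"),
    ("k11", 8.0,   True,  "base-model default", "citrate synthase Vmax-like const"),
    ("k12", 3.0,   True,  "base-model default", "isocitrate dehydrogenase lump const"),
    ("k13", 3.0,   True,  "base-model default", "aKG dehydrogenase lump const"),
    ("k14", 1.0,   True,  "base-model default", "aspartate transaminase fwd const"),
    ("k15", 0.6,   True,  "base-model default", "pyruvate carboxylase fwd const"),
    ("k16", 0.05,  True,  "base-model default", "OAA drain const (1/min)"),
    ("k17", 0.3,   True,  "base-model default", "alanine dehydrogenase fwd const"),
    ("k18", 1.0,   True,  "base-model default", "glutamate dehydrogenase fwd const"),
    ("k19", 0.8,   True,  "base-model default", "alanine transaminase fwd const"),
    ("k20", 0.3,   True,  "base-model default", "ala/asp transaminase fwd const"),
    ("k21", 2.5,    True,  "fitted",             "ATP translocation/consumption const (1/min)"),
    ("k22", 0.02,  True,  "fitted",             "proton leak const (mmol/l/min per mV)"),
    ("k23", 6.0,   True,  "fitted",             "respiration Vmax (mmol/l/min)"),
    ("k24", 12.0,   True,  "fitted",             "ATP synthase fwd const"),
    ("Keq4",  0.5,  True, "base-model default", "aldolase equilibrium const"),
    ("Keq14", 1.0,  True, "base-model default", "aspartate transaminase equilibrium const"),
    ("Keq17", 0.5,  True, "base-model default", "alanine dehydrogenase equilibrium const"),
    ("Keq18", 20.0, True, "base-model default", "glutamate dehydrogenase equilibrium const"),
    ("Keq19", 1.5,  True, "base-model default", "alanine transaminase equilibrium const"),
    ("Keq20", 1.0,  True, "base-model default", "ala/asp transaminase equilibrium const"),
    ("Keq24", 20.0, True, "base-model default", "ATP synthase equilibrium const"),
    ("K_pdh",  0.5,   True, "base-model default", "PDH pyruvate saturation const (mmol/l)"),
    ("K_pc",   0.3,   True, "base-model default", "pyruvate carboxylase saturation const (mmol/l)"),
    ("K_resp", 0.2,   True, "fitted",             "respiratory NADH saturation const (mmol/l)"),
    ("dPsi_star", 175.0, True, "fitted",          "respiratory cutoff threshold (mV)"),
    ("a_resp",    0.05,   True, "base-model default", "respiratory cutoff steepness (1/mV)"),
    ("dPsi_syn",  120.0, True, "fitted",          "ATP synthase activation midpoint (mV)"),
    ("a_syn",     0.06,  True, "fitted",          "ATP synthase activation steepness (1/mV)"),
    ("A_tot", 4.0, True, "base-model default", "adenine nucleotide pool ATP+ADP (mmol/l)"),
    ("N_tot", 1.0, True, "base-model default", "pyridine nucleotide pool NADH+NAD (mmol/l)"),
    ("C_mito", 1.0, True, "base-model default", "mitochondrial capacitance factor ((mmol/l)/mV)"),
    # held constant, not part of the adjustable registry
    ("Pi",    1.0, False, "base-model default", "inorganic phosphate (mmol/l, constant)"),
    ("J_GLC", 0.0, False, "input",              "D-glucose input flux (mmol/l/min)"),
    ("J_ALA", 0.0, False, "input",              "L-alanine input flux (mmol/l/min)"),
)

_PARAM_DEFAULTS = {row[0]: row[1] for row in _PARAM_TABLE}
_PARAM_ADJUSTABLE = tuple(row[0] for row in _PARAM_TABLE if row[2])
_PARAM_PROVENANCE = {row[0]: row[3] for row in _PARAM_TABLE}
_PARAM_DESCRIPTION = {row[0]: row[4] for row in _PARAM_TABLE}


@dataclass
class MetabolicParameters:
    """Named kinetic parameters of the metabolic network.

    The registry of *adjustable* parameters (rate constants, equilibrium
    constants, saturation constants, respiratory/synthase shape constants
    and the conserved pools) enumerates exactly 41 entries; the inorganic
    phosphate level and the two nutrient input fluxes are held outside it.
    """

    values: Dict[str, float] = field(default_factory=lambda: dict(_PARAM_DEFAULTS))

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_PARAM_DEFAULTS)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        merged = dict(_PARAM_DEFAULTS)
        merged.update(self.values)
        self.values = merged
        self.validate()

    # -- mapping-ish access -------------------------------------------------
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

    def copy(self) -> "MetabolicParameters":
        return MetabolicParameters(dict(self.values))

    def scaled(self, name: str, factor: float) -> "MetabolicParameters":
        """Return a copy with one parameter multiplied by ``factor``."""
        out = self.copy()
        out[name] = out[name] * factor
        return out

    @staticmethod
    def adjustable_names() -> Tuple[str, ...]:
        return _PARAM_ADJUSTABLE

    @staticmethod
    def provenance(name: str) -> str:
        return _PARAM_PROVENANCE[name]

    @staticmethod
    def describe(name: str) -> str:
        return _PARAM_DESCRIPTION[name]

    def validate(self) -> None:
        for name, v in self.values.items():
            if name in ("J_GLC", "J_ALA"):
                if v < 0:
                    raise ParameterError(f"{name} must be >= 0, got {v}")
            elif not v > 0:
                raise ParameterError(f"{name} must be > 0, got {v}")

    def as_dict(self) -> Dict[str, float]:
        return dict(self.values)


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def reversible_mass_action_rate(
    k_f: float,
    K_eq: float,
    reactants: Sequence[float],
    products: Sequence[float],
) -> float:
    """Net reversible mass-action rate ``k_f·(Π reactants − Π products/K_eq)``.

    Positive in the forward direction; exactly zero when the mass-action
    ratio equals the equilibrium constant.
    """
    if k_f < 0:
        raise ParameterError(f"k_f must be >= 0, got {k_f}")
    if not K_eq > 0:
        raise ParameterError(f"K_eq must be > 0, got {K_eq}")
    r = math.prod(reactants) if len(reactants) else 1.0
    p = math.prod(products) if len(products) else 1.0
    return k_f * (r - p / K_eq)


def _check_state(y: np.ndarray, p: MetabolicParameters) -> None:
    if len(y) != len(STATE_NAMES):
        raise StateError(f"expected {len(STATE_NAMES)} state quantities, got {len(y)}")
    if y[_IDX["ATP"]] > p["A_tot"] + 1e-9:
        raise StateError("ATP exceeds the conserved pool A_tot")
    if y[_IDX["NADH"]] > p["N_tot"] + 1e-9:
        raise StateError("NADH exceeds the conserved pool N_tot")


def reaction_fluxes(
    state: Sequence[float],
    params: MetabolicParameters,
    check: bool = True,
) -> np.ndarray:
    """Evaluate all 24 reaction rates plus the two input fluxes.

    Returns a vector aligned with :data:`REACTION_IDS`.  Mass-action and
    Michaelis–Menten laws vanish when their substrates do; reversible
    reactions are evaluated as net rates without clipping.
    """
    y = np.asarray(state, dtype=float)
    p = params
    if check:
        _check_state(y, p)

    GLC, F6P, FBP, GAP, DPG, PEP, PYR, LAC = y[0:8]
    AcCoA, OAA, CTT, aKG, GLU, ASP, ALA = y[8:15]
    ATP, NADH, dPsi = y[15], y[16], y[17]
    ADP = p["A_tot"] - ATP
    NAD = p["N_tot"] - NADH

    v = np.empty(len(REACTION_IDS))
    v[0] = p["k1"] * GLC * ATP                              # 1 glucokinase
    v[1] = p["k2"] * F6P * ATP                              # 2 PFK
    v[2] = p["k3"] * FBP                                    # 3 FBP drain
    v[3] = reversible_mass_action_rate(p["k4"], p["Keq4"], (FBP,), (GAP, GAP))  # 4
    v[4] = p["k5"] * GAP * NAD                              # 5 GAPDH
    v[5] = p["k6"] * DPG * ADP                              # 6 PGK
    v[6] = p["k7"] * PEP * ADP                              # 7 PK
    v[7] = p["k8"] * PYR * NADH                             # 8 LDH
    v[8] = p["k9"] * LAC                                    # 9 lactate export
    v[9] = p["k10"] * NAD * PYR / (p["K_pdh"] + PYR)        # 10 PDH
    v[10] = p["k11"] * OAA * AcCoA                          # 11 citrate synthase
    v[11] = p["k12"] * CTT * NAD                            # 12 IDH lump
    v[12] = p["k13"] * aKG * NAD * ADP                      # 13 aKGDH lump
    v[13] = reversible_mass_action_rate(p["k14"], p["Keq14"], (OAA, GLU), (aKG, ASP))
    v[14] = p["k15"] * ATP * PYR / (p["K_pc"] + PYR)        # 15 pyruvate carboxylase
    v[15] = p["k16"] * OAA                                  # 16 OAA drain
    v[16] = reversible_mass_action_rate(p["k17"], p["Keq17"], (ALA, NAD), (PYR, NADH))
    v[17] = reversible_mass_action_rate(p["k18"], p["Keq18"], (aKG, NADH), (GLU, NAD))
    v[18] = reversible_mass_action_rate(p["k19"], p["Keq19"], (ALA, aKG), (PYR, GLU))
    v[19] = reversible_mass_action_rate(p["k20"], p["Keq20"], (PYR, ASP), (ALA, OAA))
    v[20] = p["k21"] * ATP                                  # 21 ATP translocation/use
    v[21] = p["k22"] * dPsi                                 # 22 proton leak
    # 23 respiration: saturating in NADH, sigmoidal cutoff above dPsi_star
    v[22] = (
        p["k23"]
        * NADH / (p["K_resp"] + NADH)
        / (1.0 + math.exp(p["a_resp"] * (dPsi - p["dPsi_star"])))
    )
    # 24 ATP synthase: reversible in ADP/ATP, activated sigmoidally by dPsi
    v[23] = (
        p["k24"]
        / (1.0 + math.exp(p["a_syn"] * (p["dPsi_syn"] - dPsi)))
        * (ADP * p["Pi"] - ATP / p["Keq24"])
    )
    v[24] = p["J_GLC"]
    v[25] = p["J_ALA"]
    return v


# ---------------------------------------------------------------------------
# Stoichiometry
# ---------------------------------------------------------------------------

# metabolite -> {reaction id: signed coefficient}; dPsi_m handled separately
_STOICH: Dict[str, Dict[str, int]] = {
    "GLC":   {"J_GLC": 1, "v1": -1},
    "F6P":   {"v1": 1, "v2": -1},
    "FBP":   {"v2": 1, "v3": -1, "v4": -1},
    "GAP":   {"v4": 2, "v5": -1},
    "DPG":   {"v5": 1, "v6": -1},
    "PEP":   {"v6": 1, "v7": -1},
    "PYR":   {"v7": 1, "v8": -1, "v10": -1, "v15": -1, "v17": 1, "v19": 1, "v20": -1},
    "LAC":   {"v8": 1, "v9": -1},
    "AcCoA": {"v10": 1, "v11": -1},
    "OAA":   {"v11": -1, "v13": 1, "v14": -1, "v15": 1, "v16": -1, "v20": 1},
    "CTT":   {"v11": 1, "v12": -1},
    "aKG":   {"v12": 1, "v13": -1, "v14": 1, "v18": -1, "v19": -1},
    "GLU":   {"v14": -1, "v18": 1, "v19": 1},
    "ASP":   {"v14": 1, "v20": -1},
    "ALA":   {"J_ALA": 1, "v17": -1, "v19": -1, "v20": 1},
    "ATP":   {"v1": -1, "v2": -1, "v6": 1, "v7": 1, "v13": 1, "v15": -1, "v21": -1, "v24": 1},
    "NADH":  {"v5": 1, "v8": -1, "v10": 1, "v12": 1, "v13": 2, "v17": 1, "v18": -1, "v23": -1},
}

# proton bookkeeping for dPsi_m: 10 H+ pumped out per NADH oxidised
# (reaction 23), 3 H+ re-enter per ATP synthesised (24), leak (22)
_PSI_STOICH: Dict[str, int] = {"v23": 10, "v24": -3, "v22": -1}


def stoichiometry_matrix() -> np.ndarray:
    """Signed stoichiometry S (18 × 26) with the ΔΨ_m row in proton counts."""
    S = np.zeros((len(STATE_NAMES), len(REACTION_IDS)))
    rid = {r: j for j, r in enumerate(REACTION_IDS)}
    for met, entries in _STOICH.items():
        for r, coef in entries.items():
            S[_IDX[met], rid[r]] = coef
    for r, coef in _PSI_STOICH.items():
        S[_IDX["dPsi_m"], rid[r]] = coef
    return S


_S = stoichiometry_matrix()


def metabolic_rhs(
    t: float,
    state: Sequence[float],
    params: MetabolicParameters,
    check: bool = False,
) -> np.ndarray:
    """Time derivative of the 18-component metabolic state, ``S·v``.

    ADP and NAD are computed from the conserved pools, so ATP+ADP and
    NADH+NAD are constant by construction; the ΔΨ_m row is scaled by the
    capacitance factor ``C_mito``.
    """
    v = reaction_fluxes(state, params, check=check)
    dy = _S @ v
    dy[_IDX["dPsi_m"]] /= params["C_mito"]
    return dy


def default_initial_state() -> np.ndarray:
    """A plausible resting state used to seed steady-state searches."""
    y0 = np.zeros(len(STATE_NAMES))
    y0[_IDX["GLC"]] = 0.2
    y0[_IDX["F6P"]] = 0.05
    y0[_IDX["FBP"]] = 0.05
    y0[_IDX["GAP"]] = 0.05
    y0[_IDX["DPG"]] = 0.01
    y0[_IDX["PEP"]] = 0.01
    y0[_IDX["PYR"]] = 0.05
    y0[_IDX["LAC"]] = 0.1
    y0[_IDX["AcCoA"]] = 0.05
    y0[_IDX["OAA"]] = 0.02
    y0[_IDX["CTT"]] = 0.05
    y0[_IDX["aKG"]] = 0.05
    y0[_IDX["GLU"]] = 0.5
    y0[_IDX["ASP"]] = 0.1
    y0[_IDX["ALA"]] = 0.1
    y0[_IDX["ATP"]] = 1.5
    y0[_IDX["NADH"]] = 0.1
    y0[_IDX["dPsi_m"]] = 100.0
    return y0
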