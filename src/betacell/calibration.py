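"""Model calibration: the ATP dose–response fit and the Ca²⁺→insulin
scaling fit.

Two procedures are implemented:

* a bounded least-squares fit of a subset of metabolic rate constants to
  steady-state ATP observations across a stimulus grid (normalised squared
  residuals; the stimulus-free basal observation is excluded because the
  network models nutrient-driven, not basal, ATP turnover), and
* an unconstrained simplex fit of three scaling constants linking the
  membrane model to insulin-secretion observations, under the assumptions
  that (i) insulin secretion is proportional to mean intracellular Ca²⁺,
  (ii) the ATP production constant ``k_ATP`` is linear in glucose or
  alanine concentration, (iii) 10 mmol/l alanine and 16.7 mmol/l glucose
  are equipotent for ``k_ATP``, and (iv) the co-transport conductance
  ``g_NaAla`` is linear in alanine concentration.

Non-metabolizable AIB engages the Na⁺ symport (g_NaAla) without any
metabolic k_ATP contribution; oligomycin and FCCP clamp k_ATP at basal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import minimize

from .metabolic import MetabolicParameters
from .scans import metabolic_steady_state, sensitivity_ranking
from .electro import (
    ElectroParameters,
    simulate_electro,
    K_ATP_BASAL,
)

__all__ = [
    "Condition",
    "ObservationTable",
    "FitResult",
    "CalibrationScales",
    "FluxMap",
    "condition_to_fluxes",
    "condition_to_inputs",
    "atp_objective",
    "fit_atp",
    "default_fitted_subset",
    "MeanCaSurrogate",
    "build_mean_ca_surrogate",
    "insulin_objective",
    "fit_calcium_scaling",
]


# ---------------------------------------------------------------------------
# Conditions and observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """One experimental stimulus: nutrient doses plus analogue/poison flags.

    Doses in mmol/l; ``aib`` is the dose of the non-metabolizable alanine
    analogue (mutually exclusive with alanine), ``oligomycin`` and ``fccp``
    are on/off mitochondrial poisons, ``dmglu`` a membrane-permeant
    glutamate-analogue dose.
    """

    glucose: float = 0.0
    alanine: float = 0.0
    aib: float = 0.0
    oligomycin: bool = False
    fccp: bool = False
    dmglu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("glucose", "alanine", "aib", "dmglu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} dose must be >= 0")
        if self.alanine > 0 and self.aib > 0:
            raise ValueError("alanine and AIB are mutually exclusive in one condition")

    @property
    def is_basal(self) -> bool:
        return (
            self.glucose == 0 and self.alanine == 0 and self.aib == 0
            and self.dmglu == 0 and not self.oligomycin and not self.fccp
        )

    def label(self) -> str:
        parts = []
        if self.glucose:
            parts.append(f"G{self.glucose:g}")
        if self.alanine:
            parts.append(f"A{self.alanine:g}")
        if self.aib:
            parts.append(f"AIB{self.aib:g}")
        if self.dmglu:
            parts.append(f"DMGLU{self.dmglu:g}")
        if self.oligomycin:
            parts.append("oligo")
        if self.fccp:
            parts.append("FCCP")
        return "+".join(parts) if parts else "basal"


@dataclass
class ObservationTable:
    """Per-condition endpoint measurements with their dispersion.

    ``kind`` is ``"ATP"`` (nmol/(mg protein·20 min)) or ``"insulin"``
    (ng/(mg protein·20 min)); model-scale observations are accepted the
    same way since only ratios enter the objectives.
    """

    conditions: List[Condition]
    values: np.ndarray
    sd: np.ndarray
    kind: str = "ATP"
    n_replicates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.kind not in ("ATP", "insulin"):
            raise ValueError("kind must be 'ATP' or 'insulin'")
        if len(self.conditions) != self.values.size or self.values.size != self.sd.size:
            raise ValueError("conditions, values and sd must have equal length")
        if np.any(self.values < 0) or np.any(self.sd < 0):
            raise ValueError("values and sd must be >= 0")
        labels = [c.label() for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("conditions must be unique")

    def __len__(self) -> int:
        return len(self.conditions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition_glucose_mM": [c.glucose for c in self.conditions],
            "condition_alanine_mM": [c.alanine for c in self.conditions],
            "flags": [
                ";".join(
                    f for f in (
                        f"AIB={c.aib:g}" if c.aib else "",
                        "oligomycin" if c.oligomycin else "",
                        "FCCP" if c.fccp else "",
                        f"DMGLU={c.dmglu:g}" if c.dmglu else "",
                    ) if f
                )
                for c in self.conditions
            ],
            "value": self.values,
            "sd": self.sd,
            "n": (self.n_replicates if self.n_replicates is not None
                  else np.full(len(self), 3)),
        })


@dataclass
class FitResult:
    """Fitted parameters, objective trace and convergence diagnostics."""

    params: Dict[str, float]
    objective: float
    trace: List[float]
    converged: bool
    bounds: Optional[Dict[str, Tuple[float, float]]] = None
    message: str = ""
    at_bounds: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trace and self.objective > self.trace[0] + 1e-12:
            raise ValueError("final objective exceeds initial objective")


# ---------------------------------------------------------------------------
# Condition → model-input maps
# ---------------------------------------------------------------------------

@dataclass
class FluxMap:
    """Linear map from stimulus concentrations to metabolic input fluxes.

    The uptake–concentration relationship is treated as linear (uptake
    assays are quasi-linear over the tested range); slopes are in
    (mmol/l/min) per (mmol/l).  The alanine slope is set so that 10 mmol/l
    alanine alone yields a steady-state ATP comparable to 16.7 mmol/l
    glucose, matching the experimental equivalence.
    """

    glc_slope: float = 0.0133
    ala_slope: float = 0.047

    def __call__(self, c: Condition) -> Tuple[float, float]:
        return condition_to_fluxes(c, self)


def condition_to_fluxes(c: Condition, fmap: Optional[FluxMap] = None) -> Tuple[float, float]:
    """(J_GLC, J_ALA) for the metabolic network.  AIB carries no flux."""
    fmap = fmap or FluxMap()
    return fmap.glc_slope * c.glucose, fmap.ala_slope * c.alanine


@dataclass
class CalibrationScales:
    """The three fitted scaling constants of the Ca²⁺→insulin validation,
    plus the basal ATP production floor.

    * ``insulin_per_ca`` — insulin secretion per unit mean Ca²⁺ (model
      insulin units per µmol/l);
    * ``glc_to_katp`` — k_ATP increment per mmol/l D-glucose (mmol/l/ms
      per mmol/l); the alanine k_ATP slope is tied to it by the
      10 mmol/l-alanine ≡ 16.7 mmol/l-glucose equivalence;
    * ``ala_to_gnaala`` — co-transport conductance per mmol/l L-alanine
      (pS per mmol/l).
    """

    insulin_per_ca: float = 25.0
    glc_to_katp: float = 6.0e-6
    ala_to_gnaala: float = 5.0
    k_atp_basal: float = K_ATP_BASAL

    #: glucose concentration equipotent with 10 mmol/l alanine
    GLC_EQUIV: float = 16.7
    ALA_EQUIV: float = 10.0

    @property
    def ala_to_katp(self) -> float:
        return self.glc_to_katp * self.GLC_EQUIV / self.ALA_EQUIV


def condition_to_inputs(
    c: Condition,
    scales: Optional[CalibrationScales] = None,
) -> Tuple[float, float]:
    """(k_ATP, g_NaAla) for the membrane model under one condition.

    k_ATP rises linearly with glucose or alanine (or the permeant DMGLU,
    mapped with the glucose slope); AIB adds conductance but no k_ATP;
    oligomycin/FCCP clamp k_ATP to its basal floor.
    """
    s = scales or CalibrationScales()
    if c.oligomycin or c.fccp:
        k_atp = s.k_atp_basal
    else:
        k_atp = (
            s.k_atp_basal
            + s.glc_to_katp * (c.glucose + c.dmglu)
            + s.ala_to_katp * c.alanine
        )
    g_na_ala = s.ala_to_gnaala * (c.alanine + c.aib)
    return k_atp, g_na_ala


# ---------------------------------------------------------------------------
# ATP dose–response fit
# ---------------------------------------------------------------------------

def _steady_atp(
    params: MetabolicParameters,
    c: Condition,
    fmap: FluxMap,
    tol: float = 1e-8,
) -> float:
    p = params.copy()
    p["J_GLC"], p["J_ALA"] = condition_to_fluxes(c, fmap)
    res = metabolic_steady_state(p, tol=tol)
    if not res.converged:
        raise RuntimeError(f"no steady state at condition {c.label()}")
    return float(res.as_series()["ATP"])


def atp_objective(
    theta: Mapping[str, float],
    obs: ObservationTable,
    params: Optional[MetabolicParameters] = None,
    fmap: Optional[FluxMap] = None,
    normalize_by: str = "value",
    include_basal: bool = False,
    nonconverged_penalty: Optional[float] = None,
) -> float:
    """Sum of squared normalised ATP residuals over the stimulus conditions.

    For each non-basal condition the metabolic network (with the fitted
    subset ``theta`` applied) is driven to steady state at the condition's
    input fluxes and compared with the observed value:
    ``Σ ((sim − obs)/obs)²``.  The stimulus-free basal observation is
    skipped unless ``include_basal``.  If an observation is zero,
    normalisation falls back to its SD (``normalize_by='sd'`` forces
    SD-normalisation throughout).

    Some parameter combinations put the network on a glycolytic-type
    limit cycle where no steady state exists; by default that raises, but
    ``nonconverged_penalty`` substitutes a large objective value so a
    bounded optimiser can steer away from the oscillatory region.
    """
    if obs.kind != "ATP":
        raise ValueError("atp_objective expects an ATP observation table")
    base = (params or MetabolicParameters()).copy()
    for name, val in theta.items():
        base[name] = val
    fmap = fmap or FluxMap()
    total = 0.0
    for c, y, sd in zip(obs.conditions, obs.values, obs.sd):
        if c.is_basal and not include_basal:
            continue
        try:
            sim = _steady_atp(base, c, fmap)
        except RuntimeError:
            if nonconverged_penalty is None:
                raise
            total += nonconverged_penalty
            continue
        if normalize_by == "sd" or y == 0:
            denom = sd if sd > 0 else 1.0
        else:
            denom = y
        total += ((sim - y) / denom) ** 2
    return total


_DEFAULT_SUBSET_CACHE: Optional[List[str]] = None


def default_fitted_subset(
    n: int = 10,
    glucose_grid: Sequence[float] = (0.05, 0.15, 0.3),
    params: Optional[MetabolicParameters] = None,
) -> List[str]:
    """The ``n`` parameters whose scaling most displaces the ATP curve.

    Computed from a one-at-a-time sensitivity ranking (factors ½ and 2)
    over a compact glucose-influx grid; cached after the first call.
    """
    global _DEFAULT_SUBSET_CACHE
    if _DEFAULT_SUBSET_CACHE is None or len(_DEFAULT_SUBSET_CACHE) < n:
        tab = sensitivity_ranking(glucose_grid, params=params)
        _DEFAULT_SUBSET_CACHE = tab["param"].tolist()
    return _DEFAULT_SUBSET_CACHE[:n]


def fit_atp(
    obs: ObservationTable,
    theta0: Mapping[str, float],
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    params: Optional[MetabolicParameters] = None,
    fmap: Optional[FluxMap] = None,
    bound_factors: Tuple[float, float] = (0.2, 5.0),
    normalize_by: str = "value",
    maxiter: int = 60,
) -> FitResult:
    """Bounded local minimisation of :func:`atp_objective`.

    ``theta0`` names the fitted subset and its start values; default box
    bounds are ×0.2–×5 of the start values.  Deterministic given the
    start point.  Optimiser failures return ``converged=False`` with the
    last iterate rather than raising.
    """
    names = list(theta0)
    x0 = np.array([theta0[k] for k in names], dtype=float)
    if bounds is None:
        bounds = {k: (bound_factors[0] * theta0[k], bound_factors[1] * theta0[k])
                  for k in names}
    box = [bounds[k] for k in names]
    trace: List[float] = []

    def f(x: np.ndarray) -> float:
        val = atp_objective(dict(zip(names, x)), obs, params=params, fmap=fmap,
                            normalize_by=normalize_by, nonconverged_penalty=1e6)
        if not trace or val < trace[-1]:
            trace.append(val)
        return val

    res = minimize(f, x0, method="L-BFGS-B", bounds=box,
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10})
    best = dict(zip(names, res.x))
    at_bounds = [
        k for k in names
        if np.isclose(best[k], bounds[k][0], rtol=1e-6)
        or np.isclose(best[k], bounds[k][1], rtol=1e-6)
    ]
    return FitResult(
        params=best, objective=float(res.fun),
        trace=trace if trace else [float(res.fun)],
        converged=bool(res.success), bounds=dict(bounds),
        message=str(res.message), at_bounds=at_bounds,
    )


# ---------------------------------------------------------------------------
# Mean-Ca²⁺ response surface and the insulin scaling fit
# ---------------------------------------------------------------------------

class MeanCaSurrogate:
    """Bilinear interpolant of mean limit-cycle Ca²⁺ over (k_ATP, g_NaAla).

    The membrane model is integrated on a rectangular grid of inputs and
    the post-burn-in time-mean of Ca_i is tabulated once; subsequent
    calibration evaluates the interpolated surface, which keeps the
    simplex fit and the seeded recovery study inexpensive while remaining
    fully deterministic.
    """

    def __init__(self, k_grid: np.ndarray, g_grid: np.ndarray, ca_means: np.ndarray):
        self.k_grid = np.asarray(k_grid, dtype=float)
        self.g_grid = np.asarray(g_grid, dtype=float)
        self.ca_means = np.asarray(ca_means, dtype=float)
        self._interp = RegularGridInterpolator(
            (self.k_grid, self.g_grid), self.ca_means,
            bounds_error=False, fill_value=None,
        )

    def __call__(self, k_atp: float, g_na_ala: float) -> float:
        # linear extrapolation outside the tabulated rectangle keeps the
        # objective curved there, so scaling constants stay identifiable
        return float(self._interp((float(k_atp), float(g_na_ala))))


def _mean_ca_direct(
    k_atp: float,
    g_na_ala: float,
    params: Optional[ElectroParameters] = None,
    t_end: float = 240000.0,
    burn_in: float = 0.5,
) -> float:
    p = (params or ElectroParameters()).copy()
    p["k_ATP"] = float(k_atp)
    p["g_NaAla"] = float(g_na_ala)
    tc = simulate_electro(p, t_end=t_end)
    t = tc["t"].to_numpy()
    sel = t >= t[0] + burn_in * (t[-1] - t[0])
    tt = t[sel]
    return float(np.trapezoid(tc["Ca_i"].to_numpy()[sel], tt) / (tt[-1] - tt[0]))


def build_mean_ca_surrogate(
    k_grid: Sequence[float] = (4e-5, 7e-5, 1.0e-4, 1.4e-4, 1.8e-4, 2.2e-4, 2.6e-4, 3.0e-4),
    g_grid: Sequence[float] = (0.0, 12.5, 25.0, 37.5, 50.0),
    params: Optional[ElectroParameters] = None,
    t_end: float = 240000.0,
    burn_in: float = 0.5,
) -> MeanCaSurrogate:
    """Tabulate mean Ca²⁺ on an input grid and wrap it as a surrogate."""
    k_grid = np.asarray(k_grid, dtype=float)
    g_grid = np.asarray(g_grid, dtype=float)
    ca = np.empty((k_grid.size, g_grid.size))
    for i, k in enumerate(k_grid):
        for j, g in enumerate(g_grid):
            ca[i, j] = _mean_ca_direct(k, g, params=params, t_end=t_end, burn_in=burn_in)
    return MeanCaSurrogate(k_grid, g_grid, ca)


def insulin_objective(
    scales: CalibrationScales,
    obs: ObservationTable,
    mean_ca: Callable[[float, float], float],
) -> float:
    """Squared-difference objective between observed insulin and scaled
    mean Ca²⁺ at each condition's mapped (k_ATP, g_NaAla) inputs."""
    total = 0.0
    for c, y in zip(obs.conditions, obs.values):
        k_atp, g = condition_to_inputs(c, scales)
        total += (y - scales.insulin_per_ca * mean_ca(k_atp, g)) ** 2
    return total


def _check_insulin_design(obs: ObservationTable) -> None:
    basal = [c for c in obs.conditions if c.is_basal]
    glc = [c for c in obs.conditions if c.glucose > 0 and c.alanine == 0 and c.aib == 0]
    ala = [c for c in obs.conditions if c.alanine > 0 and c.glucose == 0]
    if len(basal) != 1:
        raise ValueError("insulin design needs exactly 1 stimulus-free condition")
    if len(glc) < 5:
        raise ValueError("insulin design needs 5 glucose-only conditions")
    if len(ala) < 5:
        raise ValueError("insulin design needs 5 alanine-only conditions")


def fit_calcium_scaling(
    obs: ObservationTable,
    mean_ca: Callable[[float, float], float],
    scales0: Optional[CalibrationScales] = None,
    maxiter: int = 400,
) -> FitResult:
    """Simplex (Nelder–Mead) fit of the three scaling constants.

    ``obs`` must contain 1 stimulus-free, ≥5 glucose-only and ≥5
    alanine-only insulin observations.  ``mean_ca`` maps (k_ATP, g_NaAla)
    to mean limit-cycle Ca²⁺ (either direct simulation or a
    :class:`MeanCaSurrogate`).  Optimisation is over the logarithms of the
    three positive constants, unconstrained, deterministic.
    """
    if obs.kind != "insulin":
        raise ValueError("fit_calcium_scaling expects an insulin observation table")
    _check_insulin_design(obs)
    s0 = scales0 or CalibrationScales()
    x0 = np.log([s0.insulin_per_ca, s0.glc_to_katp, s0.ala_to_gnaala])
    trace: List[float] = []

    def f(x: np.ndarray) -> float:
        s = replace(s0, insulin_per_ca=float(np.exp(x[0])),
                    glc_to_katp=float(np.exp(x[1])),
                    ala_to_gnaala=float(np.exp(x[2])))
        val = insulin_objective(s, obs, mean_ca)
        if not trace or val < trace[-1]:
            trace.append(val)
        return val

    res = minimize(f, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-12})
    best = replace(s0, insulin_per_ca=float(np.exp(res.x[0])),
                   glc_to_katp=float(np.exp(res.x[1])),
                   ala_to_gnaala=float(np.exp(res.x[2])))
    return FitResult(
        params={
            "insulin_per_ca": best.insulin_per_ca,
            "glc_to_katp": best.glc_to_katp,
            "ala_to_gnaala": best.ala_to_gnaala,
        },
        objective=float(res.fun),
        trace=trace if trace else [float(res.fun)],
        converged=bool(res.success),
        message=str(res.message),
    )
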