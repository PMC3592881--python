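"""Steady-state search, dose–response scans, sensitivity scans and
limit-cycle summaries.

All scans are deterministic: the same parameters and grids reproduce the
same tables bit for bit.  Steady states are located by long stiff
integration until the scaled residual of the right-hand side falls below a
tolerance, optionally polished with a Newton-type root solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .metabolic import (
    STATE_NAMES,
    REACTION_IDS,
    MetabolicParameters,
    ParameterError,
    metabolic_rhs,
    reaction_fluxes,
    default_initial_state,
)

__all__ = [
    "SteadyStateResult",
    "find_steady_state",
    "metabolic_steady_state",
    "dose_response_scan",
    "sensitivity_scan",
    "oscillation_summary",
    "DEFAULT_SENSITIVITY_FACTORS",
]

#: One-at-a-time sensitivity multipliers, symmetric about 1 on a log scale.
DEFAULT_SENSITIVITY_FACTORS: Tuple[float, ...] = (0.2, 0.5, 2.0, 5.0)


@dataclass
class SteadyStateResult:
    """Outcome of a steady-state search."""

    state: np.ndarray
    residual: float
    converged: bool
    t_used: float
    fluxes: Optional[np.ndarray] = None

    def as_series(self, names: Sequence[str] = STATE_NAMES) -> pd.Series:
        return pd.Series(self.state, index=list(names))


def _scaled_residual(dy: np.ndarray, y: np.ndarray) -> float:
    return float(np.max(np.abs(dy) / np.maximum(1.0, np.abs(y))))


def find_steady_state(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    x0: Sequence[float],
    tol: float = 1e-8,
    t_max: float = 2.0e4,
    t_chunk: float = 500.0,
    polish: bool = True,
    method: str = "LSODA",
) -> SteadyStateResult:
    """Integrate ``rhs`` until the scaled residual drops below ``tol``.

    The residual is max_i |dy_i| / max(1, |y_i|).  Integration proceeds in
    chunks up to ``t_max``; on timeout the result is returned with
    ``converged=False`` rather than raising.  With ``polish=True`` a final
    Newton root solve refines the fixed point (and is discarded if it
    wanders away from the integrated state or goes negative where the
    integrated state was non-negative).
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    y = np.asarray(x0, dtype=float).copy()
    t = 0.0
    residual = _scaled_residual(rhs(0.0, y), y)
    while residual > tol and t < t_max:
        span = min(t_chunk, t_max - t)
        sol = solve_ivp(
            rhs, (t, t + span), y, method=method,
            rtol=1e-9, atol=1e-10, dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"steady-state integration failed: {sol.message}")
        y = sol.y[:, -1]
        t = sol.t[-1]
        residual = _scaled_residual(rhs(t, y), y)
    converged = residual <= tol
    if converged and polish:
        res = root(lambda z: rhs(0.0, z), y, method="hybr", tol=1e-12)
        if res.success:
            z = res.x
            close = np.allclose(z, y, rtol=1e-3, atol=1e-6)
            sign_ok = not np.any((z < -1e-9) & (y >= -1e-9))
            if close and sign_ok:
                r2 = _scaled_residual(rhs(0.0, z), z)
                if r2 < residual:
                    y, residual = z, r2
    return SteadyStateResult(state=y, residual=residual, converged=converged, t_used=t)


def metabolic_steady_state(
    params: MetabolicParameters,
    x0: Optional[Sequence[float]] = None,
    tol: float = 1e-8,
    t_max: float = 2.0e4,
    polish: bool = True,
) -> SteadyStateResult:
    """Steady state of the metabolic network at its configured input fluxes."""
    if x0 is None:
        x0 = default_initial_state()
    res = find_steady_state(
        lambda t, y: metabolic_rhs(t, y, params), x0,
        tol=tol, t_max=t_max, polish=polish,
    )
    res.fluxes = reaction_fluxes(res.state, params, check=False)
    return res


# ---------------------------------------------------------------------------
# Dose–response scans
# ---------------------------------------------------------------------------

def dose_response_scan(
    varied: str,
    grid: Sequence[float],
    params: Optional[MetabolicParameters] = None,
    fixed: Optional[Dict[str, float]] = None,
    outputs: Sequence[str] = ("ATP", "LAC", "GLU", "CTT", "NADH", "dPsi_m"),
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Steady-state outputs along a grid of one input flux.

    ``varied`` is ``"J_GLC"`` or ``"J_ALA"``; ``fixed`` may pin the other
    input.  Each successive point is warm-started from the previous steady
    state.  Non-converged points are flagged in the ``converged`` column
    and the scan continues.
    """
    if varied not in ("J_GLC", "J_ALA"):
        raise ParameterError(f"varied must be J_GLC or J_ALA, got {varied!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    p = (params or MetabolicParameters()).copy()
    for key, val in (fixed or {}).items():
        p[key] = val

    rows: List[Dict[str, float]] = []
    x0 = default_initial_state()
    for j in grid:
        p[varied] = float(j)
        res = metabolic_steady_state(p, x0=x0, tol=tol)
        row: Dict[str, float] = {varied: float(j), "converged": bool(res.converged)}
        s = res.as_series()
        for name in outputs:
            row[name] = float(s[name])
        rows.append(row)
        if res.converged:
            x0 = res.state
    return pd.DataFrame(rows)


def sensitivity_scan(
    param: str,
    glucose_grid: Sequence[float],
    factors: Sequence[float] = DEFAULT_SENSITIVITY_FACTORS,
    params: Optional[MetabolicParameters] = None,
    fixed: Optional[Dict[str, float]] = None,
    output: str = "ATP",
    tol: float = 1e-8,
) -> pd.DataFrame:
    """One-at-a-time sensitivity: the steady-state ``output`` vs glucose
    influx curve, recomputed with ``param`` scaled by each factor.

    A factor of 1 reproduces the baseline curve exactly.  Returns a long
    table with columns (factor, J_GLC, value, converged).
    """
    base = params or MetabolicParameters()
    if param not in base:
        raise ParameterError(
            f"unknown parameter {param!r}; valid names: "
            f"{sorted(base.adjustable_names())}"
        )
    if any(f <= 0 for f in factors):
        raise ParameterError("sensitivity factors must be positive")
    frames = []
    for f in factors:
        p = base.scaled(param, f)
        tab = dose_response_scan(
            "J_GLC", glucose_grid, params=p, fixed=fixed,
            outputs=(output,), tol=tol,
        )
        tab.insert(0, "factor", f)
        tab = tab.rename(columns={output: "value"})
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def sensitivity_ranking(
    glucose_grid: Sequence[float],
    names: Optional[Sequence[str]] = None,
    factors: Sequence[float] = (0.5, 2.0),
    params: Optional[MetabolicParameters] = None,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Rank parameters by how much scaling them displaces the ATP curve.

    Displacement is the mean absolute log-ratio between the scaled and
    baseline steady-state ATP curves, averaged over the factors.  Used to
    choose the default fitted subset for calibration.
    """
    base_params = params or MetabolicParameters()
    names = list(names) if names is not None else list(base_params.adjustable_names())
    baseline = dose_response_scan(
        "J_GLC", glucose_grid, params=base_params, outputs=("ATP",), tol=tol
    )["ATP"].to_numpy()
    records = []
    for name in names:
        disp = 0.0
        for f in factors:
            tab = dose_response_scan(
                "J_GLC", glucose_grid, params=base_params.scaled(name, f),
                outputs=("ATP",), tol=tol,
            )
            curve = tab["ATP"].to_numpy()
            disp += float(np.mean(np.abs(np.log(
                np.maximum(curve, 1e-12) / np.maximum(baseline, 1e-12)
            ))))
        records.append({"param": name, "displacement": disp / len(factors)})
    out = pd.DataFrame(records).sort_values(
        "displacement", ascending=False, ignore_index=True
    )
    return out


# ---------------------------------------------------------------------------
# Limit-cycle summaries
# ---------------------------------------------------------------------------

def oscillation_summary(
    t: Sequence[float],
    x: Sequence[float],
    burn_in: float = 0.5,
    min_prominence_frac: float = 0.05,
) -> Dict[str, float]:
    """Time-mean, peak, trough and dominant period of one trajectory.

    The first ``burn_in`` fraction of the time window is discarded.  The
    mean is the trapezoidal time average (robust to non-uniform solver
    output).  Periodicity is detected on a linearly detrended copy of the
    window, so slowly relaxing observables (ion pools approaching their
    stationary mean) still expose their per-cycle ripple; peaks need a
    prominence of at least ``min_prominence_frac`` of the detrended range
    and that range must be resolvable above solver noise.  With fewer
    than two peaks the signal is treated as non-oscillatory (period NaN).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 3:
        raise ValueError("trajectory too short")
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in must be in [0, 1)")
    t0 = t[0] + burn_in * (t[-1] - t[0])
    sel = t >= t0
    tt, xx = t[sel], x[sel]
    mean = float(np.trapezoid(xx, tt) / (tt[-1] - tt[0]))
    rng = float(xx.max() - xx.min())
    if rng <= 0:
        return {
            "mean": mean, "peak": float(xx.max()), "trough": float(xx.min()),
            "period": float("nan"), "amplitude": 0.0, "oscillatory": False,
        }
    slope, intercept = np.polyfit(tt, xx, 1)
    resid = xx - (slope * tt + intercept)
    rng_det = float(resid.max() - resid.min())
    noise_floor = 1e-6 * (1.0 + abs(mean))
    if rng_det <= noise_floor:
        peaks = np.array([], dtype=int)
    else:
        peaks, _ = find_peaks(resid, prominence=min_prominence_frac * rng_det)
    oscillatory = len(peaks) >= 2
    period = float(np.mean(np.diff(tt[peaks]))) if oscillatory else float("nan")
    return {
        "mean": mean,
        "peak": float(xx.max()),
        "trough": float(xx.min()),
        "period": period,
        "amplitude": rng,
        "oscillatory": bool(oscillatory),
    }
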