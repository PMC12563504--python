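"""Kinetic model of the presynaptic serotonin cycle.

Eight coupled ODEs track a dietary tryptophan pulse through synthesis,
vesicular packaging, release, reuptake and degradation:

    trp_ext --k_up--> trp_in --TPH2--> 5-HTP --AADC--> fc5-HT
    fc5-HT --VMAT--> v5-HT --k_rel--> e5-HT --SERT--> fc5-HT
    fc5-HT --MAOA--> 5-HIAA --k_hiaa--> (cleared)
    e5-HT --k_eloss--> (cleared)

TPH2, SERT and MAOA follow Michaelis--Menten kinetics with genotype-scaled
Vmax (protein abundance tracks mRNA fold-change; Km is a property of the
enzyme and is never scaled).  AADC conversion, vesicular release and the
two clearance routes are first order.  5-HIAA removal (``k_hiaa``) is the
same for every individual in a run: between-individual differences in the
5-HIAA time course reflect synthesis and degradation capacity, not removal.

The eighth state, ``cleared``, accumulates everything leaving the system so
that total material is conserved exactly — the basis of the mass-balance
audit used throughout the test-suite.

All concentrations are in μM and time in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .variants import ActivityCoefficients

__all__ = [
    "KineticParameters",
    "Trajectory",
    "STATE_NAMES",
    "SPECIES",
    "derivatives",
    "simulate",
    "mass_balance",
    "steady_state",
    "plot_trajectory",
]

#: The eight state variables, in integration order.
STATE_NAMES = ("trp_ext", "trp_in", "htp", "fc5ht", "v5ht", "e5ht", "hiaa", "cleared")

#: The five reported molecular species (subset of the state).
SPECIES = ("htp", "fc5ht", "v5ht", "e5ht", "hiaa")

@dataclass(frozen=True)
class KineticParameters:
    """Rate constants, input regimen and solver settings.

    Units: Vmax in μM/min, Km in μM, first-order rates in 1/min, times in
    minutes.  ``input_mode`` selects a single dietary tryptophan pulse
    (``trp_ext0`` μM decaying at ``k_up``) or a constant intracellular
    infusion at ``infusion_rate`` μM/min (used by the analytic steady-state
    oracle).
    """

    trp_ext0: float = 100.0
    k_up: float = 0.1
    vmax_tph2: float = 1.0
    km_tph2: float = 40.0
    k_aadc: float = 0.01
    vmax_vmat: float = 1.0
    km_vmat: float = 0.3
    k_rel: float = 0.2
    vmax_sert: float = 0.5
    km_sert: float = 0.2
    k_eloss: float = 4.0
    vmax_maoa: float = 0.15
    km_maoa: float = 1.0
    k_hiaa: float = 0.0005
    t_end: float = 600.0
    dt_sample: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10
    input_mode: str = "pulse"  # or "infusion"
    infusion_rate: float = 0.02

    def __post_init__(self) -> None:
        positive = (
            "k_up vmax_tph2 km_tph2 k_aadc vmax_vmat km_vmat k_rel vmax_sert "
            "km_sert vmax_maoa km_maoa k_hiaa t_end dt_sample rtol atol"
        ).split()
        for name in positive:
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.trp_ext0 < 0 or self.infusion_rate < 0:
            raise ValueError("inputs must be non-negative")
        if self.t_end / self.dt_sample < 10:
            raise ValueError("t_end/dt_sample must be at least 10")
        if self.input_mode not in ("pulse", "infusion"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt_sample))
        return np.linspace(0.0, n * self.dt_sample, n + 1)


@dataclass
class Trajectory:
    """Sampled concentration time courses for one individual."""

    times: np.ndarray
    series: Mapping[str, np.ndarray]  # the five reported species
    full_state: Mapping[str, np.ndarray] | None = None  # all eight states
    clipped: int = 0  # solver-noise values clipped to zero

    def __post_init__(self) -> None:
        for name, x in self.series.items():
            if len(x) != len(self.times):
                raise ValueError(f"series {name!r} length mismatch with time grid")


def _fluxes(y: np.ndarray, p: KineticParameters, c: ActivityCoefficients):
    trp_in, htp, fc, v, e = y[1], y[2], y[3], y[4], y[5]
    f_t = c.c_tph2 * p.vmax_tph2 * trp_in / (p.km_tph2 + trp_in)
    f_v = p.vmax_vmat * fc / (p.km_vmat + fc)
    f_s = c.c_sert * p.vmax_sert * e / (p.km_sert + e)
    f_m = c.c_maoa * p.vmax_maoa * fc / (p.km_maoa + fc)
    return f_t, f_v, f_s, f_m, htp, v, e


def derivatives(
    state: np.ndarray,
    t: float,
    params: KineticParameters,
    coeffs: ActivityCoefficients,
) -> np.ndarray:
    """Right-hand side of the eight-state system (μM/min).

    State order follows :data:`STATE_NAMES`.  In infusion mode the external
    pool is bypassed and tryptophan enters ``trp_in`` at a constant rate.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (8,):
        raise ValueError("state must have exactly eight components")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state component")
    f_t, f_v, f_s, f_m, htp, v, e = _fluxes(y, params, coeffs)
    hiaa = y[6]
    dy = np.empty(8)
    if params.input_mode == "pulse":
        dy[0] = -params.k_up * y[0]
        dy[1] = params.k_up * y[0] - f_t
    else:
        dy[0] = 0.0
        dy[1] = params.infusion_rate - f_t
    dy[2] = f_t - params.k_aadc * htp
    dy[3] = params.k_aadc * htp + f_s - f_v - f_m
    dy[4] = f_v - params.k_rel * v
    dy[5] = params.k_rel * v - f_s - params.k_eloss * e
    dy[6] = f_m - params.k_hiaa * hiaa
    dy[7] = params.k_eloss * e + params.k_hiaa * hiaa
    return dy


def simulate(
    coeffs: ActivityCoefficients,
    params: KineticParameters | None = None,
    keep_full_state: bool = True,
) -> Trajectory:
    """Integrate the model and sample it on the uniform output grid.

    Uses an adaptive stiff-capable solver (LSODA) at the configured
    tolerances.  Negative values within the solver noise floor
    (max(1e−12, 100·atol) μM) are clipped to zero and counted in
    ``Trajectory.clipped``; anything more negative raises, since it
    indicates genuine integration failure.
    """
    p = params if params is not None else KineticParameters()
    grid = p.time_grid()
    y0 = np.zeros(8)
    if p.input_mode == "pulse":
        y0[0] = p.trp_ext0
    sol = solve_ivp(
        lambda t, y: derivatives(y, t, p, coeffs),
        (grid[0], grid[-1]),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=p.rtol,
        atol=p.atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    y = sol.y  # (8, n_times)
    negative = y < 0
    # anything within ~100x the absolute tolerance is solver noise, not mass
    noise_floor = max(1e-12, 100.0 * p.atol)
    if np.any(y < -noise_floor):
        worst = float(y.min())
        raise RuntimeError(f"negative concentration beyond noise floor: {worst} μM")
    clipped = int(np.count_nonzero(negative))
    y = np.where(negative, 0.0, y)
    full = {name: y[i].copy() for i, name in enumerate(STATE_NAMES)}
    series = {name: full[name] for name in SPECIES}
    return Trajectory(
        times=grid,
        series=series,
        full_state=full if keep_full_state else None,
        clipped=clipped,
    )


def mass_balance(trajectory: Trajectory, params: KineticParameters) -> float:
    """Maximum relative drift of total material over the sampled grid.

    Every reaction is a 1:1 molar transformation and the ``cleared`` pool
    collects all removal, so the state total should be constant (pulse mode)
    up to solver error.  Returns max_t |total(t) − total(0)| / total(0).
    """
    if trajectory.full_state is None:
        raise ValueError("mass balance requires the full state")
    total = np.sum([trajectory.full_state[name] for name in STATE_NAMES], axis=0)
    if params.input_mode == "infusion":
        total = total - params.infusion_rate * trajectory.times
    if total[0] <= 0:
        raise ValueError("mass balance undefined for zero initial material")
    return float(np.max(np.abs(total - total[0])) / total[0])


def steady_state(
    coeffs: ActivityCoefficients,
    params: KineticParameters,
    tol: float = 1e-9,
) -> dict[str, float]:
    """Solve the constant-infusion flux-balance equations by root-finding.

    Only defined for ``input_mode='infusion'``.  Returns the eight-state
    dict; the six dynamic concentration pools have |derivative| < ``tol``
    μM/min.  (``cleared`` grows linearly at the infusion rate by
    construction and is reported as 0.)  With the external pool bypassed and
    ``k_eloss = 0``, all input exits as 5-HIAA and the closed form
    ``hiaa* = R / k_hiaa`` holds.
    """
    p = params
    if p.input_mode != "infusion":
        raise ValueError("steady state requires input_mode='infusion'")
    r = p.infusion_rate
    if r == 0:
        return {name: 0.0 for name in STATE_NAMES}

    def _unpack(x: np.ndarray) -> np.ndarray:
        y = np.zeros(8)
        y[1:7] = x
        return y

    def residual(x: np.ndarray) -> np.ndarray:
        return derivatives(_unpack(np.abs(x)), 0.0, p, coeffs)[1:7]

    # Heuristic start from the chain of closed-form balances, clamped to the
    # feasible range of each saturable step.
    def _mm_inverse(flux: float, vmax: float, km: float) -> float:
        frac = min(flux / vmax, 0.95)
        return km * frac / (1.0 - frac)

    f_t = r
    trp0 = _mm_inverse(f_t, coeffs.c_tph2 * p.vmax_tph2, p.km_tph2)
    htp0 = f_t / p.k_aadc
    fc0 = _mm_inverse(min(r, 0.9 * coeffs.c_maoa * p.vmax_maoa),
                      coeffs.c_maoa * p.vmax_maoa, p.km_maoa)
    f_v = p.vmax_vmat * fc0 / (p.km_vmat + fc0)
    v0 = f_v / p.k_rel
    e0 = _mm_inverse(min(f_v, 0.9 * coeffs.c_sert * p.vmax_sert),
                     coeffs.c_sert * p.vmax_sert, p.km_sert)
    x0 = np.array([trp0, htp0, fc0, v0, e0, r / p.k_hiaa])

    sol = root(residual, x0, method="hybr", tol=1e-13)
    x = np.abs(sol.x)
    res = residual(x)
    if not sol.success or np.max(np.abs(res)) >= tol:
        raise RuntimeError(
            f"no steady state found in the positive orthant (max residual "
            f"{np.max(np.abs(res)):.3g} μM/min)"
        )
    state = {name: 0.0 for name in STATE_NAMES}
    for i, name in enumerate(STATE_NAMES[1:7]):
        state[name] = float(x[i])
    return state


def plot_trajectory(trajectory: Trajectory, ax=None):
    """Diagnostic plot of the five species' time courses."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    labels = {
        "htp": "5-HTP",
        "fc5ht": "fc5-HT",
        "v5ht": "v5-HT",
        "e5ht": "e5-HT",
        "hiaa": "5-HIAA",
    }
    for name in SPECIES:
        ax.plot(trajectory.times, trajectory.series[name], label=labels[name])
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (μM)")
    ax.legend(frameon=False)
    return ax
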