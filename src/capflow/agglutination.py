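"""Mass-action kinetics of particle immunoagglutination.

Antibody-conjugated particles (Abp) and free antigen (Ag) react inside
the paper matrix.  Because the fiber network makes binding spatially
uneven, only two binding tiers are modeled:

  primary    Abp + Ag      <=> Abp.Ag     (kon1 / koff1)
  secondary  Abp + Abp.Ag  <=> Abp2.Ag    (kon2 / koff2)
             Ag  + Abp.Ag   -> Abp.Ag2    (kon3; dissociation neglected)

Abp2.Ag is the two-particle aggregate — the agglutination readout the
assay cares about; Abp.Ag2 ties up antigen without aggregating particles.
All quantities are dimensionless model units (the simulation reproduces
trends, not absolute molarities).  The five coupled ODEs conserve both
totals

  particles:  Abp + Abp.Ag + 2 Abp2.Ag + Abp.Ag2
  antigen:    Ag  + Abp.Ag + Abp2.Ag  + 2 Abp.Ag2

which is the primary correctness check of the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "KineticState",
    "Trajectory",
    "DoseCurve",
    "derivatives",
    "simulate",
    "dose_response",
    "find_hook_peak",
    "find_crossing",
    "HookPeak",
    "CurveCrossing",
    "conservation_drift",
]

SPECIES = ("abp", "ag", "abp_ag", "abp2_ag", "abp_ag2")


class IntegrationError(RuntimeError):
    """The ODE solver diverged or produced unphysical concentrations."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and initial concentrations (dimensionless units).

    Defaults are the representative constant set of the agglutination
    simulations: kon1=6, koff1=0.1, kon2=1, koff2=0.05, kon3=2.
    """

    kon1: float = 6.0
    koff1: float = 0.1
    kon2: float = 1.0
    koff2: float = 0.05
    kon3: float = 2.0
    abp0: float = 10.0
    ag0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kon1", "koff1", "kon2", "koff2", "kon3", "abp0", "ag0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class KineticState(NamedTuple):
    """Concentrations of the five species."""

    abp: float
    ag: float
    abp_ag: float
    abp2_ag: float
    abp_ag2: float


def derivatives(state: KineticState, params: KineticParams) -> KineticState:
    """Right-hand side of the five mass-action ODEs.

    Four species follow the printed rate equations; Abp.Ag2 has the single
    production term kon3*[Abp.Ag]*[Ag] (its dissociation is neglected),
    which closes both conservation laws.
    """
    abp, ag, c1, c2, c3 = state
    p = params
    assoc1 = p.kon1 * abp * ag
    assoc2 = p.kon2 * abp * c1
    assoc3 = p.kon3 * c1 * ag
    d_c1 = assoc1 - p.koff1 * c1 - assoc2 + p.koff2 * c2 - assoc3
    d_c2 = assoc2 - p.koff2 * c2
    d_abp = -assoc1 + p.koff1 * c1 - assoc2 + p.koff2 * c2
    d_ag = -assoc1 + p.koff1 * c1 - assoc3
    d_c3 = assoc3
    return KineticState(d_abp, d_ag, d_c1, d_c2, d_c3)


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus species concentrations, shape (n_times, 5)."""

    times: np.ndarray
    states: np.ndarray
    params: KineticParams

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    @property
    def particle_total(self) -> np.ndarray:
        a, _, c1, c2, c3 = self.states.T
        return a + c1 + 2 * c2 + c3

    @property
    def antigen_total(self) -> np.ndarray:
        _, g, c1, c2, c3 = self.states.T
        return g + c1 + c2 + 2 * c3


def conservation_drift(traj: Trajectory) -> float:
    """Max relative drift of the two conserved totals along the trajectory."""
    drift = 0.0
    for total, ref in ((traj.particle_total, traj.params.abp0), (traj.antigen_total, traj.params.ag0)):
        scale = max(abs(ref), 1.0)
        drift = max(drift, float(np.abs(total - total[0]).max()) / scale)
    return drift


def simulate(
    params: KineticParams,
    t_end: float = 1.0,
    n_steps: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate from (abp0, ag0, 0, 0, 0) with adaptive Runge-Kutta.

    Concentrations are checked for non-negativity: dips below -1e-8 raise
    :class:`IntegrationError`; smaller excursions are clamped to zero.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    y0 = np.array([params.abp0, params.ag0, 0.0, 0.0, 0.0])
    t_eval = np.linspace(0.0, t_end, n_steps + 1)
    sol = solve_ivp(
        lambda t, y: derivatives(KineticState(*y), params),
        (0.0, t_end),
        y0,
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(sol.message)
    states = sol.y.T
    if states.min() < -1e-8:
        raise IntegrationError(
            f"negative concentration {states.min():.3e} beyond tolerance"
        )
    return Trajectory(times=sol.t, states=np.clip(states, 0.0, None), params=params)


@dataclass(frozen=True)
class DoseCurve:
    """Normalized agglutination Abp2.Ag(t_sample)/abp0 versus initial antigen."""

    ag_grid: np.ndarray
    norm_agglutination: np.ndarray
    abp0: float
    t_sample: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ag_grid", np.asarray(self.ag_grid, dtype=float))
        object.__setattr__(
            self, "norm_agglutination", np.asarray(self.norm_agglutination, dtype=float)
        )


def dose_response(
    params_base: KineticParams,
    ag_grid: Sequence[float],
    t_sample: float = 1.0,
    n_steps: int = 50,
) -> DoseCurve:
    """Simulate once per initial antigen level; sample Abp2.Ag at t_sample.

    t_sample defaults to 1.0, the time at which the binding has leveled
    off for the representative constants.  Values are normalized by the
    initial particle concentration abp0.
    """
    ag_grid = np.asarray(ag_grid, dtype=float)
    if np.any(ag_grid < 0) or np.any(np.diff(ag_grid) < 0):
        raise ValueError("ag_grid must be non-negative and sorted")
    if params_base.abp0 <= 0:
        raise ValueError("abp0 must be > 0 for normalized output")
    values = np.empty_like(ag_grid)
    for i, ag0 in enumerate(ag_grid):
        if ag0 == 0:
            values[i] = 0.0
            continue
        traj = simulate(replace(params_base, ag0=float(ag0)), t_end=t_sample, n_steps=n_steps)
        values[i] = traj.species("abp2_ag")[-1] / params_base.abp0
    return DoseCurve(ag_grid, values, params_base.abp0, t_sample)


class HookPeak(NamedTuple):
    ag_at_peak: float
    peak_value: float
    interior: bool  # False: curve is monotone up to the boundary (no hook)


def find_hook_peak(curve: DoseCurve) -> HookPeak:
    """Grid argmax of the dose curve; ties break toward lower antigen.

    ``interior=False`` flags a peak sitting on the grid boundary, i.e. a
    monotone curve with no hook (prozone) rollover inside the grid.
    """
    y = curve.norm_agglutination
    if y.size < 3:
        raise ValueError("dose curve needs at least 3 points")
    k = int(np.argmax(y))  # argmax takes the first (lowest-ag) maximum
    return HookPeak(float(curve.ag_grid[k]), float(y[k]), interior=0 < k < y.size - 1)


class CurveCrossing(NamedTuple):
    ag_cross: float
    kind: str  # "crossing" | "degenerate" | "none"


def find_crossing(curve_low_abp: DoseCurve, curve_high_abp: DoseCurve) -> CurveCrossing:
    """Smallest antigen level where (high - low) changes sign.

    The crossing is located by linear interpolation between the two
    bracketing grid points.  Identical curves return the first grid point
    flagged "degenerate"; curves that never cross return kind "none".
    """
    if not np.array_equal(curve_low_abp.ag_grid, curve_high_abp.ag_grid):
        raise ValueError("curves must share the same ag_grid")
    ag = curve_low_abp.ag_grid
    diff = curve_high_abp.norm_agglutination - curve_low_abp.norm_agglutination
    if np.all(diff == 0):
        return CurveCrossing(float(ag[0]), "degenerate")
    sign = np.sign(diff)
    for i in range(len(diff) - 1):
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            frac = diff[i] / (diff[i] - diff[i + 1])
            return CurveCrossing(float(ag[i] + frac * (ag[i + 1] - ag[i])), "crossing")
        if sign[i] != 0 and sign[i + 1] == 0:
            return CurveCrossing(float(ag[i + 1]), "crossing")
    return CurveCrossing(float("nan"), "none")
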