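"""Torque-minimizing waist/tail undulation for the planar three-link model.

The waist and tail joint references are single sines per gait period; the
design vector is (a_waist, b_waist, a_tail, b_tail).  The objective is the
integral of the squared waist and tail torques over one period, subject to a
bound on the peak ground-reaction moment (enforced as a quadratic penalty)
while the pelvic rotation tracks its sinusoidal reference through the GRM
servo inside the simulation.  Minimizing this cost makes the two joints
generate opposing moments — the S-shaped lateral undulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .planar import (
    GaitSchedule,
    GrfProfile,
    PdGains,
    PlanarModel,
    PlanarTrace,
    SineParams,
    simulate_stride,
)

__all__ = [
    "desired_undulation",
    "torque_cost",
    "OptimizationProblem",
    "UndulationResult",
    "optimize_undulation",
    "phase_difference",
]


def desired_undulation(t, params: SineParams, period: float):
    """Desired joint angle ``a sin(2 pi t / period + b) + c`` at time t."""
    if period <= 0:
        raise ValueError("period must be positive")
    return params(t, period)


def torque_cost(trace: PlanarTrace, period: float | None = None) -> float:
    """Integrated squared waist+tail torque over the final full period."""
    Tp = trace.period if period is None else period
    t = trace.t
    if t[-1] - t[0] < Tp * (1.0 - 1e-9):
        raise ValueError("trace must span at least one full period")
    mask = t >= t[-1] - Tp * (1.0 + 1e-12)
    tt = t[mask]
    u = trace.torques[mask]
    return float(np.trapezoid((u**2).sum(axis=1), tt))


@dataclass(frozen=True)
class OptimizationProblem:
    """Undulation design problem: amplitude bounds and the GRM budget."""

    model: PlanarModel
    schedule: GaitSchedule = field(default_factory=GaitSchedule)
    grf: GrfProfile = field(default_factory=GrfProfile)
    gains: PdGains = field(default_factory=PdGains)
    grm_bound: float = 0.03  # N*m, near-minimal feasible for the default model
    grm_penalty_weight: float = 1e4
    amplitude_bound: float = np.deg2rad(60.0)
    dt_fraction: int = 400  # simulation steps per period during optimization
    n_periods: int = 2

    def simulate(self, design: np.ndarray, dt_fraction: int | None = None) -> PlanarTrace:
        a1, b1, a2, b2 = design
        frac = self.dt_fraction if dt_fraction is None else dt_fraction
        und = (SineParams(abs(a1), b1), SineParams(abs(a2), b2))
        return simulate_stride(
            self.model,
            self.schedule,
            self.grf,
            self.gains,
            und,
            mz_limit=None,
            n_periods=self.n_periods,
            dt=self.schedule.period / frac,
        )

    def objective(self, design: np.ndarray) -> float:
        trace = self.simulate(design)
        cost = torque_cost(trace)
        peak = float(np.max(np.abs(trace.ground_moment)))
        excess = max(0.0, peak - self.grm_bound)
        return cost + self.grm_penalty_weight * excess * excess


@dataclass
class UndulationResult:
    waist: SineParams
    tail: SineParams
    objective: float
    baseline_objective: float
    peak_grm: float
    design: np.ndarray
    trace: PlanarTrace
    n_starts: int
    converged: bool


def optimize_undulation(
    problem: OptimizationProblem,
    init: np.ndarray | None = None,
    n_starts: int = 4,
    seed: int | None = None,
    maxiter: int = 120,
    polish: bool = True,
) -> UndulationResult:
    """Minimize the squared-torque objective over (a1, b1, a2, b2).

    SQP-type local searches (SLSQP, finite-difference gradients) from up to
    ``n_starts`` starting points placed in the four phase quadrants; an
    explicit ``init`` replaces the first start.  Phases are unbounded during
    the search and wrapped afterwards.
    """
    rng = np.random.default_rng(seed)
    amax = problem.amplitude_bound
    starts = []
    if init is not None:
        starts.append(np.asarray(init, float))
    quadrants = [(0.0, np.pi), (np.pi, 0.0),
                 (np.pi / 2, -np.pi / 2), (-np.pi / 2, np.pi / 2)]
    for b1, b2 in quadrants:
        if len(starts) >= n_starts:
            break
        a0 = np.deg2rad(15.0) + rng.uniform(0, np.deg2rad(5.0), size=2)
        starts.append(np.array([a0[0], b1, a0[1], b2]))
    starts = starts[:n_starts]

    bounds = [(0.0, amax), (-2 * np.pi, 2 * np.pi)] * 2
    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(
            problem.objective,
            x0,
            method="SLSQP",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-14},
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("undulation optimization produced no iterates")
    if polish:
        # a restart from the incumbent resets the SQP working set and
        # reliably descends the narrow valley of the penalized objective
        res = minimize(
            problem.objective,
            best.x,
            method="SLSQP",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-14},
        )
        if res.fun < best.fun:
            best = res

    baseline = problem.objective(np.array([0.0, 0.0, 0.0, 0.0]))
    trace = problem.simulate(best.x, dt_fraction=1000)
    a1, b1, a2, b2 = best.x
    return UndulationResult(
        waist=SineParams(abs(a1), b1),
        tail=SineParams(abs(a2), b2),
        objective=float(best.fun),
        baseline_objective=float(baseline),
        peak_grm=float(np.max(np.abs(trace.ground_moment))),
        design=np.asarray(best.x, float),
        trace=trace,
        n_starts=len(starts),
        converged=bool(any_ok),
    )


def phase_difference(
    trace_1: np.ndarray,
    trace_2: np.ndarray,
    period: float,
    t: np.ndarray | None = None,
    n_grid: int = 1000,
) -> float:
    """Phase lag between two periodic signals as a fraction of the period.

    Signals are resampled onto a uniform grid over one period and the lag is
    located at the peak of the circular cross-correlation; the result is
    folded into [0, 0.5] (half a period is the maximum meaningful lag).
    """
    x1 = np.asarray(trace_1, float)
    x2 = np.asarray(trace_2, float)
    if t is not None:
        t = np.asarray(t, float)
        if t[-1] - t[0] < period * (1 - 1e-9):
            raise ValueError("time support shorter than one period")
        grid = np.linspace(t[-1] - period, t[-1], n_grid, endpoint=False)
        x1 = np.interp(grid, t, x1)
        x2 = np.interp(grid, t, x2)
    else:
        if len(x1) != len(x2):
            raise ValueError("traces must share their sampling grid")
        n_grid = len(x1)
    x1 = x1 - x1.mean()
    x2 = x2 - x2.mean()
    corr = np.fft.irfft(np.fft.rfft(x1) * np.conj(np.fft.rfft(x2)), n=n_grid)
    lag = int(np.argmax(corr))
    frac = lag / n_grid
    return float(min(frac, 1.0 - frac))
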