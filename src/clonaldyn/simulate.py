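"""Numerical integration of the T-cell response with event detection.

A run spans the full immune response: from the instant of activation until
the end of clonal contraction (total effector T returning to its baseline
after a guarded excursion) or the integration horizon, whichever comes
first.  The pathogen-control threshold crossing (P falling below ``p_min``)
is recorded as a *non-terminal* event along the way: because the T-cell
population has inertia, clonal expansion continues after the pathogen is
controlled, and terminating there would truncate the contraction phase the
model is about.

Outcome classification:

* ELIMINATION — pathogen controlled before (or without) contraction end;
* TOLERANCE   — contraction completed while the pathogen was still above
  its infectivity threshold ("tolerance by early contraction");
* UNRESOLVED  — horizon reached with neither event (a first-class label so
  that parameter sweeps never abort).

Two integrators are provided: an adaptive high-order solver
(:func:`integrate` / :func:`integrate_multi`, scipy DOP853 with event
functions) and a deliberately simple fixed-step RK4 reference
(:func:`rk4_reference`) used as an independent cross-check, plus the exact
solution of the uncoupled (beta = 0) limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import AnalyticLimitError, ConfigurationError, NumericalError
from .model_core import (
    CloneParameters,
    DimensionalParameters,
    InitialState,
    ReducedParameters,
    SimulationControls,
    from_reduced,
    rhs_multi,
    rhs_single,
)

__all__ = [
    "PATHOGEN_CONTROLLED",
    "CONTRACTION_END",
    "HORIZON_REACHED",
    "ELIMINATION",
    "TOLERANCE",
    "UNRESOLVED",
    "EventRecord",
    "Trajectory",
    "Outcome",
    "integrate",
    "integrate_multi",
    "rk4_reference",
    "rk4_reference_multi",
    "closed_form_uncoupled",
    "classify",
]

# Event kinds
PATHOGEN_CONTROLLED = "PATHOGEN_CONTROLLED"
CONTRACTION_END = "CONTRACTION_END"
HORIZON_REACHED = "HORIZON_REACHED"

# Outcome labels
ELIMINATION = "ELIMINATION"
TOLERANCE = "TOLERANCE"
UNRESOLVED = "UNRESOLVED"

_P_OVERFLOW = 1e30  # pathogen load beyond which the run is declared numerically lost


@dataclass(frozen=True)
class EventRecord:
    """A detected event: its kind, time and the full state at that instant."""

    kind: str
    time: float
    state_at_event: tuple[float, ...]


@dataclass
class Trajectory:
    """Dense output of one run plus its detected events.

    ``states`` has one row per sample; ``columns`` names the state
    components (``T, dT, P`` for a single clone, ``T_<label>, dT_<label>,
    ..., P`` for several).  ``t_indices`` are the columns contributing to
    the total effector population and ``baseline_T`` its initial value —
    the reference level for contraction detection.
    """

    times: np.ndarray
    states: np.ndarray
    columns: list[str]
    events: list[EventRecord]
    params_echo: dict
    t_indices: tuple[int, ...] = (0,)
    baseline_T: float = 0.0

    def total_T(self) -> np.ndarray:
        return self.states[:, list(self.t_indices)].sum(axis=1)

    @property
    def P(self) -> np.ndarray:
        return self.states[:, -1]

    def first_event(self, kind: str) -> EventRecord | None:
        for ev in self.events:
            if ev.kind == kind:
                return ev
        return None


@dataclass(frozen=True)
class Outcome:
    """Classification of a run with its event times and peak statistics."""

    label: str
    t_control: float | None
    t_contraction_end: float | None
    peak_T: float
    t_peak_T: float
    residual_P: float


def _echo(params: object, init: object, controls: SimulationControls) -> dict:
    from dataclasses import asdict

    def conv(x):
        try:
            return asdict(x)
        except TypeError:
            return x

    return {"params": conv(params), "init": conv(init), "controls": conv(controls)}


def _event_driven_solve(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: np.ndarray,
    t_indices: tuple[int, ...],
    baseline_T: float,
    controls: SimulationControls,
    echo: dict,
    columns: list[str],
) -> Trajectory:
    """Two-stage adaptive integration with guarded contraction detection.

    Stage 1 runs until total T first exceeds baseline + peak_guard_eps
    (arming the contraction detector) or the horizon.  Stage 2 then runs
    until total T crosses the baseline downward.  The pathogen threshold
    crossing is watched non-terminally throughout.
    """
    p_min = controls.p_min
    if y0[-1] <= p_min:
        raise ConfigurationError(
            f"initial pathogen load {y0[-1]!r} must exceed p_min={p_min!r}"
        )
    idx = np.asarray(t_indices, dtype=int)

    def tot_T(y: np.ndarray) -> float:
        return float(y[idx].sum())

    def ev_pathogen(t, y):
        return y[-1] - p_min

    ev_pathogen.direction = -1
    ev_pathogen.terminal = False

    armed_level = baseline_T + controls.peak_guard_eps

    def ev_arm(t, y):
        return tot_T(y) - armed_level

    ev_arm.direction = 1
    ev_arm.terminal = True

    def ev_contraction(t, y):
        return tot_T(y) - baseline_T

    ev_contraction.direction = -1
    ev_contraction.terminal = True

    kwargs = dict(
        method="DOP853",
        rtol=controls.rel_tol,
        atol=controls.abs_tol,
        dense_output=True,
    )

    events: list[EventRecord] = []
    segments = []

    sol1 = solve_ivp(
        rhs, (0.0, controls.t_max), y0, events=[ev_pathogen, ev_arm], **kwargs
    )
    if not sol1.success:
        raise NumericalError(f"integrator failed in expansion stage: {sol1.message}; {echo}")
    segments.append(sol1)

    p_times = list(sol1.t_events[0])
    p_states = list(sol1.y_events[0])

    terminal: EventRecord | None = None
    if sol1.t_events[1].size > 0:  # contraction detector armed
        t_arm = float(sol1.t_events[1][0])
        y_arm = sol1.y_events[1][0]
        sol2 = solve_ivp(
            rhs,
            (t_arm, controls.t_max),
            y_arm,
            events=[ev_pathogen, ev_contraction],
            **kwargs,
        )
        if not sol2.success:
            raise NumericalError(
                f"integrator failed in contraction stage: {sol2.message}; {echo}"
            )
        segments.append(sol2)
        p_times.extend(sol2.t_events[0])
        p_states.extend(sol2.y_events[0])
        if sol2.t_events[1].size > 0:
            t_c = float(sol2.t_events[1][0])
            terminal = EventRecord(
                CONTRACTION_END, t_c, tuple(float(v) for v in sol2.y_events[1][0])
            )

    t_end = terminal.time if terminal is not None else controls.t_max

    # only the first pathogen-control crossing inside the run is an event
    if p_times:
        t_p = float(p_times[0])
        if t_p <= t_end:
            events.append(
                EventRecord(PATHOGEN_CONTROLLED, t_p, tuple(float(v) for v in p_states[0]))
            )

    if terminal is None:
        y_end = segments[-1].sol(controls.t_max)
        terminal = EventRecord(
            HORIZON_REACHED, controls.t_max, tuple(float(v) for v in y_end)
        )
    events.append(terminal)
    events.sort(key=lambda e: e.time)

    # dense sampling on a uniform grid, final point at the terminating event
    n_out = int(math.floor(t_end / controls.dt_out))
    t_grid = np.arange(n_out + 1) * controls.dt_out
    if t_end - t_grid[-1] > 1e-12 * max(1.0, t_end):
        t_grid = np.append(t_grid, t_end)
    else:
        t_grid[-1] = t_end

    states = np.empty((t_grid.size, y0.size))
    lo = 0
    for seg in segments:
        hi = int(np.searchsorted(t_grid, seg.t[-1], side="right"))
        if hi > lo:
            states[lo:hi] = seg.sol(t_grid[lo:hi]).T
        lo = hi
    if lo < t_grid.size:  # numerical stragglers at the segment boundary
        states[lo:] = segments[-1].sol(t_grid[lo:]).T
    # pin the final row to the located event state
    states[-1] = np.asarray(terminal.state_at_event)

    return Trajectory(
        times=t_grid,
        states=states,
        columns=columns,
        events=events,
        params_echo=echo,
        t_indices=t_indices,
        baseline_T=baseline_T,
    )


def _resolve_single(
    params: DimensionalParameters | ReducedParameters,
    init: InitialState | None,
) -> tuple[DimensionalParameters, InitialState]:
    if isinstance(params, ReducedParameters):
        dim, default_init = from_reduced(params)
        return dim, (init if init is not None else default_init)
    if init is None:
        init = InitialState()
    return params, init


def integrate(
    params: DimensionalParameters | ReducedParameters,
    init: InitialState | None = None,
    controls: SimulationControls | None = None,
) -> Trajectory:
    """Integrate the single-clone system adaptively with event detection.

    Reduced parameters are embedded canonically (k = lam = P0 = 1) so the
    same machinery serves both forms.
    """
    controls = controls if controls is not None else SimulationControls()
    dim, init = _resolve_single(params, init)
    echo = _echo(params, init, controls)

    def rhs(t, y):
        return rhs_single(y, dim)

    y0 = np.array([init.T0, init.dT0, init.P0], dtype=float)
    return _event_driven_solve(
        rhs, y0, (0,), init.T0, controls, echo, ["T", "dT", "P"]
    )


def _validate_clones(clones: Sequence[CloneParameters]) -> None:
    if len(clones) == 0:
        raise ConfigurationError("at least one clone is required")
    labels = [c.label for c in clones]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"clone labels must be unique, got {labels}")


def integrate_multi(
    clones: Sequence[CloneParameters],
    alpha: float,
    init: Sequence[tuple[float, float]] | None = None,
    P0: float = 1.0,
    controls: SimulationControls | None = None,
) -> Trajectory:
    """Integrate the multi-clone system; contraction is defined on total T.

    ``init`` gives per-clone (T0, dT0) pairs; all clones start empty and at
    rest by default.
    """
    _validate_clones(clones)
    if not alpha > 0:
        raise ConfigurationError(f"alpha must be > 0, got {alpha!r}")
    controls = controls if controls is not None else SimulationControls()
    n = len(clones)
    if init is None:
        init = [(0.0, 0.0)] * n
    if len(init) != n:
        raise ConfigurationError(f"expected {n} per-clone initial states, got {len(init)}")

    y0 = np.empty(2 * n + 1)
    for i, (T0, dT0) in enumerate(init):
        if T0 < 0:
            raise ConfigurationError(f"clone {clones[i].label}: T0 must be >= 0")
        y0[2 * i] = T0
        y0[2 * i + 1] = dT0
    y0[-1] = P0

    clone_list = list(clones)
    echo = {
        "clones": [
            {"label": c.label, "k": c.k, "lam": c.lam, "beta": c.beta}
            for c in clone_list
        ],
        "alpha": alpha,
        "init": [list(pair) for pair in init],
        "P0": P0,
        "controls": _echo(None, None, controls)["controls"],
    }

    def rhs(t, y):
        return rhs_multi(y, clone_list, alpha)

    t_indices = tuple(2 * i for i in range(n))
    baseline = float(sum(y0[list(t_indices)]))
    columns = []
    for c in clone_list:
        columns += [f"T_{c.label}", f"dT_{c.label}"]
    columns.append("P")
    return _event_driven_solve(rhs, y0, t_indices, baseline, controls, echo, columns)


# ---------------------------------------------------------------------------
# fixed-step RK4 reference integrator (independent oracle)
# ---------------------------------------------------------------------------


def _rk4_run(
    f: Callable[[list[float]], list[float]],
    y0: list[float],
    t_indices: Sequence[int],
    baseline_T: float,
    controls: SimulationControls,
    h: float,
    echo: dict,
    columns: list[str],
) -> Trajectory:
    """Fixed-step RK4 with sign-change event location by linear interpolation."""
    if not h > 0:
        raise ConfigurationError(f"step size h must be > 0, got {h!r}")
    if h > controls.dt_out:
        raise ConfigurationError("rk4 step h must not exceed dt_out")
    p_min = controls.p_min
    if y0[-1] <= p_min:
        raise ConfigurationError(
            f"initial pathogen load {y0[-1]!r} must exceed p_min={p_min!r}"
        )
    idx = list(t_indices)
    armed_level = baseline_T + controls.peak_guard_eps

    sample_every = max(1, round(controls.dt_out / h))
    n_steps = int(math.ceil(controls.t_max / h))

    def tot(y: list[float]) -> float:
        return sum(y[i] for i in idx)

    def lerp(ya: list[float], yb: list[float], theta: float) -> tuple[float, ...]:
        return tuple(a + theta * (b - a) for a, b in zip(ya, yb))

    times = [0.0]
    samples = [tuple(y0)]
    events: list[EventRecord] = []
    armed = tot(y0) > armed_level
    p_recorded = False
    terminal: EventRecord | None = None

    y = list(y0)
    t = 0.0
    for step in range(1, n_steps + 1):
        k1 = f(y)
        y2 = [a + 0.5 * h * b for a, b in zip(y, k1)]
        k2 = f(y2)
        y3 = [a + 0.5 * h * b for a, b in zip(y, k2)]
        k3 = f(y3)
        y4 = [a + h * b for a, b in zip(y, k3)]
        k4 = f(y4)
        y_new = [
            a + (h / 6.0) * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            for a, b1, b2, b3, b4 in zip(y, k1, k2, k3, k4)
        ]
        t_new = step * h
        if not math.isfinite(y_new[-1]) or abs(y_new[-1]) > _P_OVERFLOW:
            raise NumericalError(f"pathogen load overflow at t={t_new}; {echo}")

        if not p_recorded and y[-1] > p_min >= y_new[-1]:
            theta = (y[-1] - p_min) / (y[-1] - y_new[-1])
            events.append(
                EventRecord(PATHOGEN_CONTROLLED, t + theta * h, lerp(y, y_new, theta))
            )
            p_recorded = True

        tot_old, tot_new = tot(y), tot(y_new)
        if not armed:
            if tot_old <= armed_level < tot_new:
                armed = True
        elif tot_old > baseline_T >= tot_new:
            theta = (tot_old - baseline_T) / (tot_old - tot_new)
            t_ev = t + theta * h
            terminal = EventRecord(CONTRACTION_END, t_ev, lerp(y, y_new, theta))
            times.append(t_ev)
            samples.append(terminal.state_at_event)
            break

        y, t = y_new, t_new
        if step % sample_every == 0:
            times.append(t)
            samples.append(tuple(y))

    if terminal is None:
        if times[-1] != t:
            times.append(t)
            samples.append(tuple(y))
        terminal = EventRecord(HORIZON_REACHED, t, tuple(y))
    events.append(terminal)
    events.sort(key=lambda e: e.time)

    return Trajectory(
        times=np.array(times),
        states=np.array(samples),
        columns=columns,
        events=events,
        params_echo=echo,
        t_indices=tuple(t_indices),
        baseline_T=baseline_T,
    )


def rk4_reference(
    params: DimensionalParameters | ReducedParameters,
    init: InitialState | None = None,
    controls: SimulationControls | None = None,
    h: float = 1e-3,
) -> Trajectory:
    """Classical fixed-step RK4 for the single-clone system.

    Deterministic brute-force oracle: global error O(h^4), events located by
    sign change plus linear interpolation within a step.  Kept intentionally
    independent of the adaptive path in :func:`integrate`.
    """
    controls = controls if controls is not None else SimulationControls()
    dim, init = _resolve_single(params, init)
    echo = _echo(params, init, controls)
    k, lam, a, b = dim.k, dim.lam, dim.alpha, dim.beta

    def f(y: list[float]) -> list[float]:
        T, V, P = y
        return [V, -k * T + lam * P, a * P - b * T * P]

    return _rk4_run(
        f, [init.T0, init.dT0, init.P0], (0,), init.T0, controls, h, echo, ["T", "dT", "P"]
    )


def rk4_reference_multi(
    clones: Sequence[CloneParameters],
    alpha: float,
    init: Sequence[tuple[float, float]] | None = None,
    P0: float = 1.0,
    controls: SimulationControls | None = None,
    h: float = 1e-3,
) -> Trajectory:
    """Fixed-step RK4 oracle for the multi-clone system."""
    _validate_clones(clones)
    controls = controls if controls is not None else SimulationControls()
    n = len(clones)
    if init is None:
        init = [(0.0, 0.0)] * n
    y0 = []
    for T0, dT0 in init:
        y0 += [T0, dT0]
    y0.append(P0)
    clone_list = list(clones)

    def f(y: list[float]) -> list[float]:
        return list(rhs_multi(y, clone_list, alpha))

    t_indices = tuple(2 * i for i in range(n))
    baseline = sum(y0[i] for i in t_indices)
    columns = []
    for c in clone_list:
        columns += [f"T_{c.label}", f"dT_{c.label}"]
    columns.append("P")
    echo = {"clones": [c.label for c in clone_list], "alpha": alpha, "h": h}
    return _rk4_run(f, y0, t_indices, baseline, controls, h, echo, columns)


def closed_form_uncoupled(
    params: DimensionalParameters,
    init: InitialState,
    times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution when clearance is switched off (beta -> 0 limit).

    P grows exponentially, P(t) = P0 e^(alpha t), and T is a driven harmonic
    oscillator:

        T(t) = (T0 - C) cos(sqrt(k) t)
             + (dT0 - C alpha)/sqrt(k) * sin(sqrt(k) t)
             + C e^(alpha t),      C = lam P0 / (alpha^2 + k).

    The dimensional beta = 0 point sits outside the admissible parameter
    space (all rates strictly positive), so this accepts a plain parameter
    bundle with ``beta == 0`` built via ``object.__new__`` — in practice the
    test suites construct it through :func:`uncoupled_parameters`.
    """
    if params.beta != 0:
        raise AnalyticLimitError(
            f"closed_form_uncoupled requires beta == 0 exactly, got {params.beta!r}"
        )
    t = np.asarray(times, dtype=float)
    k, lam, alpha = params.k, params.lam, params.alpha
    sqrt_k = math.sqrt(k)
    C = lam * init.P0 / (alpha**2 + k)
    P = init.P0 * np.exp(alpha * t)
    T = (
        (init.T0 - C) * np.cos(sqrt_k * t)
        + (init.dT0 - C * alpha) / sqrt_k * np.sin(sqrt_k * t)
        + C * np.exp(alpha * t)
    )
    return T, P


def uncoupled_parameters(k: float, lam: float, alpha: float) -> DimensionalParameters:
    """Parameter bundle on the beta = 0 boundary for analytic-limit checks.

    lam = 0 is likewise allowed here (the pure harmonic-oscillator limit);
    the strict-positivity invariant applies to the interior model only.
    """
    p = object.__new__(DimensionalParameters)
    object.__setattr__(p, "k", k)
    object.__setattr__(p, "lam", lam)
    object.__setattr__(p, "alpha", alpha)
    object.__setattr__(p, "beta", 0.0)
    if not (k > 0 and lam >= 0 and alpha > 0):
        raise ConfigurationError("uncoupled limit requires k > 0, lam >= 0, alpha > 0")
    return p


def classify(traj: Trajectory, controls: SimulationControls) -> Outcome:
    """Map a trajectory's events to an outcome label with peak statistics."""
    if not traj.events:
        raise ConfigurationError("trajectory carries no events; cannot classify")

    ev_control = traj.first_event(PATHOGEN_CONTROLLED)
    ev_contraction = traj.first_event(CONTRACTION_END)
    ev_horizon = traj.first_event(HORIZON_REACHED)
    if ev_contraction is None and ev_horizon is None:
        raise ConfigurationError(
            "trajectory has neither a terminating event nor a horizon record"
        )

    tot = traj.total_T()
    i_peak = int(np.argmax(tot))
    peak_T = float(tot[i_peak])
    t_peak = float(traj.times[i_peak])
    # parabolic refinement through the three samples around the maximum:
    # resolves t_peak well below the output grid spacing, which matters when
    # comparing it against event times (the inertia delay can be small)
    if 0 < i_peak < tot.size - 1:
        t3 = traj.times[i_peak - 1 : i_peak + 2]
        f3 = tot[i_peak - 1 : i_peak + 2]
        if abs(t3[2] - t3[0] - 2 * (t3[1] - t3[0])) < 1e-9 * (t3[2] - t3[0]):
            denom = f3[0] - 2 * f3[1] + f3[2]
            if denom < 0:
                offset = 0.5 * (f3[0] - f3[2]) / denom
                if abs(offset) <= 1.0:
                    dt = t3[1] - t3[0]
                    t_peak = float(t3[1] + offset * dt)
                    peak_T = float(f3[1] - 0.25 * (f3[0] - f3[2]) * offset)
    residual_P = float(traj.states[-1, -1])

    t_control = ev_control.time if ev_control is not None else None
    t_ce = ev_contraction.time if ev_contraction is not None else None

    if t_control is not None and (t_ce is None or t_control <= t_ce):
        label = ELIMINATION
    elif t_ce is not None:
        label = TOLERANCE
    else:
        label = UNRESOLVED

    return Outcome(
        label=label,
        t_control=t_control,
        t_contraction_end=t_ce,
        peak_T=peak_T,
        t_peak_T=t_peak,
        residual_P=residual_P,
    )
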