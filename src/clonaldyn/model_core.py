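"""Parameter/state types and right-hand sides of the inertial T-cell model.

The effector T-cell population ``T(t)`` is modelled as a Newtonian degree of
freedom subject to two opposing forces: an *antigenic force* proportional to
the pathogen load ``P(t)`` and a Hooke's-law *elastic force* restoring the
population toward its baseline.  The pathogen proliferates at a constant
per-capita rate and is cleared in proportion to its encounters with effector
cells:

    T''(t) = -k T(t) + lam P(t)
    P'(t)  = alpha P(t) - beta T(t) P(t)

All four rates are strictly positive.  The second-order term gives the T-cell
population *inertia*: expansion continues after the pathogen is gone, so the
onset of clonal contraction is delayed — the feature that distinguishes this
model from first-order predator–prey formulations.

A two-parameter non-dimensional form is obtained by rescaling time by the
elastic frequency and the state by the initial antigen load (see
:func:`to_reduced`), leaving a reduced growth rate ``alpha_star`` and a
reduced clearance strength ``beta_star`` — the axes of the
tolerance/elimination phase diagram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigurationError

__all__ = [
    "DimensionalParameters",
    "ReducedParameters",
    "InitialState",
    "CloneParameters",
    "SimulationControls",
    "rhs_single",
    "rhs_multi",
    "to_reduced",
    "from_reduced",
]


def _check_positive(obj: object, **fields: float) -> None:
    for name, value in fields.items():
        if not value > 0:
            raise ConfigurationError(
                f"{type(obj).__name__}.{name} must be strictly positive, got {value!r}"
            )


@dataclass(frozen=True)
class DimensionalParameters:
    """The four positive rates of the dimensional model.

    k     : elastic restoring coefficient (time^-2)
    lam   : antigenic force coefficient (T-cells / pathogen / time^2);
            proxies the TCR/epitope affinity of the clone
    alpha : pathogen per-capita growth rate (time^-1)
    beta  : clearance coefficient (1 / T-cell / time)
    """

    k: float
    lam: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _check_positive(self, k=self.k, lam=self.lam, alpha=self.alpha, beta=self.beta)


@dataclass(frozen=True)
class ReducedParameters:
    """Non-dimensional parameters: reduced growth rate and clearance strength."""

    alpha_star: float
    beta_star: float

    def __post_init__(self) -> None:
        _check_positive(self, alpha_star=self.alpha_star, beta_star=self.beta_star)


@dataclass(frozen=True)
class InitialState:
    """State at the instant of naive T-cell activation.

    The default starts with an empty effector pool at rest (T0 = dT0 = 0)
    facing a unit pathogen load.
    """

    T0: float = 0.0
    dT0: float = 0.0
    P0: float = 1.0

    def __post_init__(self) -> None:
        if self.T0 < 0:
            raise ConfigurationError(f"InitialState.T0 must be >= 0, got {self.T0!r}")
        if not self.P0 > 0:
            raise ConfigurationError(f"InitialState.P0 must be > 0, got {self.P0!r}")


@dataclass(frozen=True)
class CloneParameters:
    """Per-clone rates for the multi-clone extension.

    Each clone has its own elasticity ``k``, affinity ``lam`` and clearance
    ``beta``; all clones face the same pathogen.
    """

    label: str
    k: float
    lam: float
    beta: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ConfigurationError("CloneParameters.label must be non-empty")
        _check_positive(self, k=self.k, lam=self.lam, beta=self.beta)


@dataclass(frozen=True)
class SimulationControls:
    """Integration horizon, event thresholds and solver tolerances.

    p_min          : minimum pathogen load at which the pathogen is still
                     infective; crossing it downward marks pathogen control.
    peak_guard_eps : minimum excursion of T above its baseline before a
                     downward return to baseline counts as contraction end
                     (guards against spurious detection at t = 0).
    """

    t_max: float = 200.0
    p_min: float = 0.05
    peak_guard_eps: float = 1e-6
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    dt_out: float = 0.01

    def __post_init__(self) -> None:
        _check_positive(
            self,
            t_max=self.t_max,
            p_min=self.p_min,
            peak_guard_eps=self.peak_guard_eps,
            rel_tol=self.rel_tol,
            abs_tol=self.abs_tol,
            dt_out=self.dt_out,
        )


def rhs_single(
    state: Sequence[float], params: DimensionalParameters
) -> tuple[float, float, float]:
    """Time derivative of (T, V, P) where V = T' is the auxiliary velocity.

    Pure function; no domain restrictions are enforced here (the integrator
    owns event-based termination).
    """
    T, V, P = state[0], state[1], state[2]
    return (
        V,
        -params.k * T + params.lam * P,
        params.alpha * P - params.beta * T * P,
    )


def rhs_multi(
    state: Sequence[float],
    clones: Sequence[CloneParameters],
    alpha: float,
) -> tuple[float, ...]:
    """Time derivative of (T_1, V_1, ..., T_n, V_n, P) for n clones.

    Each clone is driven by the shared pathogen through its own affinity
    (lam_i * P) and contributes to clearance in proportion to its abundance
    (beta_i * T_i * P); the clearance contributions add.
    """
    if len(clones) == 0:
        raise ConfigurationError("rhs_multi requires at least one clone")
    n = len(clones)
    P = state[2 * n]
    out: list[float] = []
    clearance = 0.0
    for i, c in enumerate(clones):
        T = state[2 * i]
        V = state[2 * i + 1]
        out.append(V)
        out.append(-c.k * T + c.lam * P)
        clearance += c.beta * T
    out.append(alpha * P - clearance * P)
    return tuple(out)


def to_reduced(params: DimensionalParameters, P0: float) -> ReducedParameters:
    """Non-dimensionalize: alpha* = alpha/sqrt(k), beta* = beta*lam*P0/k^(3/2).

    Under tau = sqrt(k) t, x = T k / (lam P0), y = P / P0 the system becomes
    x'' = -x + y, y' = alpha* y - beta* x y with y(0) = 1: the elastic
    frequency sets the clock and the initial antigen load sets the scale, so
    alpha* measures pathogen growth per T-cell oscillation period and beta*
    the clearance strength of a unit reduced expansion.
    """
    if not P0 > 0:
        raise ConfigurationError(f"P0 must be > 0, got {P0!r}")
    sqrt_k = math.sqrt(params.k)
    return ReducedParameters(
        alpha_star=params.alpha / sqrt_k,
        beta_star=params.beta * params.lam * P0 / params.k**1.5,
    )


def from_reduced(rp: ReducedParameters) -> tuple[DimensionalParameters, InitialState]:
    """Canonical dimensional embedding of reduced parameters.

    Chooses k = 1, lam = 1, P0 = 1 so that alpha = alpha_star and
    beta = beta_star; the round trip through :func:`to_reduced` is exact.
    """
    params = DimensionalParameters(
        k=1.0, lam=1.0, alpha=rp.alpha_star, beta=rp.beta_star
    )
    init = InitialState(T0=0.0, dT0=0.0, P0=1.0)
    return params, init
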