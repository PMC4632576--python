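"""Parameter-space experiments on the tolerance/elimination dichotomy.

This module answers the model's population-level questions: for which
combinations of reduced growth rate and clearance strength does clonal
contraction complete while the target population persists (tolerance by
early contraction), where is the critical growth-rate threshold for a given
clone, how does that threshold move with TCR/epitope affinity, and how do
several clones share — and compensate within — a response.

Every sweep is deterministic and embarrassingly parallel per cell; cells
are integrated independently, so appending values to an axis never changes
previously computed cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BracketError, ConfigurationError, NumericalError
from .model_core import (
    CloneParameters,
    DimensionalParameters,
    InitialState,
    ReducedParameters,
    SimulationControls,
)
from .simulate import (
    ELIMINATION,
    TOLERANCE,
    UNRESOLVED,
    Outcome,
    classify,
    integrate,
    integrate_multi,
)

__all__ = [
    "OutcomeGrid",
    "ThresholdCurve",
    "ImmunodominanceResult",
    "CompensationResult",
    "AcuteVsToleratedResult",
    "phase_diagram",
    "critical_alpha",
    "threshold_vs_affinity",
    "immunodominance_experiment",
    "compensation_experiment",
    "acute_vs_tolerated",
]

logger = logging.getLogger(__name__)

#: coarser output sampling for sweeps — classification needs event times,
#: not a finely resolved trajectory
SWEEP_CONTROLS = SimulationControls(dt_out=0.2)


@dataclass
class OutcomeGrid:
    """Phase diagram over (alpha*, beta*): labels plus per-cell outcomes."""

    alpha_star_values: np.ndarray
    beta_star_values: np.ndarray
    labels: np.ndarray  # shape (n_beta, n_alpha), dtype object
    outcomes: list[list[Outcome | None]]
    controls_echo: SimulationControls

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per cell with outcome statistics."""
        rows = []
        for j, b in enumerate(self.beta_star_values):
            for i, a in enumerate(self.alpha_star_values):
                o = self.outcomes[j][i]
                rows.append(
                    {
                        "alpha_star": a,
                        "beta_star": b,
                        "label": self.labels[j, i],
                        "t_control": None if o is None else o.t_control,
                        "t_contraction_end": None if o is None else o.t_contraction_end,
                        "peak_T": None if o is None else o.peak_T,
                        "residual_P": None if o is None else o.residual_P,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ThresholdCurve:
    """Critical growth rate as a function of a swept clone parameter.

    Entries where no threshold exists (the clone eliminates every growth
    rate probed, however the bracket is widened) carry ``defined == False``
    and NaN — never a silent placeholder number.
    """

    sweep_values: np.ndarray
    critical_alpha: np.ndarray
    defined: np.ndarray
    bracket_echo: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sweep_value": self.sweep_values,
                "critical_alpha": self.critical_alpha,
                "defined": self.defined,
            }
        )


@dataclass
class ImmunodominanceResult:
    """Per-clone peak expansions in a joint response, ranked."""

    table: pd.DataFrame  # columns: label, lam, peak_T, t_peak
    outcome: Outcome
    ordering: list[str]  # clone labels sorted by descending peak


@dataclass
class CompensationResult:
    """Full vs depleted runs after removing one clone."""

    removed_label: str
    full_peaks: dict[str, float]
    depleted_peaks: dict[str, float]
    full_outcome: Outcome
    depleted_outcome: Outcome
    config_echo: dict


@dataclass
class AcuteVsToleratedResult:
    """Same clone versus a slow- and a fast-growing target population."""

    alpha_lo: float
    alpha_hi: float
    outcome_lo: Outcome
    outcome_hi: Outcome
    peak_ratio: float  # peak_T(alpha_hi) / peak_T(alpha_lo)
    config_echo: dict


def _classify_reduced(
    alpha_star: float, beta_star: float, controls: SimulationControls
) -> Outcome:
    traj = integrate(ReducedParameters(alpha_star, beta_star), controls=controls)
    return classify(traj, controls)


def phase_diagram(
    alpha_star_values: Sequence[float],
    beta_star_values: Sequence[float],
    controls: SimulationControls | None = None,
) -> OutcomeGrid:
    """Classify every (alpha*, beta*) cell of a rectangular grid.

    Integrator failures are recorded as UNRESOLVED with a logged warning so
    a sweep never aborts.
    """
    a_vals = np.asarray(alpha_star_values, dtype=float)
    b_vals = np.asarray(beta_star_values, dtype=float)
    for name, v in (("alpha_star_values", a_vals), ("beta_star_values", b_vals)):
        if v.size == 0:
            raise ConfigurationError(f"{name} must be non-empty")
        if np.any(v <= 0):
            raise ConfigurationError(f"{name} must be strictly positive")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise ConfigurationError(f"{name} must be strictly increasing")
    controls = controls if controls is not None else SWEEP_CONTROLS

    labels = np.empty((b_vals.size, a_vals.size), dtype=object)
    outcomes: list[list[Outcome | None]] = []
    for j, b in enumerate(b_vals):
        row: list[Outcome | None] = []
        for i, a in enumerate(a_vals):
            try:
                o = _classify_reduced(a, b, controls)
            except NumericalError as exc:
                logger.warning(
                    "cell (alpha*=%g, beta*=%g) failed numerically: %s", a, b, exc
                )
                o = None
            labels[j, i] = UNRESOLVED if o is None else o.label
            row.append(o)
        outcomes.append(row)
        logger.debug("phase diagram row beta*=%g done", b)
    return OutcomeGrid(a_vals, b_vals, labels, outcomes, controls)


def _label_fn_from_fixed(
    fixed: Mapping[str, float] | float,
    controls: SimulationControls,
):
    """Build alpha -> Outcome for a clone fixed in all parameters but alpha.

    ``fixed`` is either a bare number (the reduced clearance strength
    beta*) or a mapping with dimensional keys k, lam, beta and optional
    T0, dT0, P0.
    """
    if isinstance(fixed, (int, float)):
        beta_star = float(fixed)

        def label_fn(alpha: float) -> Outcome:
            return _classify_reduced(alpha, beta_star, controls)

        return label_fn

    allowed = {"k", "lam", "beta", "T0", "dT0", "P0"}
    unknown = set(fixed) - allowed
    if unknown:
        raise ConfigurationError(f"unknown fixed-parameter keys: {sorted(unknown)}")
    missing = {"k", "lam", "beta"} - set(fixed)
    if missing:
        raise ConfigurationError(f"missing fixed-parameter keys: {sorted(missing)}")
    init = InitialState(
        T0=float(fixed.get("T0", 0.0)),
        dT0=float(fixed.get("dT0", 0.0)),
        P0=float(fixed.get("P0", 1.0)),
    )

    def label_fn(alpha: float) -> Outcome:
        params = DimensionalParameters(
            k=float(fixed["k"]), lam=float(fixed["lam"]), alpha=alpha,
            beta=float(fixed["beta"]),
        )
        return classify(integrate(params, init, controls), controls)

    return label_fn


def critical_alpha(
    fixed: Mapping[str, float] | float,
    bracket: tuple[float, float],
    tol: float = 1e-4,
    controls: SimulationControls | None = None,
    verify: bool = True,
) -> float:
    """Bisect for the growth-rate threshold separating tolerance from elimination.

    The lower bracket endpoint must classify TOLERANCE and the upper
    ELIMINATION; bisection narrows the bracket to ``tol`` and returns its
    midpoint.  With ``verify`` the flanking classifications at +/- tol are
    re-checked.
    """
    controls = controls if controls is not None else SWEEP_CONTROLS
    lo, hi = bracket
    if not (0 < lo < hi):
        raise BracketError(f"bracket must satisfy 0 < lo < hi, got {bracket!r}")
    label_fn = _label_fn_from_fixed(fixed, controls)

    lab_lo = label_fn(lo).label
    lab_hi = label_fn(hi).label
    for name, lab in (("lower", lab_lo), ("upper", lab_hi)):
        if lab == UNRESOLVED:
            raise BracketError(
                f"{name} bracket endpoint is UNRESOLVED; increase t_max "
                f"(currently {controls.t_max})"
            )
    if not (lab_lo == TOLERANCE and lab_hi == ELIMINATION):
        raise BracketError(
            f"bracket endpoints must classify (TOLERANCE, ELIMINATION); "
            f"got ({lab_lo}, {lab_hi}) at alpha=({lo}, {hi})"
        )

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lab = label_fn(mid).label
        if lab == TOLERANCE:
            lo = mid
        elif lab == ELIMINATION:
            hi = mid
        else:
            raise BracketError(
                f"UNRESOLVED at alpha={mid}; increase t_max (currently {controls.t_max})"
            )
    crit = 0.5 * (lo + hi)

    if verify:
        below = label_fn(max(crit - tol, 0.5 * lo)).label
        above = label_fn(crit + tol).label
        if below != TOLERANCE or above != ELIMINATION:
            raise BracketError(
                f"post-verification failed at alpha_c={crit}: "
                f"({below} at -tol, {above} at +tol)"
            )
    return crit


def threshold_vs_affinity(
    lam_values: Sequence[float],
    fixed: Mapping[str, float],
    controls: SimulationControls | None = None,
    bracket: tuple[float, float] = (0.05, 3.0),
    tol: float = 1e-4,
    max_widenings: int = 10,
) -> ThresholdCurve:
    """Critical growth rate as a function of the affinity coefficient lam.

    For each lam the bracket is re-validated: the lower endpoint is halved
    while it classifies ELIMINATION (high-affinity clones push the
    threshold down) and the upper endpoint doubled while it classifies
    TOLERANCE.  A lam for which no valid bracket emerges — the clone
    eliminates the target at every growth rate probed — is marked
    undefined.
    """
    lam_arr = np.asarray(lam_values, dtype=float)
    if lam_arr.size == 0 or np.any(lam_arr <= 0):
        raise ConfigurationError("lam_values must be non-empty and positive")
    if lam_arr.size > 1 and np.any(np.diff(lam_arr) <= 0):
        raise ConfigurationError("lam_values must be strictly increasing")
    controls = controls if controls is not None else SWEEP_CONTROLS
    base = dict(fixed)
    base.pop("lam", None)

    crit = np.full(lam_arr.size, np.nan)
    defined = np.zeros(lam_arr.size, dtype=bool)
    for idx, lam in enumerate(lam_arr):
        this = {**base, "lam": float(lam)}
        label_fn = _label_fn_from_fixed(this, controls)
        lo, hi = bracket
        ok = True
        for _ in range(max_widenings):
            if label_fn(lo).label != ELIMINATION:
                break
            lo *= 0.5
        else:
            ok = False
        if ok:
            for _ in range(max_widenings):
                if label_fn(hi).label != TOLERANCE:
                    break
                hi *= 2.0
            else:
                ok = False
        if ok and label_fn(lo).label == TOLERANCE and label_fn(hi).label == ELIMINATION:
            crit[idx] = critical_alpha(this, (lo, hi), tol=tol, controls=controls,
                                       verify=False)
            defined[idx] = True
        else:
            logger.info("lam=%g: no tolerance/elimination bracket; marked undefined", lam)
    return ThresholdCurve(
        sweep_values=lam_arr,
        critical_alpha=crit,
        defined=defined,
        bracket_echo={"bracket": list(bracket), "tol": tol, "max_widenings": max_widenings},
    )


def _clone_peaks(traj) -> dict[str, tuple[float, float]]:
    """Per-clone (peak_T, t_peak) read off the dense trajectory."""
    peaks = {}
    for col_idx in traj.t_indices:
        name = traj.columns[col_idx]
        label = name[2:] if name.startswith("T_") else name
        series = traj.states[:, col_idx]
        i = int(np.argmax(series))
        peaks[label] = (float(series[i]), float(traj.times[i]))
    return peaks


def immunodominance_experiment(
    clones: Sequence[CloneParameters],
    alpha: float,
    controls: SimulationControls | None = None,
    P0: float = 1.0,
) -> ImmunodominanceResult:
    """Joint response of several clones: who expands most.

    Clones with higher affinity for the shared antigen expand more
    (immunodominance); the returned ordering makes the ranking explicit.
    """
    if len(clones) < 2:
        raise ConfigurationError("immunodominance requires at least 2 clones")
    controls = controls if controls is not None else SimulationControls()
    traj = integrate_multi(clones, alpha, P0=P0, controls=controls)
    outcome = classify(traj, controls)
    peaks = _clone_peaks(traj)
    table = pd.DataFrame(
        [
            {"label": c.label, "lam": c.lam, "peak_T": peaks[c.label][0],
             "t_peak": peaks[c.label][1]}
            for c in clones
        ]
    )
    ordering = list(table.sort_values("peak_T", ascending=False)["label"])
    return ImmunodominanceResult(table=table, outcome=outcome, ordering=ordering)


def compensation_experiment(
    clones: Sequence[CloneParameters],
    removed_label: str,
    alpha: float,
    controls: SimulationControls | None = None,
    P0: float = 1.0,
) -> CompensationResult:
    """Compare the full repertoire with the same repertoire minus one clone.

    Quantifies compensatory expansion: surviving clones take up the
    clearance left behind by the removed (typically dominant) clone.
    """
    if len(clones) < 2:
        raise ConfigurationError("compensation requires at least 2 clones")
    labels = [c.label for c in clones]
    if removed_label not in labels:
        raise ConfigurationError(
            f"removed_label {removed_label!r} not among clones {labels}"
        )
    controls = controls if controls is not None else SimulationControls()
    depleted = [c for c in clones if c.label != removed_label]

    traj_full = integrate_multi(clones, alpha, P0=P0, controls=controls)
    traj_depl = integrate_multi(depleted, alpha, P0=P0, controls=controls)
    peaks_full = {k: v[0] for k, v in _clone_peaks(traj_full).items()}
    peaks_depl = {k: v[0] for k, v in _clone_peaks(traj_depl).items()}
    return CompensationResult(
        removed_label=removed_label,
        full_peaks=peaks_full,
        depleted_peaks=peaks_depl,
        full_outcome=classify(traj_full, controls),
        depleted_outcome=classify(traj_depl, controls),
        config_echo={
            "clones": [
                {"label": c.label, "k": c.k, "lam": c.lam, "beta": c.beta}
                for c in clones
            ],
            "removed_label": removed_label,
            "alpha": alpha,
            "P0": P0,
        },
    )


def acute_vs_tolerated(
    fixed: Mapping[str, float] | float,
    alpha_lo: float,
    alpha_hi: float,
    controls: SimulationControls | None = None,
) -> AcuteVsToleratedResult:
    """One clone against a slow- and a fast-growing target population.

    The slow target must be tolerated and the fast one eliminated; the
    result reports both peaks and their ratio.  The comparison itself
    asserts nothing — the observation that the *eliminated* fast-growing
    target provokes the larger expansion lives in the caller (and the test
    suite).
    """
    if not alpha_lo < alpha_hi:
        raise BracketError(
            f"alpha_lo must be < alpha_hi, got ({alpha_lo}, {alpha_hi})"
        )
    controls = controls if controls is not None else SimulationControls()
    label_fn = _label_fn_from_fixed(fixed, controls)
    out_lo = label_fn(alpha_lo)
    out_hi = label_fn(alpha_hi)
    if out_lo.label != TOLERANCE or out_hi.label != ELIMINATION:
        raise BracketError(
            f"expected (TOLERANCE, ELIMINATION) at alpha=({alpha_lo}, {alpha_hi}); "
            f"got ({out_lo.label}, {out_hi.label})"
        )
    return AcuteVsToleratedResult(
        alpha_lo=alpha_lo,
        alpha_hi=alpha_hi,
        outcome_lo=out_lo,
        outcome_hi=out_hi,
        peak_ratio=out_hi.peak_T / out_lo.peak_T,
        config_echo={"fixed": fixed if isinstance(fixed, (int, float)) else dict(fixed),
                     "alpha_lo": alpha_lo, "alpha_hi": alpha_hi},
    )
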