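"""Frozen parameter presets for each qualitative regime of the model.

The model's own literature reports no numeric parameter values, so each
preset here was discovered by a coarse grid search over the reduced
(alpha*, beta*) plane against the qualitative criteria it is meant to
reproduce (acute response with delayed contraction; tolerance by early
contraction; immunodominance ranking; compensatory expansion) and then
frozen.  Preset ids are stable across releases: they anchor the regression
and oracle-equivalence suites.

Every preset value is a plain JSON-compatible dict validated against the
config schemas in :mod:`clonaldyn.cli_io`.
"""

from __future__ import annotations

from .errors import ConfigurationError

__all__ = ["PRESETS", "ORACLE_SUITE", "get_preset", "preset_ids"]


def _reduced(alpha_star: float, beta_star: float) -> dict:
    return {
        "kind": "run",
        "config": {
            "mode": "reduced",
            "reduced": {"alpha_star": alpha_star, "beta_star": beta_star},
        },
    }


#: id -> {kind, config, note, expected_label?}
PRESETS: dict[str, dict] = {
    # -- single-clone reduced regimes: acute responses (elimination with the
    #    peak of clonal expansion after pathogen control, i.e. delayed
    #    contraction) --
    "acute": {
        **_reduced(2.5, 1.0),
        "note": (
            "Acute infection: fast-growing target eliminated; clonal expansion "
            "peaks after the pathogen falls below its infectivity threshold "
            "(delayed onset of contraction). Found by grid search, frozen."
        ),
        "expected_label": "ELIMINATION",
    },
    "acute-strong-clearance": {
        **_reduced(2.0, 2.0),
        "note": "Acute regime with stronger clearance; smaller peak, same outcome.",
        "expected_label": "ELIMINATION",
    },
    "acute-fast-growth": {
        **_reduced(3.0, 0.5),
        "note": "Very fast-growing target; large clonal expansion before control.",
        "expected_label": "ELIMINATION",
    },
    "acute-high-clearance": {
        **_reduced(1.5, 3.0),
        "note": "High-affinity/high-clearance clone eliminating a moderate grower.",
        "expected_label": "ELIMINATION",
    },
    "acute-weak-expansion": {
        **_reduced(1.0, 4.0),
        "note": "Clearance so strong the response stays small yet still eliminates.",
        "expected_label": "ELIMINATION",
    },
    # -- tolerance by early contraction: contraction completes while the
    #    target persists above its infectivity threshold --
    "tolerated": {
        **_reduced(0.3, 0.5),
        "note": (
            "Slow-growing target tolerated: clonal contraction completes with "
            "residual pathogen above threshold (early contraction)."
        ),
        "expected_label": "TOLERANCE",
    },
    "tolerated-moderate": {
        **_reduced(0.5, 0.5),
        "note": "Tolerance at a moderate growth rate, same clone as 'tolerated'.",
        "expected_label": "TOLERANCE",
    },
    "tolerated-mid-growth": {
        **_reduced(1.0, 0.3),
        "note": "Weak-clearance clone tolerating a mid-range growth rate.",
        "expected_label": "TOLERANCE",
    },
    "tolerated-weak-clearance": {
        **_reduced(1.8, 0.1),
        "note": (
            "Very weak clearance: even a fast grower is tolerated — large "
            "expansion, yet contraction ends first."
        ),
        "expected_label": "TOLERANCE",
    },
    "tolerated-slow-growth": {
        **_reduced(0.05, 0.7),
        "note": "Near-static target population; tolerated by early contraction.",
        "expected_label": "TOLERANCE",
    },
    # -- multi-clone regimes --
    "two-clone": {
        "kind": "run",
        "config": {
            "mode": "multi",
            "multi": {
                "alpha": 1.0,
                "P0": 1.0,
                "clones": [
                    {"label": "clone1", "k": 1.0, "lam": 2.0, "beta": 1.0},
                    {"label": "clone2", "k": 1.0, "lam": 1.2, "beta": 1.0},
                ],
            },
        },
        "note": (
            "Dominant/subdominant pair: clone1 (higher affinity) expands more; "
            "removing it still controls the infection via compensatory "
            "expansion of clone2. Chosen so both the full and the depleted "
            "repertoires eliminate."
        ),
        "expected_label": "ELIMINATION",
    },
    "three-clone": {
        "kind": "run",
        "config": {
            "mode": "multi",
            "multi": {
                "alpha": 1.0,
                "P0": 1.0,
                "clones": [
                    {"label": "c1", "k": 1.0, "lam": 3.0, "beta": 0.3334},
                    {"label": "c2", "k": 1.0, "lam": 2.0, "beta": 0.3333},
                    {"label": "c3", "k": 1.0, "lam": 1.0, "beta": 0.3333},
                ],
            },
        },
        "note": (
            "Immunodominance hierarchy: affinities lam1 > lam2 > lam3 produce "
            "identically ordered peak expansions."
        ),
        "expected_label": "ELIMINATION",
    },
    # -- comparison / sweep presets --
    "acute-vs-tolerated": {
        "kind": "compare",
        "config": {
            "fixed": {"beta_star": 0.5},
            "alpha_lo": 0.3,
            "alpha_hi": 2.5,
        },
        "note": (
            "One clone against a slow (tolerated) and a fast (eliminated) "
            "target: the eliminated fast grower provokes the larger clonal "
            "expansion, so tolerance is not an expansion-capacity limit."
        ),
    },
    "affinity-sweep": {
        "kind": "threshold",
        "config": {
            "lam_values": [0.4, 0.7, 1.0, 1.5, 2.0, 3.0],
            "fixed": {"k": 1.0, "beta": 0.5, "P0": 1.0},
            "bracket": [0.05, 3.0],
            "tol": 1e-4,
        },
        "note": (
            "Critical growth rate versus TCR/epitope affinity (lam): higher "
            "affinity lowers the tolerated growth-rate threshold until no "
            "tolerance remains (threshold undefined)."
        ),
    },
}

#: the ten single-clone presets used for adaptive-vs-RK4 oracle equivalence,
#: five per outcome label
ORACLE_SUITE: tuple[str, ...] = (
    "acute",
    "acute-strong-clearance",
    "acute-fast-growth",
    "acute-high-clearance",
    "acute-weak-expansion",
    "tolerated",
    "tolerated-moderate",
    "tolerated-mid-growth",
    "tolerated-weak-clearance",
    "tolerated-slow-growth",
)


def preset_ids() -> list[str]:
    return list(PRESETS)


def get_preset(preset_id: str) -> dict:
    try:
        return PRESETS[preset_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {preset_id!r}; available: {', '.join(PRESETS)}"
        ) from None
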