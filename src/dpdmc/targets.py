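"""Machine-readable validation targets for the full-scale reference system.

These are the expectations for the full-size study system — the (40 R_c)^3
box with 1.92e5 beads run for 5e5 to 5e6 steps — recorded here so that a
cluster-scale validation campaign can check them mechanically.  Desk-scale
runs (boxes of 12-20 R_c) reproduce the morphology classes and the
qualitative trends but not these quantitative values, which is why every
entry carries ``desk_scale: False`` and is *not* asserted by the desk-scale
test suite.
"""

from __future__ import annotations

FULL_SCALE_TARGETS: tuple[dict, ...] = (
    {
        "name": "aggregate_order_parameter",
        "description": "Equilibrium segregation order parameter of the "
                       "whole aggregates (polymer vs solvent).",
        "value": 0.514,
        "tolerance": 0.001,
        "units": "dimensionless",
        "desk_scale": False,
        "setup": {"box_edge": 40.0, "rho": 3.0,
                  "composition": {"A19": 4, "A1S6": 13, "S6": 3, "W": 80},
                  "n_steps_min": 500_000},
    },
    {
        "name": "core_order_parameter",
        "description": "Equilibrium segregation order parameter of the "
                       "solvophobic cores.",
        "value": 0.134,
        "tolerance": 0.001,
        "units": "dimensionless",
        "desk_scale": False,
        "setup": {"box_edge": 40.0, "rho": 3.0,
                  "composition": {"A19": 4, "A1S6": 13, "S6": 3, "W": 80},
                  "n_steps_min": 500_000},
    },
    {
        "name": "spherical_multicore_aAW_threshold",
        "description": "Solvophobe-solvent repulsion above which the "
                       "equilibrated assemblies are spherical multicore.",
        "value": 95.0,
        "units": "reduced energy / R_c",
        "desk_scale": False,
        "setup": {"sweep": "a_AW", "grid_range": [35, 115]},
    },
    {
        "name": "multicompartment_aSW_threshold",
        "description": "Solvophile-solvent repulsion above which "
                       "multicore-multicompartment assemblies form.",
        "value": 45.0,
        "units": "reduced energy / R_c",
        "desk_scale": False,
        "setup": {"sweep": "a_SW", "grid_range": [30, 115]},
    },
)
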