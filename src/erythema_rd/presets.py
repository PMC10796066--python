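"""Named parameter presets for the simulated erythema conditions.

Two reference points anchor the parameter plane: the census baseline
(p_a = 0.05, q_a = 3.0, r_a = 0.8, p_i = 0.12, q_i = 6.0 with
D_a = D_i = 0.3, n = 2) and the shrinkage set.  The per-pattern
simulation sets are synthetic stand-ins calibrated within this
package: each expanding-pattern point was located by scanning the
production parameter plane around the anchor until the named
morphology emerges robustly.  Lowering q_a toward propagation failure
gives fading, the near-failure margin gives arcuate fragments, the
oscillatory excitable core gives gyrate and polycyclic, and the
bistable band at higher q_a or depleted p_i gives annular and
circular.
"""

from __future__ import annotations

from .model_core import Params

__all__ = ["CENSUS_BASELINE", "SHRINKAGE", "FADING", "FADING_FAST",
           "EXPANDING_PRESETS", "EXPANDING_SIM_SETTINGS", "preset_params",
           "PRESET_NAMES"]

#: reference point anchoring the production parameter plane;
#: excitable census (1 stable + 2 unstable) with an oscillatory
#: upper focus
CENSUS_BASELINE = Params(p_a=0.05, q_a=3.0, r_a=0.8, p_i=0.12, q_i=6.0,
                         D_a=0.3, D_i=0.3, n=2)

#: fully printed shrinkage set: bistable, threshold state nearer the
#: inflamed state, fronts retreat
SHRINKAGE = Params(p_a=0.03, q_a=2.0, r_a=0.99, p_i=0.02, q_i=6.0,
                   D_a=0.3, D_i=0.3, n=2)

#: calibrated healthy condition: excitable, waves fail to propagate,
#: a stimulated disk clears interior-first and disappears (slow)
FADING = CENSUS_BASELINE.with_(q_a=2.45)

#: further reduced activator production: larger healthy-threshold
#: distance, quicker disappearance
FADING_FAST = CENSUS_BASELINE.with_(q_a=2.3)

#: calibrated synthetic stand-ins for the five expanding morphologies;
#: arcuate, polycyclic and gyrate sit on the q_a axis between the
#: fading condition and the bistable band
EXPANDING_PRESETS: dict[str, Params] = {
    "arcuate": CENSUS_BASELINE.with_(q_a=2.5),
    "polycyclic": CENSUS_BASELINE.with_(q_a=2.54),
    "gyrate": CENSUS_BASELINE,
    "annular": CENSUS_BASELINE.with_(q_a=3.5),
    "circular": CENSUS_BASELINE.with_(q_a=3.5, p_i=0.03),
}

#: (grid edge, t_end) at which each preset's morphology is fully
#: developed — the sizes used by the acceptance checks
EXPANDING_SIM_SETTINGS: dict[str, tuple[int, float]] = {
    "arcuate": (128, 160.0),
    "polycyclic": (128, 200.0),
    "gyrate": (128, 180.0),
    "annular": (96, 80.0),
    "circular": (96, 60.0),
}

PRESET_NAMES = ("census_baseline", "shrinkage", "fading", "fading_fast",
                *EXPANDING_PRESETS)


def preset_params(name: str) -> Params:
    """Look up a named parameter preset."""
    table = {"census_baseline": CENSUS_BASELINE, "shrinkage": SHRINKAGE,
             "fading": FADING, "fading_fast": FADING_FAST,
             **EXPANDING_PRESETS}
    try:
        return table[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; valid: {PRESET_NAMES}") \
            from None
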