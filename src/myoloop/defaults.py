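"""Reference parameterization of the closed-loop model.

One versioned set of defaults for a resting adult: sarcomere constitutive
constants, wall volumes and midwall reference areas, circulation
resistances/compliances, valve constants, and the homeostatic regulation
targets (mean arterial pressure 92 mmHg, stroke volume 72 ml at 71 bpm).
Scenario code copies and overrides this dictionary; nothing mutates it in
place.
"""

from __future__ import annotations

import copy

__all__ = ["reference_config"]

_REFERENCE = {
    "heart_rate": 71.0,           # bpm
    "ls_ref": 2.0,                # um; zero-strain sarcomere length
    "solver": {
        "dt": 0.002,              # s; maximum (and output) timestep
        "err_tol": 5e-4,          # relative local-error acceptance
    },
    "activation": {
        "t_ventricle": 0.16,      # s after cycle start (AV delay)
        "t_atria": 0.0,
    },
    # ventricular myofiber constitutive defaults
    "sarcomere": {
        "Sf_act": 290.0,          # kPa/um
        "Sf_pas": 1.5,            # kPa
        "Ls0_pas": 1.75,          # um
        "k_ECM": 10.0,
        "k1_tit": 0.012,
        "k2_tit": 4.0,
        "Lsi0_act": 1.51,         # um
        "Lse_iso": 0.04,          # um
        "CD": 0.45,               # s
        "v_max": 7.0,             # um/s
        "C_rest": 0.0,
    },
    "atrial_sarcomere": {
        "Sf_act": 60.0,
        "CD": 0.20,
        "v_max": 14.0,
        "Sf_pas": 1.4,
    },
    # wall volume (ml) and midwall reference area (cm^2) at Ls = ls_ref
    "walls": {
        "lv": {"wall_volume": 125.0, "am_ref": 139.0,
               "patches": [{"share": 1.0}]},
        "sw": {"wall_volume": 64.0, "am_ref": 72.0,
               "patches": [{"share": 1.0}]},
        "rv": {"wall_volume": 42.0, "am_ref": 168.0,
               "patches": [{"share": 1.0}]},
        "la": {"wall_volume": 12.0, "am_ref": 55.0,
               "patches": [{"share": 1.0}]},
        "ra": {"wall_volume": 8.0, "am_ref": 60.0,
               "patches": [{"share": 1.0}]},
    },
    "circulation": {
        "r_sys": 1.03,            # mmHg*s/ml, peripheral arterial resistance
        "r_pulm": 0.08,
        "r_sys_venous": 0.025,    # systemic venous return
        "r_pulm_venous": 0.015,   # pulmonary venous return
        "c_syart": 1.3,           # ml/mmHg
        "c_syven": 45.0,
        "c_puart": 5.0,
        "c_puven": 12.0,
        "v0_syart": 60.0,         # ml, unstressed volumes
        "v0_syven": 400.0,
        "v0_puart": 30.0,
        "v0_puven": 60.0,
        "valve_inertance": 6e-4,  # mmHg*s^2/ml
        "valve_resistance": 1.5e-3,
        "bernoulli": {"mi": 1.1e-5, "ao": 2.0e-5,
                      "tr": 8.0e-6, "pu": 1.6e-5},
        "init_pressures": {"syart": 92.0, "syven": 6.0,
                           "puart": 15.0, "puven": 9.0},
        "init_volumes": {"lv": 125.0, "rv": 125.0, "la": 60.0, "ra": 60.0},
    },
    "regulation": {
        "enabled": True,
        "map": 92.0,              # mmHg target
        "sv": 72.0,               # ml target
        "gain_r": 0.5,            # exponent on MAP error for R update
        "gain_v": 3.0,            # ml venous volume per ml SV error
    },
}


def reference_config() -> dict:
    """A deep copy of the reference parameterization."""
    return copy.deepcopy(_REFERENCE)
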