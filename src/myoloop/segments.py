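"""18-segment left-ventricular segmentation.

Standard echocardiographic 18-segment scheme: three levels (basal, mid,
apical) by six circumferential walls.  Anteroseptal and inferoseptal
segments belong to the septal wall of the model (6 patches); the remaining
twelve map to the LV free wall.  Per-level volume weights approximate the
tapering of the ventricle toward the apex.
"""

from __future__ import annotations

import numpy as np

from .heart import HeartModel

__all__ = ["SEGMENTS_18", "SEGMENT_WALL", "segment_shares",
           "build_segment_model", "SEPTAL_SEGMENTS"]

_LEVELS = ("basal", "mid", "apical")
_WALLS = ("anterior", "anteroseptal", "inferoseptal",
          "inferior", "inferolateral", "anterolateral")
_LEVEL_WEIGHT = {"basal": 1.2, "mid": 1.0, "apical": 0.7}

SEGMENTS_18 = tuple(f"{lvl}_{w}" for lvl in _LEVELS for w in _WALLS)
SEPTAL_SEGMENTS = tuple(s for s in SEGMENTS_18 if "septal" in s)
SEGMENT_WALL = {s: ("sw" if "septal" in s else "lv") for s in SEGMENTS_18}


def segment_shares() -> dict:
    """Within-wall volume share of each segment (shares sum to 1 per wall)."""
    shares = {}
    for wall in ("lv", "sw"):
        segs = [s for s in SEGMENTS_18 if SEGMENT_WALL[s] == wall]
        w = np.array([_LEVEL_WEIGHT[s.split("_")[0]] for s in segs])
        w = w / w.sum()
        shares.update(dict(zip(segs, w)))
    return shares


def build_segment_model(heart_rate: float = 71.0,
                        map_target: float = 92.0,
                        sv_target: float = 72.0,
                        overrides: dict | None = None) -> HeartModel:
    """Closed-loop model whose LV free wall + septum carry the 18 segments."""
    shares = segment_shares()
    patches = {"lv": [], "sw": []}
    for s in SEGMENTS_18:
        patches[SEGMENT_WALL[s]].append({"share": shares[s], "name": s})
    cfg = {
        "heart_rate": heart_rate,
        "regulation": {"map": map_target, "sv": sv_target, "enabled": True},
        "walls": {"lv": {"patches": patches["lv"]},
                  "sw": {"patches": patches["sw"]}},
    }
    if overrides:
        from .heart import _merge
        cfg = _merge(cfg, overrides)
    return HeartModel(cfg)
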