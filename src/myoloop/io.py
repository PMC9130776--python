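"""File formats and run reproducibility plumbing.

Strain datasets travel as plain-text delimited tables: '#' comment lines,
a metadata block (heart rate, EDV, EF) in comments, a header row with
``time`` plus the 18 segment ids, then one row per sample (time in
seconds, strain in percent, '.' decimal).  Configurations are YAML;
results and manifests are JSON.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import yaml

from .estimation import N_SEG, SegmentDataset
from .segments import SEGMENTS_18

__all__ = ["read_dataset", "write_dataset", "read_config", "write_config",
           "write_manifest", "write_json"]


def write_dataset(path, ds: SegmentDataset) -> None:
    """Write an 18-segment dataset as delimited text with '#' metadata."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# 18-segment longitudinal strain dataset\n")
        fh.write(f"# heart_rate_bpm: {ds.heart_rate:.6g}\n")
        fh.write(f"# edv_ml: {ds.edv:.6g}\n")
        fh.write(f"# ef_percent: {ds.ef:.6g}\n")
        fh.write("time\t" + "\t".join(ds.segments) + "\n")
        for k in range(ds.time.size):
            row = "\t".join(f"{v:.6g}" for v in ds.strain[k])
            fh.write(f"{ds.time[k]:.6g}\t{row}\n")


def read_dataset(path) -> SegmentDataset:
    """Parse a dataset file, validating segment count and time ordering."""
    path = Path(path)
    meta = {}
    header = None
    rows = []
    with path.open() as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        pass
                continue
            if header is None:
                header = line.split("\t")
                if len(header) < 2 or header[0] != "time":
                    raise ValueError(
                        f"{path}:{ln}: expected header 'time<TAB>segments...'")
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{ln}: {len(parts)} fields, expected "
                    f"{len(header)}")
            rows.append([float(v) for v in parts])
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    segments = tuple(header[1:])
    missing = [s for s in SEGMENTS_18 if s not in segments]
    if len(segments) != N_SEG or missing:
        raise ValueError(
            f"{path}: expected {N_SEG} segments, got {len(segments)}"
            + (f"; missing {missing}" if missing else ""))
    data = np.array(rows)
    for key in ("heart_rate_bpm", "edv_ml", "ef_percent"):
        if key not in meta:
            raise ValueError(f"{path}: missing metadata '{key}'")
    # reorder columns into canonical segment order
    order = [segments.index(s) for s in SEGMENTS_18]
    return SegmentDataset(time=data[:, 0], strain=data[:, 1:][:, order],
                          heart_rate=meta["heart_rate_bpm"],
                          edv=meta["edv_ml"], ef=meta["ef_percent"],
                          segments=SEGMENTS_18)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


def write_manifest(outdir, config: dict, seed: int | None,
                   command: str) -> None:
    """Record what produced a run: command, config hash, seed, versions."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "command": command,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "myoloop_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
    }
    write_json(Path(outdir) / "manifest.json", manifest)
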