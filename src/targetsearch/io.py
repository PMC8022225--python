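"""File formats, configuration and report plumbing.

Package-wide conventions: lengths in µm, times in s, diffusion in µm²/s,
masses in kDa, footprints in bp; frames are 0-based; positions are
continuous coordinates with the centre of pixel i at (i + 0.5)·pixel_size.

Tabular data is plain CSV:

* localizations — ``frame,x_um,y_um,cell_id[,track_id]``
* tracks        — ``track_id,frame,x_um,y_um[,cell_id]``
* geometry      — ``axial_start_um,axial_end_um,radius_um``

Reports are JSON with embedded provenance (config, seeds, version).
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import CellGeometry
from .models import AcquisitionModel, MotionModel

__all__ = [
    "read_localizations",
    "write_localizations",
    "read_tracks",
    "write_tracks",
    "read_geometry",
    "write_geometry",
    "load_config",
    "motion_from_config",
    "acquisition_from_config",
    "write_report",
]

_LOC_COLUMNS = ["frame", "x_um", "y_um", "cell_id"]
_TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


def write_localizations(locs: pd.DataFrame, path):
    cols = [c for c in _LOC_COLUMNS + ["track_id"] if c in locs.columns]
    locs[cols].to_csv(path, index=False)


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("frame", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise ValueError(f"localization table missing columns: {missing}")
    return df


def write_tracks(tracks: pd.DataFrame, path):
    cols = [c for c in _TRACK_COLUMNS + ["cell_id"] if c in tracks.columns]
    tracks[cols].to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracks table missing columns: {missing}")
    return df


def write_geometry(geom: CellGeometry, path):
    geom.to_frame().to_csv(path, index=False)


def read_geometry(path) -> CellGeometry:
    return CellGeometry.from_frame(pd.read_csv(path))


def load_config(path) -> dict:
    """YAML key-value config mirroring the model field names."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def motion_from_config(cfg: dict) -> MotionModel:
    keys = ("d_free", "d_bound", "switching_enabled", "mean_t_bound", "mean_t_free")
    kwargs = {k: cfg[k] for k in keys if k in cfg}
    if "phi" in cfg:
        return MotionModel.from_phi(
            cfg["d_free"],
            cfg["phi"],
            cfg.get("d_bound", 0.04),
            cfg.get("mean_t_bound", 0.001),
        )
    return MotionModel(**kwargs)


def acquisition_from_config(cfg: dict) -> AcquisitionModel:
    keys = ("frame_interval", "n_subframes", "sigma_loc", "bleach_mean",
            "movie_frames", "pixel_size")
    return AcquisitionModel(**{k: cfg[k] for k in keys if k in cfg})


def _jsonify(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(payload: dict, path, config: dict | None = None, seed: int | None = None):
    """JSON report with provenance (config, seed, package version)."""
    doc = {
        "version": __version__,
        "config": _jsonify(config or {}),
        "seed": seed,
        **_jsonify(payload),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc
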