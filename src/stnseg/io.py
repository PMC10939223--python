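"""File I/O: MER tables, world transforms, fitted transforms and configs.

Volumes and labels are NIfTI-1 (see :mod:`stnseg.volume`), meshes PLY or
legacy VTK (see :mod:`stnseg.mesh`).  MER tables are CSV with the header
``trajectory,depth_mm,x_mm,y_mm,z_mm,nrms,label``; world-to-world transforms
are plain-text row-major 4x4 matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mer import FitTransform, MerTrajectorySet

MER_COLUMNS = ["trajectory", "depth_mm", "x_mm", "y_mm", "z_mm", "nrms", "label"]
_LABEL_MAP = {"in": "IN", "stn": "IN", "1": "IN", "out": "OUT", "0": "OUT", "": "unknown",
              "unknown": "unknown", "nan": "unknown"}


def load_mer_table(path: str | Path) -> MerTrajectorySet:
    """Read a MER site table, validating depth monotonicity per trajectory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(MER_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"MER table {path} missing columns {sorted(missing)}")
    if "label" in df.columns:
        df["label"] = (
            df["label"].astype(str).str.strip().str.lower().map(_LABEL_MAP).fillna("unknown")
        )
    for traj, grp in df.groupby("trajectory"):
        depths = grp["depth_mm"].to_numpy()
        if len(np.unique(depths)) != len(depths):
            raise ValueError(f"duplicate depth rows in trajectory {traj!r}")
        if not np.all(np.diff(depths) > 0) and not np.all(np.diff(depths[::-1]) > 0):
            # rows may be stored in any consistent order; require strict monotonicity
            if not (np.all(np.diff(np.sort(depths)) > 0)):
                raise ValueError(f"non-monotone depth within trajectory {traj!r}")
    return MerTrajectorySet(df)


def save_mer_table(sites: MerTrajectorySet, path: str | Path) -> None:
    sites.sites.to_csv(path, index=False, columns=[c for c in MER_COLUMNS if c in sites.sites.columns])


def load_world_transform(path: str | Path) -> np.ndarray:
    """Plain-text row-major 4x4 world-to-world affine."""
    mat = np.loadtxt(path)
    if mat.shape != (4, 4):
        raise ValueError(f"transform in {path} is not 4x4")
    return mat


def save_world_transform(mat: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mat, dtype=float), fmt="%.9g")


def save_fit_transform(transform: FitTransform, path: str | Path) -> None:
    payload = {"translation_mm": transform.t.tolist(), "scaling": transform.s.tolist(),
               "converged": bool(transform.converged)}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fit_transform(path: str | Path) -> FitTransform:
    payload = json.loads(Path(path).read_text())
    return FitTransform(
        t=np.asarray(payload["translation_mm"], dtype=float),
        s=np.asarray(payload["scaling"], dtype=float),
        converged=bool(payload.get("converged", True)),
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
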