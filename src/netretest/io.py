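"""NIfTI volume, manifest and config I/O.

Volumes are NIfTI-1, float32 on disk, float64 in memory.  The 4th dimension
is time for BOLD series and network for template stacks.  Masks go out as
uint8.  The manifest is a CSV with columns subject_id, group, session, path;
every subject must have exactly one BL and one FU row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import (
    GROUPS,
    GridMismatchError,
    NetworkMask,
    SESSIONS,
    SimulationConfig,
    TemplateSet,
)

MANIFEST_COLUMNS = ("subject_id", "group", "session", "path")


def read_volume(path) -> Tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (float64 data, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:  # nibabel raises several unrelated types
        raise IOError(f"failed to read NIfTI volume {path}: {exc}") from exc
    return data, np.asarray(img.affine)


def write_volume(data: np.ndarray, affine: np.ndarray, path, dtype=np.float32) -> None:
    path = Path(path)
    try:
        img = nib.Nifti1Image(np.asarray(data, dtype=dtype), np.asarray(affine))
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"failed to write NIfTI volume {path}: {exc}") from exc


def check_grid(data: np.ndarray, expected: Sequence[int], what: str = "volume") -> None:
    if tuple(data.shape[:3]) != tuple(expected):
        raise GridMismatchError(
            f"{what} grid {tuple(data.shape[:3])} does not match expected grid "
            f"{tuple(expected)}"
        )


def read_template_set(path, names: Optional[Sequence[str]] = None) -> TemplateSet:
    """Load a 4D template stack (4th dimension = network)."""
    data, affine = read_volume(path)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise IOError(f"template stack {path} must be 4D, got {data.ndim}D")
    maps = np.moveaxis(data, -1, 0)
    if names is None:
        names = [f"network{j:02d}" for j in range(maps.shape[0])]
    return TemplateSet(maps=maps, names=list(names), affine=affine)


def write_template_set(templates: TemplateSet, path) -> None:
    write_volume(np.moveaxis(templates.maps, 0, -1), templates.affine, path)


def write_mask(mask: NetworkMask, affine: np.ndarray, path) -> None:
    write_volume(mask.voxels.astype(np.uint8), affine, path, dtype=np.uint8)


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate the subject-session manifest."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest {path} is missing columns {missing_cols}")
    validate_manifest(df, base_dir=path.parent, check_paths=check_paths)
    return df


def validate_manifest(df: pd.DataFrame, base_dir=None, check_paths: bool = True) -> None:
    bad_group = sorted(set(df["group"]) - set(GROUPS))
    if bad_group:
        raise ValueError(f"unknown group labels {bad_group}; expected {GROUPS}")
    bad_session = sorted(set(df["session"]) - set(SESSIONS))
    if bad_session:
        raise ValueError(f"unknown session labels {bad_session}; expected {SESSIONS}")
    for sid, sub in df.groupby("subject_id"):
        counts = sub["session"].value_counts()
        for session in SESSIONS:
            if counts.get(session, 0) != 1:
                raise ValueError(
                    f"subject {sid!r} must have exactly one {session} row, "
                    f"found {counts.get(session, 0)}"
                )
    if check_paths:
        for p in df["path"]:
            fp = Path(p)
            if base_dir is not None and not fp.is_absolute():
                fp = Path(base_dir) / fp
            if not fp.exists():
                raise FileNotFoundError(f"manifest references missing file {fp}")


def write_manifest(df: pd.DataFrame, path) -> None:
    df.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


def write_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
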