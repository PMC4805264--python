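"""Synthetic two-session resting-state study with known ground truth.

No public dataset accompanies the design this package analyses, so every
downstream stage is exercised on simulated data built from the minimal
generative model under which dual regression is the correct estimator: each
subject-session 4D series is a low-rank mixture of spatial network maps and
independent time courses plus additive Gaussian noise,

    data(x, t) = sum_j map_j(x) * c_j(t) + eps(x, t).

Subject-session maps perturb the group templates multiplicatively:

    map_ijs = template_j * (1 + b_ij + w_ijs + shift * 1[s = FU]),

with ``b`` a per-subject/network draw of SD ``sigma_between`` (stable across
sessions) and ``w`` a per-session draw of SD ``sigma_within``.  Reliability
statistics downstream are therefore controlled: large ``sigma_between`` with
small ``sigma_within`` gives high ICC, and vice versa.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import (
    SESSIONS,
    Bold4D,
    ConfigurationError,
    GroundTruth,
    SimulationConfig,
    TemplateSet,
)

# Z-like peak height of each template blob; typical of thresholded IC maps.
TEMPLATE_PEAK_Z = 5.0

# Seed-stream tags (mixed with the user seed into independent generators).
_STREAM_TRUTH = 1
_STREAM_BOLD = 2

_MIN_CELL = 4  # voxels per lattice cell per axis; keeps blobs separable


def _blob_centers(config: SimulationConfig) -> List[Tuple[int, ...]]:
    """Lay blob centers on a regular lattice; error if the grid is too small."""
    n = config.n_networks
    c = max(1, math.ceil(n ** (1.0 / 3.0)))
    cells = [d // c for d in config.grid_dims]
    if min(cells) < _MIN_CELL:
        raise ConfigurationError(
            f"grid {config.grid_dims} too small to place {n} separable network "
            f"blobs: needs >= {c * _MIN_CELL} voxels per axis "
            f"({c} lattice cells of >= {_MIN_CELL} voxels)"
        )
    centers = []
    for ix in range(c):
        for iy in range(c):
            for iz in range(c):
                centers.append(
                    (
                        cells[0] * ix + cells[0] // 2,
                        cells[1] * iy + cells[1] // 2,
                        cells[2] * iz + cells[2] // 2,
                    )
                )
    return centers[:n]


def make_templates(config: SimulationConfig) -> TemplateSet:
    """Build ``n_networks`` smooth positive Gaussian-bump template maps.

    Each map is scaled to a Z-like peak of :data:`TEMPLATE_PEAK_Z`.  Maps sit
    at distinct lattice positions so pairwise spatial correlation stays below
    0.5, keeping the regression dictionary well conditioned.
    """
    centers = _blob_centers(config)
    sigma = max(1.0, min(d // max(1, math.ceil(config.n_networks ** (1 / 3))) for d in config.grid_dims) / 4.0)
    gx, gy, gz = np.meshgrid(
        *[np.arange(d, dtype=np.float64) for d in config.grid_dims], indexing="ij"
    )
    maps = np.empty((config.n_networks,) + tuple(config.grid_dims))
    for j, (cx, cy, cz) in enumerate(centers):
        d2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
        blob = np.exp(-d2 / (2.0 * sigma**2))
        maps[j] = TEMPLATE_PEAK_Z * blob / blob.max()
    names = [f"network{j:02d}" for j in range(config.n_networks)]
    tset = TemplateSet(maps=maps, names=names)
    _check_template_separation(tset)
    return tset


def _check_template_separation(templates: TemplateSet) -> None:
    k = templates.n_networks
    if k < 2:
        return
    flat = templates.maps.reshape(k, -1)
    corr = np.corrcoef(flat)
    off = corr[~np.eye(k, dtype=bool)]
    if np.nanmax(np.abs(off)) >= 0.5:
        raise ConfigurationError(
            "template maps are not distinguishable: pairwise spatial "
            f"correlation reaches {np.nanmax(np.abs(off)):.2f} (must be < 0.5); "
            "enlarge the grid or reduce n_networks"
        )


def _subject_ids(config: SimulationConfig) -> Tuple[List[str], List[str]]:
    ids, groups = [], []
    for group, size in config.group_sizes.items():
        for i in range(size):
            ids.append(f"{group}{i + 1:02d}")
            groups.append(group)
    return ids, groups


def simulate_ground_truth(
    templates: TemplateSet, config: SimulationConfig
) -> GroundTruth:
    """Draw per-subject, per-session network maps around the templates."""
    if tuple(templates.grid_dims) != tuple(config.grid_dims):
        raise ConfigurationError(
            f"template grid {templates.grid_dims} != config grid {config.grid_dims}"
        )
    if templates.n_networks != config.n_networks:
        raise ConfigurationError(
            f"template count {templates.n_networks} != config n_networks {config.n_networks}"
        )
    rng = np.random.default_rng([config.seed, _STREAM_TRUTH])
    ids, groups = _subject_ids(config)
    n, k = len(ids), config.n_networks
    b = rng.normal(0.0, config.sigma_between, size=(n, k))
    # Per-session perturbation; SD may differ by group (e.g. larger for MS).
    w = rng.standard_normal(size=(n, 2, k))
    sd_w = np.array([config.sigma_within_for(g) for g in groups])
    w = w * sd_w[:, None, None]
    shift = np.array([0.0, config.session_shift])  # BL, FU
    amplitudes = 1.0 + b[:, None, :] + w + shift[None, :, None]
    maps = amplitudes[..., None, None, None] * templates.maps[None, None, ...]
    return GroundTruth(
        subject_maps=maps,
        subject_amplitudes=amplitudes,
        group_labels=groups,
        subject_ids=ids,
    )


def true_time_courses(
    config: SimulationConfig, subject: int, session: int
) -> np.ndarray:
    """The (t, network) standard-normal time courses mixed into one series.

    Regenerated from the seeded stream used by :func:`simulate_bold`, so
    recovery of stage-1 estimates can be checked against the exact truth.
    """
    rng = np.random.default_rng([config.seed, _STREAM_BOLD, subject, session])
    return rng.standard_normal((config.n_timepoints, config.n_networks))


def simulate_bold(
    truth: GroundTruth,
    templates: TemplateSet,
    config: SimulationConfig,
    subject: int,
    session: int,
) -> Bold4D:
    """Mix one subject-session's maps with random time courses plus noise."""
    if not (0 <= subject < truth.n_subjects):
        raise IndexError(f"subject index {subject} out of range [0, {truth.n_subjects})")
    if not (0 <= session < len(SESSIONS)):
        raise IndexError(f"session index {session} not in (0, 1)")
    rng = np.random.default_rng([config.seed, _STREAM_BOLD, subject, session])
    tcs = rng.standard_normal((config.n_timepoints, config.n_networks))
    maps = truth.subject_maps[subject, session]  # (network, x, y, z)
    data = np.einsum("jxyz,tj->xyzt", maps, tcs)
    if config.sigma_noise > 0:
        data = data + rng.normal(0.0, config.sigma_noise, size=data.shape)
    return Bold4D(
        data=data,
        tr_seconds=config.tr_seconds,
        subject_id=truth.subject_ids[subject],
        session=SESSIONS[session],
        group=truth.group_labels[subject],
    )


def simulate_dataset(
    config: SimulationConfig,
) -> Tuple[TemplateSet, GroundTruth]:
    """Convenience: templates plus ground truth from one config."""
    templates = make_templates(config)
    return templates, simulate_ground_truth(templates, config)


def write_dataset(
    truth: GroundTruth,
    templates: TemplateSet,
    config: SimulationConfig,
    directory,
) -> pd.DataFrame:
    """Write the full study to disk as NIfTI volumes plus manifest and config.

    Produces one 4D BOLD file per subject-session, a 4D template stack
    (4th dimension = network), ``manifest.csv`` and ``config.yaml``; returns
    the manifest table.
    """
    from . import io as nio  # deferred: keeps array-only use free of nibabel

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nio.write_template_set(templates, directory / "templates.nii.gz")
    rows = []
    for i, sid in enumerate(truth.subject_ids):
        for s, session in enumerate(SESSIONS):
            bold = simulate_bold(truth, templates, config, i, s)
            path = directory / f"sub-{sid}_ses-{session}_bold.nii.gz"
            nio.write_volume(bold.data, templates.affine, path)
            rows.append(
                {
                    "subject_id": sid,
                    "group": truth.group_labels[i],
                    "session": session,
                    "path": str(path),
                }
            )
    manifest = pd.DataFrame(rows)
    nio.write_manifest(manifest, directory / "manifest.csv")
    nio.write_config(config, directory / "config.yaml")
    return manifest
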