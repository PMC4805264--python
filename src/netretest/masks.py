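"""Entire-network and subject-overlap ROI masks, and map summaries.

Two mask families feed the reliability statistics: the entire-network (EN)
mask — the suprathreshold support of a group template map — and the
subject-overlap ROI — the voxels one subject keeps suprathreshold (strictly
Z > threshold) at both baseline and follow-up.  Thresholds are strict
inequalities throughout, so exact ties at the cutoff are excluded.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import DegenerateInputError, GridMismatchError, NetworkMask

logger = logging.getLogger(__name__)


def entire_network_mask(
    template_map: np.ndarray, threshold: float = 0.0, network: str = ""
) -> NetworkMask:
    """Mask of template voxels strictly above ``threshold``.

    Raises if the mask comes out empty — that means the threshold exceeds
    the template's maximum and the network has no support at all.
    """
    template_map = np.asarray(template_map, dtype=np.float64)
    voxels = template_map > threshold
    if not voxels.any():
        raise DegenerateInputError(
            f"entire-network mask is empty: threshold {threshold} is at or above "
            f"the template maximum {template_map.max():.4g}"
            + (f" (network {network!r})" if network else "")
        )
    return NetworkMask(
        voxels=voxels, network=network, provenance="entire_network", threshold=threshold
    )


def subject_overlap_mask(
    z_bl: np.ndarray,
    z_fu: np.ndarray,
    threshold: float = 0.0,
    network: str = "",
    subject_id: str = "subject",
) -> NetworkMask:
    """Per-subject ROI: voxels with Z > threshold at both BL and FU.

    An empty overlap is a legitimate outcome (the subject then contributes a
    missing value downstream); it is logged, not raised.
    """
    z_bl = np.asarray(z_bl, dtype=np.float64)
    z_fu = np.asarray(z_fu, dtype=np.float64)
    if z_bl.shape != z_fu.shape:
        raise GridMismatchError(f"BL grid {z_bl.shape} != FU grid {z_fu.shape}")
    voxels = (z_bl > threshold) & (z_fu > threshold)
    mask = NetworkMask(
        voxels=voxels,
        network=network,
        provenance="subject_overlap",
        threshold=threshold,
        subject_id=subject_id,
    )
    if mask.is_empty:
        logger.warning(
            "empty overlap mask for subject %s network %s at Z > %g",
            subject_id,
            network or "?",
            threshold,
        )
    return mask


def mask_mean(volume: np.ndarray, mask: NetworkMask) -> float:
    """Arithmetic mean of ``volume`` over the mask voxels."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.shape != mask.voxels.shape:
        raise GridMismatchError(
            f"volume grid {volume.shape} != mask grid {mask.voxels.shape}"
        )
    if mask.is_empty:
        raise DegenerateInputError(
            f"cannot take the mean over an empty mask (network {mask.network!r}, "
            f"subject {mask.subject_id!r})"
        )
    return float(volume[mask.voxels].mean())
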