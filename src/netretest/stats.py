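"""Test-retest reliability statistics: ICC(3,1) and the Dice overlap ratio.

ICC(3,1) comes from the two-way ANOVA with random subject effects and fixed
session effects:

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) * EMS),

where BMS is the between-subject mean square, EMS the residual mean square
and k the number of sessions (k = 2 here).  A fixed additive session effect
is absorbed by the session mean square (JMS) and leaves the ICC untouched —
the reason this consistency form suits longitudinal designs.  Values near 1
mean between-subject variance dominates within-subject variance.

The ratio of overlapping connectivity is the Dice coefficient of the two
sessions' suprathreshold voxel sets:

    R12 = 2 * V_overlap / (V1 + V2),

with V1, V2 the suprathreshold (strictly Z > threshold) counts at baseline
and follow-up and V_overlap the count suprathreshold in both; it runs from
0 (no overlap) to 1 (perfect overlap).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .masks import entire_network_mask, mask_mean, subject_overlap_mask
from .types import (
    DegenerateInputError,
    GridMismatchError,
    SESSIONS,
    SubjectNetworkMaps,
    TemplateSet,
)

logger = logging.getLogger(__name__)


@dataclass
class SessionValueTable:
    """Per-subject summary connectivity, one column per session (BL, FU)."""

    values: np.ndarray  # (subject, session), NaN = missing
    network: str = ""
    group: str = ""
    mask_kind: str = ""  # EN | ROI

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("values must be (subject, session) with >= 2 sessions")

    def complete_rows(self) -> np.ndarray:
        return self.values[~np.isnan(self.values).any(axis=1)]


@dataclass
class IccResult:
    icc: float  # clamped to [0, 1]
    icc_raw: float
    bms: float
    ems: float
    jms: float
    k: int
    n: int


@dataclass
class OverlapResult:
    r12: float
    v1: int
    v2: int
    v_overlap: int
    threshold: float


def icc31(table: "SessionValueTable | np.ndarray") -> IccResult:
    """ICC(3,1) from the two-way ANOVA decomposition of a subject×session table.

    Rows with any missing session are dropped; at least 3 complete rows are
    required.  If the table has zero total variance the formula is 0/0 and
    the ICC is reported as 0 with a warning — "no between-subject variance"
    is the statistic's own worst case.
    """
    if not isinstance(table, SessionValueTable):
        table = SessionValueTable(values=np.asarray(table, dtype=np.float64))
    y = table.complete_rows()
    n, k = y.shape
    if n < 3:
        raise DegenerateInputError(
            f"ICC needs >= 3 complete subject rows, got {n} "
            f"(network {table.network!r}, group {table.group!r})"
        )
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_subject = k * float(((row_means - grand) ** 2).sum())
    ss_session = n * float(((col_means - grand) ** 2).sum())
    # residual SS from the interaction residuals directly (numerically stable
    # under large additive session effects, unlike total-minus-parts)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ss_error = float((resid**2).sum())
    bms = ss_subject / (n - 1)
    jms = ss_session / (k - 1)
    ems = ss_error / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    if denom <= 0:
        warnings.warn(
            "zero total between/within variance: ICC(3,1) is 0/0, reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        icc_raw = 0.0
    else:
        icc_raw = (bms - ems) / denom
    return IccResult(
        icc=float(min(max(icc_raw, 0.0), 1.0)),
        icc_raw=float(icc_raw),
        bms=bms,
        ems=ems,
        jms=jms,
        k=k,
        n=n,
    )


def dice_r12(
    z_bl: np.ndarray, z_fu: np.ndarray, threshold: float = 0.0
) -> OverlapResult:
    """Dice ratio of the two sessions' strictly suprathreshold voxel sets."""
    z_bl = np.asarray(z_bl, dtype=np.float64)
    z_fu = np.asarray(z_fu, dtype=np.float64)
    if z_bl.shape != z_fu.shape:
        raise GridMismatchError(f"BL grid {z_bl.shape} != FU grid {z_fu.shape}")
    m1 = z_bl > threshold
    m2 = z_fu > threshold
    v1, v2 = int(m1.sum()), int(m2.sum())
    v_overlap = int((m1 & m2).sum())
    if v1 + v2 == 0:
        raise DegenerateInputError(
            f"no suprathreshold voxels in either session at Z > {threshold}; "
            "the overlap ratio is undefined (not 0)"
        )
    return OverlapResult(
        r12=2.0 * v_overlap / (v1 + v2),
        v1=v1,
        v2=v2,
        v_overlap=v_overlap,
        threshold=threshold,
    )


def threshold_sweep(
    z_bl: np.ndarray, z_fu: np.ndarray, thresholds: Sequence[float]
) -> List[Optional[OverlapResult]]:
    """Dice overlap at each of a strictly increasing ladder of thresholds.

    Where both sessions lose all suprathreshold voxels the entry is ``None``
    (a missing-result marker), not a zero.
    """
    thresholds = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be strictly increasing, got {thresholds}")
    out: List[Optional[OverlapResult]] = []
    for t in thresholds:
        try:
            out.append(dice_r12(z_bl, z_fu, t))
        except DegenerateInputError:
            out.append(None)
    return out


def _session_pairs(
    subject_maps: Iterable[SubjectNetworkMaps],
) -> Mapping[str, Mapping[str, SubjectNetworkMaps]]:
    by_subject: dict = {}
    for m in subject_maps:
        by_subject.setdefault(m.subject_id, {})[m.session] = m
    for sid, sessions in by_subject.items():
        missing = [s for s in SESSIONS if s not in sessions]
        if missing:
            raise ValueError(f"subject {sid!r} is missing session(s) {missing}")
    return by_subject


def network_reproducibility(
    subject_maps: Iterable[SubjectNetworkMaps],
    templates: TemplateSet,
    group_labels: Mapping[str, str],
    threshold: float = 0.0,
    en_threshold: float = 0.0,
    use_beta: bool = False,
) -> pd.DataFrame:
    """Per-network, per-group reliability summary table.

    For every network and group: the entire-network (EN) ICC of the mean map
    value over the template support, the ROI ICC of the mean over each
    subject's BL∩FU overlap mask, and the mean/SD of the per-subject Dice
    overlap R12.  Subjects with an empty overlap mask contribute a missing
    value to the ROI ICC for that network and are dropped pairwise (logged).

    Columns: network, group, n, icc_en, icc_en_raw, icc_roi, icc_roi_raw,
    r12_mean, r12_sd, threshold.
    """
    by_subject = _session_pairs(subject_maps)
    sids = sorted(by_subject)
    rows = []
    for j, name in enumerate(templates.names):
        en_mask = entire_network_mask(templates.maps[j], en_threshold, network=name)
        for group in sorted(set(group_labels.values())):
            gsids = [s for s in sids if group_labels[s] == group]
            en_vals = np.full((len(gsids), 2), np.nan)
            roi_vals = np.full((len(gsids), 2), np.nan)
            r12s = []
            for i, sid in enumerate(gsids):
                pair = by_subject[sid]
                vols = {
                    s: (pair[s].beta[j] if use_beta else pair[s].zmap[j])
                    for s in SESSIONS
                }
                zs = {s: pair[s].zmap[j] for s in SESSIONS}
                for c, s in enumerate(SESSIONS):
                    en_vals[i, c] = mask_mean(vols[s], en_mask)
                roi = subject_overlap_mask(
                    zs["BL"], zs["FU"], threshold, network=name, subject_id=sid
                )
                if roi.is_empty:
                    logger.warning(
                        "dropping subject %s from ROI ICC for network %s "
                        "(empty overlap at Z > %g)",
                        sid,
                        name,
                        threshold,
                    )
                else:
                    for c, s in enumerate(SESSIONS):
                        roi_vals[i, c] = mask_mean(vols[s], roi)
                try:
                    r12s.append(dice_r12(zs["BL"], zs["FU"], threshold).r12)
                except DegenerateInputError:
                    logger.warning(
                        "subject %s network %s: no suprathreshold voxels, "
                        "R12 undefined",
                        sid,
                        name,
                    )
            icc_en = icc31(
                SessionValueTable(en_vals, network=name, group=group, mask_kind="EN")
            )
            icc_roi = icc31(
                SessionValueTable(roi_vals, network=name, group=group, mask_kind="ROI")
            )
            r12_arr = np.asarray(r12s, dtype=np.float64)
            rows.append(
                {
                    "network": name,
                    "group": group,
                    "n": icc_roi.n,
                    "icc_en": icc_en.icc,
                    "icc_en_raw": icc_en.icc_raw,
                    "icc_roi": icc_roi.icc,
                    "icc_roi_raw": icc_roi.icc_raw,
                    "r12_mean": float(r12_arr.mean()) if r12_arr.size else np.nan,
                    "r12_sd": float(r12_arr.std(ddof=1)) if r12_arr.size > 1 else np.nan,
                    "threshold": threshold,
                }
            )
    return pd.DataFrame(rows)


def voxelwise_icc(
    subject_maps: Iterable[SubjectNetworkMaps],
    templates: TemplateSet,
    network: int,
    en_threshold: float = 0.0,
    use_beta: bool = False,
) -> np.ndarray:
    """Optional voxel-wise ICC(3,1) map over the entire-network mask.

    Voxels outside the mask are NaN.  A finer-grained view than the
    single-number EN/ROI summaries; not part of the headline tables.
    """
    by_subject = _session_pairs(subject_maps)
    sids = sorted(by_subject)
    en = entire_network_mask(
        templates.maps[network], en_threshold, network=str(templates.names[network])
    )
    idx = np.flatnonzero(en.voxels.ravel())
    vals = np.empty((len(sids), 2, idx.size))
    for i, sid in enumerate(sids):
        for c, s in enumerate(SESSIONS):
            m = by_subject[sid][s]
            vol = m.beta[network] if use_beta else m.zmap[network]
            vals[i, c] = vol.ravel()[idx]
    out = np.full(en.voxels.size, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for v in range(idx.size):
            out[idx[v]] = icc31(vals[:, :, v]).icc
    return out.reshape(en.voxels.shape)
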