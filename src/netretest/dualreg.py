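"""Two-stage dual regression of a 4D BOLD series against template maps.

Stage 1 regresses every volume (voxels as observations, demeaned over the
in-brain mask) on all template maps jointly, yielding one time course per
network.  Stage 2 variance-normalizes those time courses and regresses every
voxel's demeaned time series on all of them jointly, yielding per-network
coefficient (beta) maps and Z maps (coefficient over its standard error).

Both stages are joint multiple regressions — never one network at a time —
so shared variance between overlapping networks is partitioned rather than
double-counted.  Z maps are the OLS t-statistics used directly; with ~150
time points the t-to-Z deviate conversion is negligible and thresholding at
zero is identical either way (a conversion is available via ``t_to_z``).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import (
    Bold4D,
    GridMismatchError,
    SubjectNetworkMaps,
    TemplateSet,
    TimeCourses,
    Z_CAP,
)

_RANK_TOL = 1e-10


def _check_grids(bold: Bold4D, templates: TemplateSet) -> None:
    if tuple(bold.grid_dims) != tuple(templates.grid_dims):
        raise GridMismatchError(
            f"BOLD grid {bold.grid_dims} != template grid {templates.grid_dims}"
        )


def _name_collinear_pair(X: np.ndarray, names) -> str:
    k = X.shape[1]
    best, pair = 0.0, (names[0], names[0])
    for a in range(k):
        for b in range(a + 1, k):
            na, nb = np.linalg.norm(X[:, a]), np.linalg.norm(X[:, b])
            if na == 0 or nb == 0:
                return f"{names[a]!r} or {names[b]!r} is constant over the mask"
            r = abs(float(X[:, a] @ X[:, b]) / (na * nb))
            if r > best:
                best, pair = r, (names[a], names[b])
    return f"{pair[0]!r} and {pair[1]!r} (|r| = {best:.4f})"


def stage1_spatial_regression(bold: Bold4D, templates: TemplateSet) -> TimeCourses:
    """Spatial regression: volumes on template maps, one fit per time point.

    Design columns (template maps over masked voxels) and each volume are
    demeaned over the mask before the joint OLS fit.
    """
    _check_grids(bold, templates)
    mask = bold.get_mask().ravel()
    X = templates.maps.reshape(templates.n_networks, -1).T[mask]  # (V, K)
    X = X - X.mean(axis=0)
    if np.linalg.matrix_rank(X, tol=_RANK_TOL * max(1.0, np.abs(X).max())) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "template matrix is rank deficient over the mask; most collinear "
            "pair: " + _name_collinear_pair(X, list(templates.names))
        )
    Y = bold.data.reshape(-1, bold.n_timepoints)[mask]  # (V, T)
    Y = Y - Y.mean(axis=0)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)  # (K, T)
    return TimeCourses(values=coef.T, names=list(templates.names))


def variance_normalize(tcs: TimeCourses) -> TimeCourses:
    """Scale each time course to unit sample variance (constants untouched)."""
    vals = tcs.values - tcs.values.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    out = np.where(sd > 0, vals / np.where(sd > 0, sd, 1.0), vals)
    return TimeCourses(values=out, names=list(tcs.names), variance_normalized=True)


def stage2_temporal_regression(bold: Bold4D, tcs: TimeCourses) -> SubjectNetworkMaps:
    """Temporal regression: each voxel's series on all time courses jointly.

    Residual degrees of freedom are t − n_networks − 1 (the −1 for the
    removed voxel mean).  Voxels with constant time series get beta = Z = 0;
    voxels fit exactly (zero residual variance, e.g. noiseless simulations)
    get Z = ±Z_CAP so Z stays finite wherever the series is non-constant.
    """
    T = bold.n_timepoints
    if tcs.values.shape[0] != T:
        raise ValueError(
            f"time-course length {tcs.values.shape[0]} != BOLD length {T}"
        )
    K = tcs.values.shape[1]
    if T <= K + 1:
        raise ValueError(
            f"no residual degrees of freedom: t = {T} <= n_networks + 1 = {K + 1}"
        )
    D = variance_normalize(tcs).values  # demeaned, unit-variance columns
    G = D.T @ D
    if np.linalg.matrix_rank(G) < K:
        raise np.linalg.LinAlgError(
            "stage-2 design is rank deficient; most collinear pair: "
            + _name_collinear_pair(D, list(tcs.names))
        )
    Ginv = np.linalg.inv(G)

    mask = bold.get_mask().ravel()
    grid = bold.grid_dims
    Yfull = bold.data.reshape(-1, T)
    Y = Yfull[mask].T  # (T, V)
    Y = Y - Y.mean(axis=0)
    B = Ginv @ (D.T @ Y)  # (K, V)
    resid = Y - D @ B
    dof = T - K - 1
    ss_res = (resid**2).sum(axis=0)
    ss_tot = (Y**2).sum(axis=0)
    # a voxel fit whose residual SS is at rounding level relative to its total
    # SS is an exact fit: its Z is capped, not left to float noise
    perfect = ss_res <= 1e-20 * ss_tot
    sigma2 = ss_res / dof
    se = np.sqrt(np.outer(np.diag(Ginv), sigma2))  # (K, V)

    constant = Y.std(axis=0) == 0
    B[:, constant] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(se > 0, B / np.where(se > 0, se, 1.0), 0.0)
    Z[:, perfect] = np.sign(B[:, perfect]) * Z_CAP
    Z[:, constant] = 0.0

    beta = np.zeros((K,) + tuple(grid)).reshape(K, -1)
    zmap = np.zeros_like(beta)
    beta[:, mask] = B
    zmap[:, mask] = Z
    return SubjectNetworkMaps(
        beta=beta.reshape((K,) + tuple(grid)),
        zmap=zmap.reshape((K,) + tuple(grid)),
        subject_id=bold.subject_id,
        session=bold.session,
        group=bold.group,
        names=list(tcs.names),
    )


def dual_regress(bold: Bold4D, templates: TemplateSet) -> SubjectNetworkMaps:
    """Full dual regression: stage 1 → variance-normalize → stage 2."""
    tcs = stage1_spatial_regression(bold, templates)
    return stage2_temporal_regression(bold, variance_normalize(tcs))


def t_to_z(tmap: np.ndarray, dof: int) -> np.ndarray:
    """Convert t statistics to standard-normal deviates of equal tail mass."""
    t = np.clip(np.asarray(tmap, dtype=np.float64), -Z_CAP, Z_CAP)
    return stats.norm.isf(stats.t.sf(t, dof))
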