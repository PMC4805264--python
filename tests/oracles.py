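"""Independent brute-force oracles used only by the test suite.

Each oracle is a naive, loop-based evaluation of the statistic it checks,
written without reference to the package's vectorised implementations.
"""

import numpy as np


def icc31_oracle(y):
    """Cell-by-cell two-way ANOVA table and ICC(3,1), all explicit loops."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(y[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(y[i, j] for i in range(n)) / n for j in range(k)]
    ss_sub = k * sum((row[i] - grand) ** 2 for i in range(n))
    ss_ses = n * sum((col[j] - grand) ** 2 for j in range(k))
    ss_err = sum(
        (y[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    bms = ss_sub / (n - 1)
    jms = ss_ses / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    icc = (bms - ems) / (bms + (k - 1) * ems)
    return {"bms": bms, "jms": jms, "ems": ems, "icc": icc}


def stage1_oracle(data4d, template_maps):
    """Per-time-point normal-equation OLS of volumes on demeaned templates."""
    K = template_maps.shape[0]
    X = np.column_stack([template_maps[j].ravel() for j in range(K)])
    X = X - X.mean(axis=0)
    T = data4d.shape[3]
    out = np.empty((T, K))
    for t in range(T):
        y = data4d[..., t].ravel()
        y = y - y.mean()
        out[t] = np.linalg.solve(X.T @ X, X.T @ y)
    return out


def stage2_oracle(data4d, design):
    """Per-voxel OLS (beta and t) on the demeaned, unit-variance design."""
    T, K = design.shape
    D = design - design.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    D = D / sd
    dof = T - K - 1
    G = D.T @ D
    Ginv = np.linalg.inv(G)
    nx, ny, nz, _ = data4d.shape
    beta = np.zeros((K, nx, ny, nz))
    tmap = np.zeros((K, nx, ny, nz))
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                y = data4d[ix, iy, iz, :].astype(float)
                y = y - y.mean()
                if np.all(y == 0):
                    continue
                b = np.linalg.solve(G, D.T @ y)
                resid = y - D @ b
                s2 = float(resid @ resid) / dof
                se = np.sqrt(np.diag(Ginv) * s2)
                beta[:, ix, iy, iz] = b
                with np.errstate(divide="ignore"):
                    tmap[:, ix, iy, iz] = np.where(se > 0, b / se, 0.0)
    return beta, tmap


def dice_oracle(a, b, thr):
    """Set-based Dice via explicit voxel index sets."""
    s1 = {tuple(idx) for idx in np.argwhere(np.asarray(a) > thr)}
    s2 = {tuple(idx) for idx in np.argwhere(np.asarray(b) > thr)}
    if not s1 and not s2:
        return None
    return 2.0 * len(s1 & s2) / (len(s1) + len(s2))
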