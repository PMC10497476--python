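"""Independent oracle implementations used only by the tests.

Deliberately naive: plain loops and textbook formulas, sharing no code
with the package's vectorized paths.
"""

import numpy as np


def ols_fit(x, y):
    """Straight-line least squares via the raw normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    A = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    sse = float(((y - (slope * x + intercept)) ** 2).sum())
    return float(slope), float(intercept), sse


def patlak_points(mid_min, ct, cp, t_star):
    """Patlak coordinates recomputed step by step with explicit loops."""
    t = [0.0] + list(mid_min)
    v = [0.0] + list(cp)
    integral = np.zeros(len(mid_min))
    acc = 0.0
    for k in range(1, len(t)):
        acc += 0.5 * (v[k] + v[k - 1]) * (t[k] - t[k - 1])
        integral[k - 1] = acc
    xs, ys = [], []
    for k, tm in enumerate(mid_min):
        if tm >= t_star and cp[k] > 0:
            xs.append(integral[k] / cp[k])
            ys.append(ct[k] / cp[k])
    return np.asarray(xs), np.asarray(ys)


def roi_patlak_fit(dyn, labels, label, cp_values, t_star):
    """ROI-mean TAC, Patlak transform, and OLS fit, all done naively."""
    mask = labels == label
    vox = dyn.data[mask]
    ct = np.array([float(np.mean(vox[:, j])) for j in range(vox.shape[1])])
    x, y = patlak_points(dyn.schedule.mid_times_min, ct, cp_values, t_star)
    return ols_fit(x, y)


def masked_mean(volume, mask):
    total, n = 0.0, 0
    it = np.nditer(mask, flags=["multi_index"])
    for m in it:
        if m:
            total += float(volume[it.multi_index])
            n += 1
    return total / n


def cylinder_membership(dyn, centerline_pts, radius_mm):
    """Per-voxel loop deciding cylinder membership from world geometry."""
    pts = centerline_pts[np.argsort(centerline_pts[:, 2])]
    nx, ny, nz = dyn.shape3d
    A = dyn.affine
    mask = np.zeros((nx, ny, nz), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                wx, wy, wz, _ = A @ np.array([i, j, k, 1.0])
                if wz < pts[0, 2] - 1e-9 or wz > pts[-1, 2] + 1e-9:
                    continue
                cx = np.interp(wz, pts[:, 2], pts[:, 0])
                cy = np.interp(wz, pts[:, 2], pts[:, 1])
                if (wx - cx) ** 2 + (wy - cy) ** 2 <= radius_mm**2 + 1e-9:
                    mask[i, j, k] = True
    return mask
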