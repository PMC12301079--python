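"""Independent reference implementations used only to check the package.

Each oracle is deliberately written from scratch (own interpolation, own
search, own counting) so agreement with the production code is evidence,
not tautology.
"""

from __future__ import annotations

import numpy as np


def bilinear_sample(axes, values, points):
    """Manual bilinear interpolation on a 2D regular grid; NaN outside."""
    ax, ay = axes
    pts = np.atleast_2d(points)
    x, y = pts[:, 0], pts[:, 1]
    out = np.full(len(pts), np.nan)
    inside = (x >= ax[0]) & (x <= ax[-1]) & (y >= ay[0]) & (y <= ay[-1])
    if not np.any(inside):
        return out
    xi, yi = x[inside], y[inside]
    ix = np.clip(np.searchsorted(ax, xi, side="right") - 1, 0, len(ax) - 2)
    iy = np.clip(np.searchsorted(ay, yi, side="right") - 1, 0, len(ay) - 2)
    tx = (xi - ax[ix]) / (ax[ix + 1] - ax[ix])
    ty = (yi - ay[iy]) / (ay[iy + 1] - ay[iy])
    v00 = values[ix, iy]
    v10 = values[ix + 1, iy]
    v01 = values[ix, iy + 1]
    v11 = values[ix + 1, iy + 1]
    out[inside] = (
        v00 * (1 - tx) * (1 - ty)
        + v10 * tx * (1 - ty)
        + v01 * (1 - tx) * ty
        + v11 * tx * ty
    )
    return out


def _lattice(step: float, radius: float) -> np.ndarray:
    n = int(np.ceil(radius / step))
    axis = np.arange(-n, n + 1) * step
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    offs = np.stack([xx.ravel(), yy.ravel()], axis=-1)
    return offs[np.linalg.norm(offs, axis=1) <= radius + 1e-12]


def max_gradient(grid) -> float:
    """Bound on |grad D| of the bilinear interpolant from finite differences."""
    total = 0.0
    for axis in range(grid.values.ndim):
        d = np.abs(np.diff(grid.values, axis=axis))
        total += (d.max() / grid.spacing[axis]) ** 2
    return float(np.sqrt(total))


def gamma_brute(grid, position, ref_dose, delta_d_gy, dta_mm,
                search_factor=3.0):
    """Exhaustive dense-search gamma for one reference point.

    A coarse lattice covers the full search disc; every coarse cell whose
    gamma lower bound (from the lattice half-diagonal and the grid's
    maximum dose gradient) could undercut the incumbent is then searched
    densely, with a final micro-lattice around the running optimum.  All
    interpolation is a from-scratch bilinear evaluation.
    """
    axes = grid.axes
    values = grid.values
    position = np.asarray(position, dtype=float)
    radius = search_factor * dta_mm

    def gamma_sq(offsets):
        dists2 = np.einsum("ij,ij->i", offsets, offsets)
        doses = bilinear_sample(axes, values, position[None, :] + offsets)
        with np.errstate(invalid="ignore"):
            return dists2 / dta_mm**2 + ((doses - ref_dose) / delta_d_gy) ** 2

    step1 = min(dta_mm / 20.0, 0.05)
    offs1 = _lattice(step1, radius)
    dist1 = np.linalg.norm(offs1, axis=1)
    doses1 = bilinear_sample(axes, values, position[None, :] + offs1)
    with np.errstate(invalid="ignore"):
        ddiff = np.abs(doses1 - ref_dose)
        g2 = (dist1 / dta_mm) ** 2 + (ddiff / delta_d_gy) ** 2
    best = float(np.nanmin(g2))

    half_diag = step1 * np.sqrt(2) / 2
    grad = max_gradient(grid)
    with np.errstate(invalid="ignore"):
        lb = (np.clip(dist1 - half_diag, 0, None) / dta_mm) ** 2 + (
            np.clip(ddiff - grad * half_diag, 0, None) / delta_d_gy
        ) ** 2
    # out-of-grid samples keep a spatial-only bound: their cell can straddle
    # the grid boundary
    lb = np.where(np.isnan(lb), (np.clip(dist1 - half_diag, 0, None)
                                 / dta_mm) ** 2, lb)
    candidates = offs1[lb < best]
    best_off = offs1[int(np.nanargmin(g2))]

    if len(candidates):
        cell = _lattice(step1 / 25.0, half_diag)
        offs2 = (candidates[:, None, :] + cell[None, :, :]).reshape(-1, 2)
        offs2 = offs2[np.linalg.norm(offs2, axis=1) <= radius + 1e-12]
        g2f = gamma_sq(offs2)
        if np.any(np.isfinite(g2f)):
            i = int(np.nanargmin(g2f))
            if g2f[i] < best:
                best = float(g2f[i])
                best_off = offs2[i]

    # shrinking dense micro-lattices around the incumbent
    micro_step = step1 / 25.0
    while micro_step > 2e-6:
        sub = micro_step / 20.0
        micro = best_off[None, :] + _lattice(sub, 2.0 * micro_step)
        micro = micro[np.linalg.norm(micro, axis=1) <= radius + 1e-12]
        g2m = gamma_sq(micro)
        if np.any(np.isfinite(g2m)):
            i = int(np.nanargmin(g2m))
            if g2m[i] < best:
                best = float(g2m[i])
                best_off = micro[i]
        micro_step = sub
    return float(np.sqrt(best))


def perimeter_shapely(cp, gap_tol=0.5):
    """Aperture perimeter as the boundary length of a shapely box union.

    Leaf pairs are stacked along y in array order, each open pair a
    rectangle [bank_a, bank_b] x [y_i, y_i + width].
    """
    from shapely.geometry import box
    from shapely.ops import unary_union

    y = 0.0
    rects = []
    for w, a, b in zip(cp.leaf_widths, cp.bank_a_positions, cp.bank_b_positions):
        if b - a > gap_tol:
            rects.append(box(a, y, b, y + w))
        y += w
    if not rects:
        return 0.0
    union = unary_union(rects)
    geoms = getattr(union, "geoms", [union])
    return float(sum(g.exterior.length for g in geoms))


def auc_pairwise(gprs, fails):
    """AUC as the exhaustive pair count P(GPR_fail < GPR_pass) + 0.5 ties."""
    gprs = np.asarray(gprs, dtype=float)
    fails = np.asarray(fails, dtype=bool)
    gf = gprs[fails]
    gp = gprs[~fails]
    total = 0.0
    for f in gf:
        for p in gp:
            if f < p:
                total += 1.0
            elif f == p:
                total += 0.5
    return total / (len(gf) * len(gp))
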