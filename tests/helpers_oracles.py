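"""Independent brute-force oracles used by the oracle-equivalence tests.

These minimizers never call the fitting code they check: they evaluate the
raw least-squares objectives on successively refined grids.
"""

import numpy as np

from cortmap.phantom import blurred_profile


def grid_search_profile_thickness(x, y, sigma, densities, t_bounds=(0.3, 15.0),
                                  final_step=1e-4):
    """Brute-force (x0, x1) grid minimizer of the fixed-density profile SSE.

    Coarse-to-fine refinement down to ``final_step`` mm; equivalent to a dense
    grid at that resolution because each refinement window spans several
    parent cells around the running minimum.
    """
    t_lo, t_hi = t_bounds

    def sse(x0g, tg):
        pred = blurred_profile(x[None, None, :], x0g[:, None, None],
                               tg[None, :, None], sigma, densities)
        return np.sum((pred - y) ** 2, axis=2)

    # global coarse scan over the admissible (x0, t) rectangle
    step = 0.02
    x0g = np.arange(-3.0, 3.0 + step / 2, step)
    tg = np.arange(t_lo, min(t_hi, 10.0) + step / 2, step)
    cost = sse(x0g, tg)
    i, j = np.unravel_index(np.argmin(cost), cost.shape)
    x0_best, t_best = float(x0g[i]), float(tg[j])

    while step > final_step:
        step = max(step / 10.0, final_step)
        x0g = x0_best + np.arange(-15, 16) * step
        tg = np.clip(t_best + np.arange(-15, 16) * step, t_lo, t_hi)
        cost = sse(x0g, tg)
        i, j = np.unravel_index(np.argmin(cost), cost.shape)
        x0_best, t_best = float(x0g[i]), float(tg[j])
    return x0_best, t_best


def _fibonacci_sphere(n=4000):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def _refine_direction(cost, final_step=2e-8):
    """Global spherical scan, then tangent-plane grid refinement of a direction.

    ``cost`` maps an (n, 3) array of unit directions to n objective values.
    Each refinement level perturbs the running best direction by a grid in its
    tangent plane, shrinking the step until ``final_step`` radians.
    """
    dirs = _fibonacci_sphere()
    best = dirs[int(np.argmin(cost(dirs)))]
    step = 0.05
    grid = np.linspace(-8, 8, 17)
    A, B = np.meshgrid(grid, grid, indexing="ij")
    while True:
        u = np.cross(best, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(best, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(best, u)
        cand = (best[None, :] + step * (A.ravel()[:, None] * u
                                        + B.ravel()[:, None] * v))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        k = int(np.argmin(cost(cand)))
        best = cand[k]
        if step <= final_step:
            return best
        step = max(step / 6.0, final_step)


def grid_search_line_direction(points, final_step=2e-8):
    """Grid minimizer of summed squared orthogonal distances to a line."""
    pts = np.asarray(points, dtype=float)
    d = pts - pts.mean(axis=0)
    total = np.sum(d**2)

    def cost(dirs):
        return total - np.sum((d @ dirs.T) ** 2, axis=0)

    return _refine_direction(cost, final_step)


def grid_search_plane_normal(points, final_step=2e-8):
    """Grid minimizer of summed squared plane-offset residuals."""
    pts = np.asarray(points, dtype=float)
    d = pts - pts.mean(axis=0)

    def cost(dirs):
        return np.sum((d @ dirs.T) ** 2, axis=0)

    return _refine_direction(cost, final_step)


def grid_search_circle_center(points, final_step=1e-4):
    """2D grid minimizer of summed squared radial deviations (r set to mean)."""
    pts = np.asarray(points, dtype=float)
    a, b = pts.mean(axis=0)
    step = 0.5
    while True:
        ag = a + np.linspace(-10, 10, 21) * step
        bg = b + np.linspace(-10, 10, 21) * step
        AG, BG = np.meshgrid(ag, bg, indexing="ij")
        d = np.sqrt((pts[:, 0] - AG[..., None]) ** 2
                    + (pts[:, 1] - BG[..., None]) ** 2)
        r = d.mean(axis=2)
        c = np.sum((d - r[..., None]) ** 2, axis=2)
        i, j = np.unravel_index(np.argmin(c), c.shape)
        a, b = float(AG[i, j]), float(BG[i, j])
        if step <= final_step:
            return np.array([a, b])
        step = max(step / 8.0, final_step)


def angle_between(u, v):
    """Acute angle (rad) between two directions."""
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    return float(np.arccos(np.clip(abs(u @ v), 0.0, 1.0)))
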