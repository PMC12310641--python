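"""Independent brute-force oracles shared by the test modules."""
from itertools import combinations

import numpy as np


def brute_force_mec(pts):
    """Smallest enclosing circle by exhaustive pair/triple enumeration.

    Every candidate circle is either the diameter circle of a pair or the
    circumcircle of a triple; the answer is the smallest candidate that
    contains all points.  Vectorised so n = 60 stays fast.  Returns
    (cx, cy, r).
    """
    pts = np.asarray(pts, float)
    n = len(pts)
    if n == 1:
        return pts[0][0], pts[0][1], 0.0

    centers = []
    radii = []
    ii, jj = np.triu_indices(n, k=1)
    mid = (pts[ii] + pts[jj]) / 2.0
    centers.append(mid)
    radii.append(np.linalg.norm(pts[ii] - pts[jj], axis=1) / 2.0)

    if n >= 3:
        trip = np.array(list(combinations(range(n), 3)))
        a, b, c = pts[trip[:, 0]], pts[trip[:, 1]], pts[trip[:, 2]]
        d = 2.0 * (a[:, 0] * (b[:, 1] - c[:, 1]) + b[:, 0] * (c[:, 1] - a[:, 1])
                   + c[:, 0] * (a[:, 1] - b[:, 1]))
        ok = np.abs(d) > 1e-12
        a, b, c, d = a[ok], b[ok], c[ok], d[ok]
        a2 = (a ** 2).sum(1)
        b2 = (b ** 2).sum(1)
        c2 = (c ** 2).sum(1)
        ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1])
              + c2 * (a[:, 1] - b[:, 1])) / d
        uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0])
              + c2 * (b[:, 0] - a[:, 0])) / d
        centers.append(np.column_stack([ux, uy]))
        radii.append(np.hypot(a[:, 0] - ux, a[:, 1] - uy))

    centers = np.vstack(centers)
    radii = np.concatenate(radii)
    dist = np.sqrt(((pts[None, :, :] - centers[:, None, :]) ** 2).sum(-1))
    valid = np.all(dist <= radii[:, None] + 1e-9, axis=1)
    best = np.flatnonzero(valid)[np.argmin(radii[valid])]
    return centers[best, 0], centers[best, 1], radii[best]


def numeric_curvature(a, b, c, x, h=1.0):
    """Central-difference curvature of y = a x^2 + b x + c at x.

    For a quadratic the central differences for y' and y'' are exact in
    real arithmetic for any step h, so this is a genuinely independent
    path to K.
    """
    def f(t):
        return a * t * t + b * t + c

    d1 = (f(x + h) - f(x - h)) / (2.0 * h)
    d2 = (f(x + h) - 2.0 * f(x) + f(x - h)) / (h * h)
    return np.abs(d2) / (1.0 + d1 ** 2) ** 1.5
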