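"""Eyelid-margin curvature measurement from binary masks.

Pipeline: trace the inner boundary of the palpebral-fissure mask in a
bottom-left (y-up) coordinate frame, split it into upper/lower lid
chains (one point per column), fit the smallest enclosing circle of the
corneal mask to get centre c(m, n) and radius r, restrict both chains to
the corneal span [m-r, m+r], fit each restricted chain with an ordinary
least-squares quadratic y = a x^2 + b x + c, and evaluate the plane-curve
curvature

    K(x) = |y''| / (1 + y'^2)^(3/2) = |2a| / (1 + (2 a x + b)^2)^(3/2)

in pixel^-1, converted to mm^-1 with the pixel scale implied by the
11.5 mm corneal horizontal diameter (or an externally supplied scale).
Mean curvature averages K at every integer column in the span; point
curvatures are reported at x = m-r, m, m+r (the Ul/Um/Ur positions).
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as P
from scipy import ndimage

CORNEAL_DIAMETER_MM = 11.5

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class MeasurementError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlanePoint:
    """Pixel coordinates with the origin at the image's bottom-left corner."""
    x: float
    y: float


@dataclass
class LidChain:
    """One lid margin: a single y per integer x, sorted by x."""
    role: str  # "upper" | "lower"
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self):
        if len(self.xs) < 2:
            raise MeasurementError("lid chain needs at least 2 columns")
        if len(np.unique(self.xs)) != len(self.xs):
            raise MeasurementError("lid chain x values must be unique")


@dataclass(frozen=True)
class CorneaCircle:
    m: float
    n: float
    r: float


@dataclass
class QuadraticFit:
    a: float
    b: float
    c: float
    domain: tuple[float, float]
    rms_residual: float
    n_points: int

    def __call__(self, x):
        return self.a * np.asarray(x, float) ** 2 + self.b * np.asarray(x, float) + self.c


@dataclass
class CurvatureReport:
    """Mean and Ul/Um/Ur point curvatures (mm^-1) for both lids."""
    upper_mean_mm: float
    lower_mean_mm: float
    point_curvatures: dict  # {"upper": {"left","center","right"}, "lower": {...}}
    pixel_scale_mm: float
    circle: CorneaCircle
    upper_fit: QuadraticFit
    lower_fit: QuadraticFit

    def to_dict(self) -> dict:
        return {
            "upper_mean_mm": self.upper_mean_mm,
            "lower_mean_mm": self.lower_mean_mm,
            "point_curvatures": self.point_curvatures,
            "pixel_scale_mm": self.pixel_scale_mm,
            "cornea": {"m": self.circle.m, "n": self.circle.n, "r": self.circle.r},
            "upper_fit": {"a": self.upper_fit.a, "b": self.upper_fit.b,
                          "c": self.upper_fit.c, "domain": list(self.upper_fit.domain),
                          "rms_residual": self.upper_fit.rms_residual},
            "lower_fit": {"a": self.lower_fit.a, "b": self.lower_fit.b,
                          "c": self.lower_fit.c, "domain": list(self.lower_fit.domain),
                          "rms_residual": self.lower_fit.rms_residual},
        }


# ---------------------------------------------------------------------
# coordinate frame and boundary tracing
# ---------------------------------------------------------------------

def to_plane_coords(row: int, col: int, height: int) -> PlanePoint:
    """Array indices -> bottom-left y-up plane coordinates."""
    if not (0 <= row < height) or col < 0:
        raise ValueError("index out of range")
    return PlanePoint(x=float(col), y=float(height - 1 - row))


def inner_boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one background 4-neighbour (boolean image)."""
    return mask & ~ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)


def trace_fissure_boundary(fissure_mask: np.ndarray) -> np.ndarray:
    """Inner boundary of the fissure mask as an (N, 2) array of plane (x, y).

    Requires a nonempty, single-4-connected-component mask (the edge set
    a Canny detector would produce on the clean binary region).
    """
    mask = np.asarray(fissure_mask, bool)
    if not mask.any():
        raise MeasurementError("empty mask")
    _, ncomp = ndimage.label(mask, structure=_CROSS)
    if ncomp != 1:
        raise MeasurementError(f"expected a single connected component, got {ncomp}")
    rows, cols = np.nonzero(inner_boundary(mask))
    h = mask.shape[0]
    return np.column_stack([cols.astype(float), (h - 1 - rows).astype(float)])


def split_lid_chains(boundary: np.ndarray, canthus_gap_px: float = 2.0
                     ) -> tuple[LidChain, LidChain]:
    """Upper chain = max y per column, lower chain = min y per column.

    Columns where the two differ by less than ``canthus_gap_px`` (the
    canthus tips, where upper and lower margins merge) are dropped.
    """
    pts = np.asarray(boundary, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("boundary must be an (N, 2) array of (x, y)")
    xs = np.round(pts[:, 0]).astype(int)
    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], pts[order, 1]
    ux, start = np.unique(xs, return_index=True)
    upper = np.maximum.reduceat(ys, start)
    lower = np.minimum.reduceat(ys, start)
    keep = (upper - lower) >= canthus_gap_px
    if keep.sum() < 2:
        raise MeasurementError("fewer than 2 usable columns after canthus exclusion")
    return (LidChain("upper", ux[keep].astype(float), upper[keep]),
            LidChain("lower", ux[keep].astype(float), lower[keep]))


# ---------------------------------------------------------------------
# smallest enclosing circle (Welzl)
# ---------------------------------------------------------------------

def _circle_two(p, q):
    cx, cy = (p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0
    r = np.hypot(p[0] - q[0], p[1] - q[1]) / 2.0
    return cx, cy, r


def _circumcircle(p, q, s):
    ax, ay = p
    bx, by = q
    cx, cy = s
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    return ux, uy, np.hypot(ax - ux, ay - uy)


def _inside(c, p, tol=1e-7):
    return np.hypot(p[0] - c[0], p[1] - c[1]) <= c[2] + tol


def min_enclosing_circle(points, shuffle_seed: int = 0) -> CorneaCircle:
    """Smallest circle containing all points (Welzl's move-to-front algorithm).

    Deterministic: the working order is a fixed shuffle of the input
    driven by ``shuffle_seed``.
    """
    pts = [tuple(map(float, p)) for p in np.asarray(points, float).reshape(-1, 2)]
    if not pts:
        raise MeasurementError("empty point set")
    rnd = random.Random(shuffle_seed)
    rnd.shuffle(pts)
    c = (pts[0][0], pts[0][1], 0.0)
    for i, p in enumerate(pts):
        if _inside(c, p):
            continue
        c = (p[0], p[1], 0.0)
        for j in range(i):
            q = pts[j]
            if _inside(c, q):
                continue
            c = _circle_two(p, q)
            for k in range(j):
                s = pts[k]
                if _inside(c, s):
                    continue
                cc = _circumcircle(p, q, s)
                if cc is not None:
                    c = cc
    return CorneaCircle(m=c[0], n=c[1], r=c[2])


def cornea_circle_from_mask(cornea_mask: np.ndarray,
                            shuffle_seed: int = 0) -> CorneaCircle:
    """Smallest enclosing circle of the corneal mask's inner boundary."""
    mask = np.asarray(cornea_mask, bool)
    if not mask.any():
        raise MeasurementError("empty cornea mask")
    rows, cols = np.nonzero(inner_boundary(mask))
    h = mask.shape[0]
    pts = np.column_stack([cols.astype(float), (h - 1 - rows).astype(float)])
    return min_enclosing_circle(pts, shuffle_seed=shuffle_seed)


# ---------------------------------------------------------------------
# span, fitting, curvature
# ---------------------------------------------------------------------

def corneal_span(circle: CorneaCircle, x_domain: tuple[float, float] | None = None,
                 min_width_px: float = 10.0) -> tuple[int, int]:
    """Horizontal corneal range [m-r, m+r], rounded and clamped to the
    chains' shared x-domain."""
    if circle.r <= 0:
        raise MeasurementError("circle radius must be positive")
    x_lo = int(round(circle.m - circle.r))
    x_hi = int(round(circle.m + circle.r))
    if x_domain is not None:
        x_lo = max(x_lo, int(np.ceil(x_domain[0])))
        x_hi = min(x_hi, int(np.floor(x_domain[1])))
    if x_hi - x_lo < min_width_px:
        raise MeasurementError(
            f"corneal span collapsed after clamping: [{x_lo}, {x_hi}]")
    return x_lo, x_hi


def fit_quadratic(chain: LidChain, x_lo: float, x_hi: float) -> QuadraticFit:
    """OLS quadratic through the chain points with x in [x_lo, x_hi]."""
    sel = (chain.xs >= x_lo) & (chain.xs <= x_hi)
    xs, ys = chain.xs[sel], chain.ys[sel]
    if len(xs) < 10:
        raise MeasurementError(
            f"need >= 10 points in [{x_lo}, {x_hi}], have {len(xs)}")
    if np.ptp(xs) == 0:
        raise MeasurementError("degenerate fit: all points share one x")
    coeffs = P.polyfit(xs, ys, 2)  # [c, b, a]
    resid = P.polyval(xs, coeffs) - ys
    return QuadraticFit(a=float(coeffs[2]), b=float(coeffs[1]), c=float(coeffs[0]),
                        domain=(float(x_lo), float(x_hi)),
                        rms_residual=float(np.sqrt(np.mean(resid ** 2))),
                        n_points=int(len(xs)))


def curvature_at(fit: QuadraticFit, x) -> np.ndarray | float:
    """Plane-curve curvature of y = a x^2 + b x + c at x, in pixel^-1."""
    slope = 2.0 * fit.a * np.asarray(x, float) + fit.b
    k = np.abs(2.0 * fit.a) / (1.0 + slope ** 2) ** 1.5
    return float(k) if np.isscalar(x) or np.ndim(x) == 0 else k


def mean_curvature(fit: QuadraticFit, x_lo: int, x_hi: int) -> float:
    """Arithmetic mean of K over every integer x in [x_lo, x_hi] inclusive."""
    xs = np.arange(int(x_lo), int(x_hi) + 1)
    if len(xs) == 0:
        raise MeasurementError("empty integer range for mean curvature")
    return float(np.mean(curvature_at(fit, xs)))


def pixel_scale(circle: CorneaCircle,
                corneal_diameter_mm: float = CORNEAL_DIAMETER_MM) -> float:
    """mm per pixel implied by the corneal calibration object: D_mm / (2r)."""
    if circle.r <= 0:
        raise MeasurementError("circle radius must be positive")
    return corneal_diameter_mm / (2.0 * circle.r)


def millimetres_per_pixel(length_mm: float, length_px: float) -> float:
    """Generic calibration ratio (e.g. sensor height 97.7 mm over 1984 px)."""
    if length_px <= 0:
        raise ValueError("pixel length must be positive")
    return length_mm / length_px


# ---------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------

def measure_eye(fissure_mask: np.ndarray, cornea_mask: np.ndarray,
                scale_mode: str = "cornea",
                corneal_diameter_mm: float = CORNEAL_DIAMETER_MM) -> CurvatureReport:
    """Run the full measurement pipeline on a pair of binary masks.

    ``scale_mode`` is ``"cornea"`` (scale from the fitted corneal circle,
    11.5 mm over 2r) or ``"fixed:<mm_per_px>"`` for an externally
    calibrated scale.
    """
    fissure = np.asarray(fissure_mask, bool)
    cornea = np.asarray(cornea_mask, bool)
    if not fissure.any() or not cornea.any():
        raise MeasurementError("refusing empty mask input")

    boundary = trace_fissure_boundary(fissure)
    upper, lower = split_lid_chains(boundary)
    circle = cornea_circle_from_mask(cornea)

    domain = (max(upper.xs.min(), lower.xs.min()),
              min(upper.xs.max(), lower.xs.max()))
    x_lo, x_hi = corneal_span(circle, domain)

    upper_fit = fit_quadratic(upper, x_lo, x_hi)
    lower_fit = fit_quadratic(lower, x_lo, x_hi)

    if scale_mode == "cornea":
        scale = pixel_scale(circle, corneal_diameter_mm)
    elif scale_mode.startswith("fixed:"):
        scale = float(scale_mode.split(":", 1)[1])
        if scale <= 0:
            raise ValueError("fixed scale must be positive mm/px")
    else:
        raise ValueError(f"unknown scale_mode {scale_mode!r}")

    # K has units 1/length: pixel^-1 -> mm^-1 divides by mm-per-pixel
    def to_mm(k_px):
        return k_px / scale

    keypoints = {"left": circle.m - circle.r, "center": circle.m,
                 "right": circle.m + circle.r}
    point_curvatures = {
        role: {name: to_mm(curvature_at(fit, x)) for name, x in keypoints.items()}
        for role, fit in (("upper", upper_fit), ("lower", lower_fit))
    }
    return CurvatureReport(
        upper_mean_mm=to_mm(mean_curvature(upper_fit, x_lo, x_hi)),
        lower_mean_mm=to_mm(mean_curvature(lower_fit, x_lo, x_hi)),
        point_curvatures=point_curvatures,
        pixel_scale_mm=scale,
        circle=circle,
        upper_fit=upper_fit,
        lower_fit=lower_fit,
    )
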