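"""Synthetic anterior-segment image generator with exact ground truth.

Each synthetic eye is an almond-shaped palpebral fissure bounded by two
quadratic arcs y = a x^2 + b x + c (y-up, origin at the bottom-left
pixel) that intersect exactly at the two canthi, plus a circular corneal
disc clipped to the fissure.  The vertex curvature of each arc, 2|a|,
converted to mm^-1 via the corneal calibration scale 11.5 mm / (2 r),
is drawn from a configurable range emulating clinically reported eyelid
curvature magnitudes (~0.2-0.25 mm^-1).

Photographs are rendered as layered flat colours (skin, sclera, iris,
pupil) with optional Gaussian noise; masks are exact rasterisations of
the generating geometry, so segmentation and measurement accuracy can
be scored against analytic truth.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

CORNEAL_DIAMETER_MM = 11.5


class GenerationError(RuntimeError):
    """Raised when no geometry satisfying the constraints exists for a seed."""


@dataclass
class EyeGeometry:
    """Ground-truth geometry of one synthetic eye (bottom-left y-up frame)."""

    upper_coeffs: tuple[float, float, float]
    lower_coeffs: tuple[float, float, float]
    canthus_left_x: float
    canthus_right_x: float
    cornea_center: tuple[float, float]
    cornea_radius: float
    image_height: int
    image_width: int

    @property
    def pixel_scale_mm(self) -> float:
        """mm per pixel implied by the 11.5 mm corneal diameter."""
        return CORNEAL_DIAMETER_MM / (2.0 * self.cornea_radius)

    def y_upper(self, x):
        a, b, c = self.upper_coeffs
        return a * np.asarray(x, float) ** 2 + b * np.asarray(x, float) + c

    def y_lower(self, x):
        a, b, c = self.lower_coeffs
        return a * np.asarray(x, float) ** 2 + b * np.asarray(x, float) + c

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EyeGeometry":
        return cls(
            upper_coeffs=tuple(d["upper_coeffs"]),
            lower_coeffs=tuple(d["lower_coeffs"]),
            canthus_left_x=float(d["canthus_left_x"]),
            canthus_right_x=float(d["canthus_right_x"]),
            cornea_center=tuple(d["cornea_center"]),
            cornea_radius=float(d["cornea_radius"]),
            image_height=int(d["image_height"]),
            image_width=int(d["image_width"]),
        )


def _through_points(a: float, x1: float, y1: float, x2: float, y2: float
                    ) -> tuple[float, float, float]:
    """Coefficients (a,b,c) of the parabola with leading coeff `a` through
    (x1,y1) and (x2,y2)."""
    b = (y2 - y1 - a * (x2 ** 2 - x1 ** 2)) / (x2 - x1)
    c = y1 - a * x1 ** 2 - b * x1
    return a, b, c


def sample_eye_geometry(rng_seed: int, height: int = 496, width: int = 744,
                        curvature_range_mm: tuple[float, float] = (0.19, 0.26),
                        max_tries: int = 200) -> EyeGeometry:
    """Draw one valid eye geometry; identical seed gives identical output.

    Vertex curvatures 2|a| of both arcs, in mm^-1 under the corneal
    calibration scale, fall inside ``curvature_range_mm``.  Raises
    :class:`GenerationError` if no admissible geometry is found within
    ``max_tries`` resampling attempts (e.g. extreme curvatures on a tiny
    canvas).
    """
    if height < 64 or width < 64:
        raise ValueError("canvas must be at least 64x64")
    lo, hi = curvature_range_mm
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("curvature_range_mm must be an interval inside (0, 1)")
    rng = np.random.default_rng(rng_seed)

    for _ in range(max_tries):
        r = rng.uniform(0.14, 0.17) * width
        scale = CORNEAL_DIAMETER_MM / (2.0 * r)  # mm per pixel
        k_up = rng.uniform(lo, hi)
        k_lo = rng.uniform(lo, hi)
        # vertex curvature 2|a| px^-1 equals k mm^-1 times scale mm/px
        a_up = -(k_up * scale) / 2.0
        a_lo = (k_lo * scale) / 2.0

        # fissure width: corneal diameter is 60-80% of it
        frac = rng.uniform(0.62, 0.78)
        half_w = (2.0 * r / frac) / 2.0
        cx = width / 2.0 + rng.uniform(-0.02, 0.02) * width
        x1, x2 = cx - half_w, cx + half_w
        if x1 < 4 or x2 > width - 5:
            continue

        # central opening height between the two arcs
        opening = (abs(a_up) + abs(a_lo)) * half_w ** 2
        if opening > 0.80 * height:
            continue

        # canthus heights (slight tilt allowed)
        tilt = rng.uniform(-0.02, 0.02) * half_w
        up_peak = abs(a_up) * half_w ** 2
        lo_dip = abs(a_lo) * half_w ** 2
        yc = height / 2.0 - (up_peak - lo_dip) / 2.0 + rng.uniform(-0.02, 0.02) * height
        y1c, y2c = yc - tilt, yc + tilt
        upper = _through_points(a_up, x1, y1c, x2, y2c)
        lower = _through_points(a_lo, x1, y1c, x2, y2c)

        g = EyeGeometry(upper, lower, x1, x2, (0.0, 0.0), r, height, width)
        top = float(np.max(g.y_upper(np.linspace(x1, x2, 200))))
        bot = float(np.min(g.y_lower(np.linspace(x1, x2, 200))))
        if top > height - 5 or bot < 4:
            continue

        # cornea centred horizontally near the fissure centre, vertically in
        # the local opening; must stay inside both the fissure and the canvas
        m = cx + rng.uniform(-0.02, 0.02) * half_w
        if m - r <= x1 + 3 or m + r >= x2 - 3:
            continue
        n = (float(g.y_upper(m)) + float(g.y_lower(m))) / 2.0
        g = EyeGeometry(upper, lower, x1, x2, (m, n), r, height, width)
        xs = np.linspace(m - r, m + r, 256)
        half_h = np.sqrt(np.maximum(r ** 2 - (xs - m) ** 2, 0.0))
        if np.all(g.y_upper(xs) >= n + half_h - 0.5) and \
           np.all(g.y_lower(xs) <= n - half_h + 0.5) and \
           n + r < height - 2 and n - r > 2:
            return g
    raise GenerationError(
        f"no admissible geometry for seed={rng_seed} on {height}x{width} "
        f"with curvature range {curvature_range_mm}"
    )


def rasterize_masks(g: EyeGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Exact rasterisation: boolean (H,W) fissure and cornea masks.

    A pixel at (row, col) has plane coordinates x=col, y=H-1-row; it is
    fissure iff y_lower(x) <= y <= y_upper(x) with x strictly between the
    canthi, and cornea iff additionally inside the corneal disc.
    """
    H, W = g.image_height, g.image_width
    cols = np.arange(W, dtype=float)
    yp = (H - 1 - np.arange(H, dtype=float))[:, None]  # plane y per row
    yu = g.y_upper(cols)[None, :]
    yl = g.y_lower(cols)[None, :]
    inside_x = ((cols >= g.canthus_left_x) & (cols <= g.canthus_right_x))[None, :]
    fissure = inside_x & (yp >= yl) & (yp <= yu)
    m, n = g.cornea_center
    cornea = ((cols[None, :] - m) ** 2 + (yp - n) ** 2 <= g.cornea_radius ** 2) & fissure
    return fissure, cornea


# base colours (RGB) for the four intensity layers
_SKIN = np.array([196, 158, 140], dtype=np.float32)
_SCLERA = np.array([232, 228, 222], dtype=np.float32)
_IRIS = np.array([112, 84, 58], dtype=np.float32)
_PUPIL = np.array([28, 24, 24], dtype=np.float32)


def render_photograph(g: EyeGeometry, masks: tuple[np.ndarray, np.ndarray],
                      rng_seed: int, noise_sd: float = 6.0) -> np.ndarray:
    """Layered flat-colour rendering plus seeded Gaussian noise (uint8 RGB)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fissure, cornea = masks
    H, W = g.image_height, g.image_width
    img = np.empty((H, W, 3), dtype=np.float32)
    img[:] = _SKIN
    img[fissure] = _SCLERA
    img[cornea] = _IRIS
    m, n = g.cornea_center
    cols = np.arange(W, dtype=float)
    yp = (H - 1 - np.arange(H, dtype=float))[:, None]
    pupil = ((cols[None, :] - m) ** 2 + (yp - n) ** 2
             <= (0.35 * g.cornea_radius) ** 2) & cornea
    img[pupil] = _PUPIL
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def write_mask_png(mask: np.ndarray, path: Path) -> None:
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


def read_mask_png(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128


def write_dataset(n: int, out_dir: str | Path, seed: int = 0, *,
                  height: int = 496, width: int = 744,
                  curvature_range_mm: tuple[float, float] = (0.19, 0.26),
                  noise_sd: float = 6.0) -> dict:
    """Write ``n`` synthetic samples plus a JSON manifest; returns the manifest.

    The train/test split emulates a 100:30 ratio: the first
    ``floor(n * 100/130)`` samples (in seed order) are training samples.
    Per sample: image PNG, fissure/cornea mask PNGs ({0,255}), and a
    ground-truth geometry JSON.  Re-running with the same arguments
    reproduces identical files.
    """
    if n < 2:
        raise ValueError("need at least 2 samples for a train/test split")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "geometry").mkdir(exist_ok=True)
    samples = []
    for i in range(n):
        g = sample_eye_geometry(seed * 100003 + i, height, width, curvature_range_mm)
        fissure, cornea = rasterize_masks(g)
        img = render_photograph(g, (fissure, cornea), seed * 100003 + i,
                                noise_sd=noise_sd)
        sid = f"eye_{i:04d}"
        Image.fromarray(img).save(out / "images" / f"{sid}.png")
        write_mask_png(fissure, out / "masks" / f"{sid}_fissure.png")
        write_mask_png(cornea, out / "masks" / f"{sid}_cornea.png")
        with open(out / "geometry" / f"{sid}.json", "w") as fh:
            json.dump(g.to_dict(), fh, indent=1)
        samples.append({
            "id": sid,
            "image": f"images/{sid}.png",
            "fissure_mask": f"masks/{sid}_fissure.png",
            "cornea_mask": f"masks/{sid}_cornea.png",
            "geometry": f"geometry/{sid}.json",
        })
    n_train = (n * 100) // 130
    manifest = {
        "seed": seed,
        "n": n,
        "height": height,
        "width": width,
        "curvature_range_mm": list(curvature_range_mm),
        "noise_sd": noise_sd,
        "train": [s["id"] for s in samples[:n_train]],
        "test": [s["id"] for s in samples[n_train:]],
        "samples": samples,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh)
    manifest["_root"] = str(path.parent)
    return manifest


def load_sample(manifest: dict, sample_id: str
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, EyeGeometry]:
    """Load (image, fissure_mask, cornea_mask, geometry) for one sample id."""
    root = Path(manifest["_root"])
    rec = next(s for s in manifest["samples"] if s["id"] == sample_id)
    img = np.asarray(Image.open(root / rec["image"]).convert("RGB"))
    fissure = read_mask_png(root / rec["fissure_mask"])
    cornea = read_mask_png(root / rec["cornea_mask"])
    with open(root / rec["geometry"]) as fh:
        g = EyeGeometry.from_dict(json.load(fh))
    return img, fissure, cornea, g
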