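"""Segmentation overlap/surface metrics and manual-vs-automatic agreement.

Overlap: IoU and Dice on binary masks.  Surface: HD95 and ASSD over the
pooled directed nearest-neighbour distances between the two masks' inner
boundaries (95th percentile with linear interpolation / mean), in
pixels.  Agreement between automatic and manual curvature series:
squared Pearson correlation r^2, MAE, RMSE, and Bland-Altman bias with
1.96-SD limits of agreement (differences oriented automatic - manual).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .measure import inner_boundary


@dataclass
class SegScores:
    iou: float
    dice: float
    hd95: float
    assd: float


@dataclass
class AgreementStats:
    r2: float
    mae: float
    rmse: float
    bias: float
    loa_low: float
    loa_high: float
    pct_within_loa: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def overlap_scores(pred_mask: np.ndarray, true_mask: np.ndarray
                   ) -> tuple[float, float]:
    """(IoU, Dice); both 1.0 when both masks are empty."""
    a = np.asarray(pred_mask, bool)
    b = np.asarray(true_mask, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    inter = np.count_nonzero(a & b)
    sa, sb = np.count_nonzero(a), np.count_nonzero(b)
    if sa + sb == 0:
        return 1.0, 1.0
    union = sa + sb - inter
    return inter / union, 2.0 * inter / (sa + sb)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(inner_boundary(np.asarray(mask, bool)))
    return np.column_stack([rows, cols]).astype(float)


def surface_scores(pred_mask: np.ndarray, true_mask: np.ndarray
                   ) -> tuple[float, float]:
    """(HD95, ASSD) in pixels over pooled directed boundary distances."""
    a = np.asarray(pred_mask, bool)
    b = np.asarray(true_mask, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("surface distances undefined for an empty mask")
    pa, pb = _boundary_points(a), _boundary_points(b)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    pooled = np.concatenate([d_ab, d_ba])
    return float(np.percentile(pooled, 95)), float(pooled.mean())


def seg_scores(pred_mask: np.ndarray, true_mask: np.ndarray) -> SegScores:
    iou, dice = overlap_scores(pred_mask, true_mask)
    hd95, assd = surface_scores(pred_mask, true_mask)
    return SegScores(iou=iou, dice=dice, hd95=hd95, assd=assd)


def agreement(auto, manual) -> tuple[float, float, float]:
    """(r2, MAE, RMSE) between paired measurement series."""
    a = np.asarray(auto, float)
    m = np.asarray(manual, float)
    if a.shape != m.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(a) == 0 or np.std(m) == 0:
        raise ValueError("zero variance in a series")
    r = np.corrcoef(a, m)[0, 1]
    d = a - m
    return float(r ** 2), float(np.mean(np.abs(d))), float(np.sqrt(np.mean(d ** 2)))


def bland_altman(auto, manual) -> tuple[float, float, float, float]:
    """(bias, loa_low, loa_high, pct_within_loa) for d = auto - manual.

    Limits of agreement are bias +/- 1.96 * SD(d) with the n-1 sample SD;
    the within-limits percentage is rounded to one decimal.
    """
    a = np.asarray(auto, float)
    m = np.asarray(manual, float)
    if a.shape != m.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("series must be 1-D, equal length, n >= 3")
    d = a - m
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    within = np.abs(d - bias) <= 1.96 * sd
    pct = round(100.0 * np.count_nonzero(within) / len(d), 1)
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, pct


def agreement_stats(auto, manual) -> AgreementStats:
    r2, mae, rmse = agreement(auto, manual)
    bias, lo, hi, pct = bland_altman(auto, manual)
    return AgreementStats(r2=r2, mae=mae, rmse=rmse, bias=bias,
                          loa_low=lo, loa_high=hi, pct_within_loa=pct)


def bland_altman_plot(auto, manual, path, title: str = "Bland-Altman") -> None:
    """Scatter of differences vs means with bias and LoA lines (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(auto, float)
    m = np.asarray(manual, float)
    bias, lo, hi, _ = bland_altman(a, m)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + m) / 2.0, a - m, s=18)
    for yv, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of automatic and manual (mm$^{-1}$)")
    ax.set_ylabel("automatic - manual (mm$^{-1}$)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
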