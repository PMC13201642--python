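"""Segmentation and image-quality evaluation battery.

Overlap metrics (Dice loss with distance-based weight maps, DSC, HD95,
precision/recall/F1, average volume difference) and reference-based image
quality metrics (PSNR/MSE, SSIM, Universal Quality Index). Degenerate inputs
never crash batch evaluation: each metric carries a defined-ness flag and the
undefined value is reported as a sentinel, not silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from wmhkit.types import (
    ConfigurationError,
    ShapeMismatchError,
    UndefinedMetricError,
    as_bool_mask,
)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class WeightMap:
    """Per-voxel Dice-loss weights in [1, 2].

    Definite-WMH voxels carry weight 2; suspected voxels carry
    1 + f(dis) with f(dis) = 1 - dis/dis_max, where dis is the Euclidean
    distance (mm) to the nearest definite-region centroid and dis_max the
    maximum such distance over suspected voxels; all other voxels weigh 1.
    """

    weights: np.ndarray
    dis_max: float


def weight_map(definite, suspected, spacing=(1.0, 1.0, 1.0)) -> WeightMap:
    """Distance-based weight map from definite and suspected lesion masks."""
    definite = as_bool_mask(definite)
    suspected = as_bool_mask(suspected)
    if definite.shape != suspected.shape:
        raise ShapeMismatchError("definite and suspected masks must align")
    if suspected.any() and not definite.any():
        raise UndefinedMetricError("suspected voxels present but no definite region")
    spacing = np.asarray(spacing, dtype=float)

    weights = np.ones(definite.shape, dtype=np.float64)
    weights[definite] = 2.0
    if suspected.any():
        labeled, n = ndimage.label(definite, structure=_CONN26)
        centroids = np.asarray(
            ndimage.center_of_mass(definite, labeled, index=range(1, n + 1))
        ) * spacing
        coords = np.argwhere(suspected) * spacing
        dis = cKDTree(centroids).query(coords)[0]
        dis_max = float(dis.max())
        f = np.ones_like(dis) if dis_max == 0 else 1.0 - dis / dis_max
        weights[suspected] = 1.0 + f
    else:
        dis_max = 0.0
    return WeightMap(weights=weights, dis_max=dis_max)


def dice_loss(pred_probs, truth, weights=None, n_classes: int = 1) -> float:
    """Dice loss 1 - (1/C) sum_c 2*sum(p*g) / (sum(p^2) + sum(g^2)).

    With ``n_classes > 1`` the leading axis of both arrays indexes classes.
    The weighted variant multiplies per-voxel weights inside both the
    numerator and denominator of each class term. A class empty in both
    prediction and truth is a vacuous agreement and contributes zero loss.
    """
    pred = np.asarray(pred_probs, dtype=np.float64)
    true = np.asarray(truth, dtype=np.float64)
    if pred.shape != true.shape:
        raise ShapeMismatchError(f"pred {pred.shape} vs truth {true.shape}")
    if np.any((pred < 0) | (pred > 1)):
        raise ConfigurationError("pred_probs must lie in [0, 1]")
    if n_classes > 1:
        if pred.shape[0] != n_classes:
            raise ShapeMismatchError(f"leading axis {pred.shape[0]} != n_classes {n_classes}")
        classes = list(zip(pred, true))
    else:
        classes = [(pred, true)]

    if weights is None:
        w = 1.0
    else:
        w = weights.weights if isinstance(weights, WeightMap) else np.asarray(weights, dtype=np.float64)
        if np.ndim(w) and w.shape != classes[0][0].shape:
            raise ShapeMismatchError("weight map must align with each class field")

    terms = []
    for p, g in classes:
        num = 2.0 * np.sum(w * p * g)
        den = np.sum(w * p**2) + np.sum(w * g**2)
        terms.append(0.0 if den == 0 else 1.0 - num / den)
    return float(np.mean(terms))


def dsc(g, p) -> float:
    """Dice similarity coefficient 2|G∩P| / (|G|+|P|); both empty -> 1."""
    g = as_bool_mask(g)
    p = as_bool_mask(p)
    if g.shape != p.shape:
        raise ShapeMismatchError("masks must align")
    denom = g.sum() + p.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(g, p).sum() / denom)


def _boundary_points(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Physical coordinates of the boundary (mask minus its erosion)."""
    eroded = ndimage.binary_erosion(mask)
    boundary = mask & ~eroded
    return np.argwhere(boundary) * spacing


def _directed_h95(src: np.ndarray, dst_tree: cKDTree) -> float:
    """Nearest-rank 95th-percentile directed distance (K = ceil(0.95 N))."""
    dists = np.sort(dst_tree.query(src)[0])
    k = max(1, math.ceil(0.95 * len(dists)))
    return float(dists[k - 1])


def hd95(g, p, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric 95th-percentile boundary distance in mm."""
    g = as_bool_mask(g)
    p = as_bool_mask(p)
    if g.shape != p.shape:
        raise ShapeMismatchError("masks must align")
    if not g.any() or not p.any():
        raise UndefinedMetricError("hd95 undefined for an empty mask")
    spacing = np.asarray(spacing, dtype=float)
    gb = _boundary_points(g, spacing)
    pb = _boundary_points(p, spacing)
    g_tree, p_tree = cKDTree(gb), cKDTree(pb)
    return max(_directed_h95(gb, p_tree), _directed_h95(pb, g_tree))


def precision_recall_f1(g, p) -> tuple[float, float, float, dict[str, bool]]:
    """Voxel-level precision, recall, F1 plus per-metric defined flags.

    Zero-denominator metrics are flagged undefined and reported as 0.
    """
    g = as_bool_mask(g)
    p = as_bool_mask(p)
    if g.shape != p.shape:
        raise ShapeMismatchError("masks must align")
    tp = float(np.logical_and(g, p).sum())
    fp = float(np.logical_and(~g, p).sum())
    fn = float(np.logical_and(g, ~p).sum())
    defined = {"precision": tp + fp > 0, "recall": tp + fn > 0}
    precision = tp / (tp + fp) if defined["precision"] else 0.0
    recall = tp / (tp + fn) if defined["recall"] else 0.0
    defined["f1"] = defined["precision"] and defined["recall"] and (precision + recall) > 0
    f1 = 2 * precision * recall / (precision + recall) if defined["f1"] else 0.0
    return precision, recall, f1, defined


def lesion_recall_f1(g, p) -> tuple[float, float]:
    """Lesion-level recall and F1 over 26-connected components of the truth.

    A truth component counts as detected if the prediction overlaps it by at
    least one voxel; precision stays voxel-level.
    """
    g = as_bool_mask(g)
    p = as_bool_mask(p)
    labeled, n = ndimage.label(g, structure=_CONN26)
    if n == 0:
        raise UndefinedMetricError("lesion recall undefined without truth lesions")
    detected = sum(1 for i in range(1, n + 1) if np.any(p[labeled == i]))
    recall = detected / n
    precision = precision_recall_f1(g, p)[0]
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return float(recall), float(f1)


def avd(p_volume: float, g_volume: float) -> float:
    """Average volume difference |A - B| / B * 100 (%)."""
    if g_volume <= 0:
        raise UndefinedMetricError("avd undefined for zero ground-truth volume")
    return float(abs(p_volume - g_volume) / g_volume * 100.0)


def psnr_mse(x, y, k_max: float = 255.0) -> tuple[float, float]:
    """(PSNR in dB, MSE). Identical images give MSE 0 and PSNR +inf."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ShapeMismatchError("images must align")
    mse = float(np.mean((x - y) ** 2))
    psnr = math.inf if mse == 0 else float(10.0 * np.log10(k_max**2 / mse))
    return psnr, mse


def ssim(
    x,
    y,
    window: int = 8,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float | None = None,
) -> float:
    """Mean structural similarity over sliding windows.

    c1 = (k1*L)^2, c2 = (k2*L)^2 with L the dynamic range (joint value range
    of both images when not given). Symmetric in its arguments. Values below 0
    are possible for strongly anticorrelated windows and are reported as
    computed.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ShapeMismatchError("images must align")
    if any(s < window for s in x.shape):
        raise ConfigurationError(f"window {window} larger than image {x.shape}")
    if dynamic_range is None:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        dynamic_range = float(hi - lo) or 1.0
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2

    size = (window,) * x.ndim

    def win_mean(a):
        return ndimage.uniform_filter(a, size=size, mode="constant")

    # restrict to fully supported windows
    core = tuple(slice(window // 2, s - (window - 1) // 2) for s in x.shape)
    mu_x = win_mean(x)[core]
    mu_y = win_mean(y)[core]
    var_x = win_mean(x * x)[core] - mu_x**2
    var_y = win_mean(y * y)[core] - mu_y**2
    cov = win_mean(x * y)[core] - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


def uqi_factors(gt, pred) -> tuple[float, float, float]:
    """The three global UQI factors: correlation, mean similarity, contrast
    similarity. Raises if either image has zero variance (the correlation and
    contrast factors are then undefined)."""
    gt = np.asarray(gt, dtype=np.float64).ravel()
    pred = np.asarray(pred, dtype=np.float64).ravel()
    if gt.size != pred.size:
        raise ShapeMismatchError("images must align")
    m1, m2 = gt.mean(), pred.mean()
    s1, s2 = gt.std(ddof=0), pred.std(ddof=0)
    if s1 == 0 or s2 == 0:
        raise UndefinedMetricError("uqi undefined for a constant image")
    cov = float(np.mean((gt - m1) * (pred - m2)))
    correlation = cov / (s1 * s2)
    mean_similarity = 2 * m1 * m2 / (m1**2 + m2**2) if (m1, m2) != (0.0, 0.0) else 1.0
    contrast_similarity = 2 * s1 * s2 / (s1**2 + s2**2)
    return float(correlation), float(mean_similarity), float(contrast_similarity)


def uqi(gt, pred, mode: str = "global", window: int = 8) -> float:
    """Universal Quality Index: correlation x mean-similarity x contrast-
    similarity, in [-1, 1]. ``mode='windowed'`` averages the product over
    sliding windows, skipping zero-variance windows."""
    if mode == "global":
        c, m, s = uqi_factors(gt, pred)
        return float(c * m * s)
    if mode != "windowed":
        raise ConfigurationError(f"unknown uqi mode {mode!r}")
    gt = np.asarray(gt, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if gt.shape != pred.shape:
        raise ShapeMismatchError("images must align")
    values = []
    for r in range(0, gt.shape[0] - window + 1):
        for col in range(0, gt.shape[1] - window + 1):
            a = gt[r : r + window, col : col + window]
            b = pred[r : r + window, col : col + window]
            if a.std() == 0 or b.std() == 0:
                continue
            c, m, s = uqi_factors(a, b)
            values.append(c * m * s)
    if not values:
        raise UndefinedMetricError("uqi: no window with nonzero variance")
    return float(np.mean(values))


@dataclass
class MetricReport:
    """The full evaluation battery with per-metric defined-ness flags."""

    dice_loss: float = math.nan
    dsc: float = math.nan
    hd95: float = math.nan
    precision: float = math.nan
    recall: float = math.nan
    f1: float = math.nan
    avd: float = math.nan
    psnr: float = math.nan
    mse: float = math.nan
    ssim: float = math.nan
    uqi: float = math.nan
    defined: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "dice_loss", "dsc", "hd95", "precision", "recall",
                "f1", "avd", "psnr", "mse", "ssim", "uqi",
            )
        }
        out["defined"] = dict(self.defined)
        return out


def evaluate(
    pred,
    truth,
    spacing=(1.0, 1.0, 1.0),
    definite=None,
    suspected=None,
    intensity_pred=None,
    intensity_truth=None,
    k_max: float = 255.0,
) -> MetricReport:
    """Run the whole battery on a predicted vs truth mask pair.

    Image-quality metrics (PSNR/MSE/SSIM/UQI) run on the intensity pair when
    given, otherwise on the 0/1 mask fields scaled to [0, k_max].
    """
    pred = as_bool_mask(pred)
    truth = as_bool_mask(truth)
    spacing = tuple(float(s) for s in spacing)
    report = MetricReport()
    report.defined = {}

    weights = None
    if definite is not None and suspected is not None:
        weights = weight_map(definite, suspected, spacing)
    report.dice_loss = dice_loss(pred.astype(float), truth, weights=weights)
    report.defined["dice_loss"] = True
    report.dsc = dsc(truth, pred)
    report.defined["dsc"] = True
    try:
        report.hd95 = hd95(truth, pred, spacing)
        report.defined["hd95"] = True
    except UndefinedMetricError:
        report.defined["hd95"] = False
    p, r, f1, flags = precision_recall_f1(truth, pred)
    report.precision, report.recall, report.f1 = p, r, f1
    report.defined.update(flags)
    voxel = float(np.prod(spacing))
    try:
        report.avd = avd(pred.sum() * voxel, truth.sum() * voxel)
        report.defined["avd"] = True
    except UndefinedMetricError:
        report.defined["avd"] = False

    if intensity_pred is None or intensity_truth is None:
        intensity_pred = pred.astype(np.float64) * k_max
        intensity_truth = truth.astype(np.float64) * k_max
    report.psnr, report.mse = psnr_mse(intensity_truth, intensity_pred, k_max=k_max)
    report.defined["psnr"] = True
    report.defined["mse"] = True
    try:
        report.ssim = ssim(intensity_truth, intensity_pred, dynamic_range=k_max)
        report.defined["ssim"] = True
    except ConfigurationError:
        report.defined["ssim"] = False
    try:
        report.uqi = uqi(intensity_truth, intensity_pred)
        report.defined["uqi"] = True
    except UndefinedMetricError:
        report.defined["uqi"] = False
    return report
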