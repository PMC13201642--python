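"""Intensity standardization and candidate-lesion detection.

The chain: per-class statistics over a labeled calibration volume, modal
intensity of a new image, shifted piecewise contrast-stretch bounds, the
[1, 255] piecewise rescale, median (+ optional Gaussian) denoising, z-score +
min-max normalization, adaptive thresholding at mu_B + k*sigma_B, morphological
opening, lesion volume, and tissue-weighted input composition. Geometry
standardization resamples in-plane to a target spacing and center-crops/pads
to a target matrix size, leaving the through-plane axis untouched.

Brain-class statistics (mu_B, sigma_B) are recomputed on the input of each
stage that uses them, over the supplied brain mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball
from skimage.transform import resize

from wmhkit.types import (
    ConfigurationError,
    DegenerateBoundsError,
    EmptyClassError,
    LabelMap,
    ShapeMismatchError,
    Volume,
    ZeroVarianceError,
    as_bool_mask,
)


@dataclass
class ClassStats:
    """Sample statistics of one tissue class.

    ``sd`` is the population standard deviation (divisor n, not n-1).
    The intensity histogram realizes the class PDF: the Dirac-delta mixture
    definition is not directly computable, so it is discretized as a
    normalized histogram with a configurable bin count.
    """

    class_id: int
    n: int
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    max_intensity: float


@dataclass
class TransformBounds:
    """Bounds of the piecewise linear contrast stretch."""

    p_min: float
    p_max: float
    mu_T_new: float
    mu_V_new: float
    n_pdf: float


@dataclass
class SegmentationParams:
    """Tunable parameters of the candidate-lesion stage."""

    k: float = 2.0  # threshold multiplier in T = mu_B + k*sigma_B
    structuring_radius: int = 1  # ball radius (voxels) of the opening element
    w_B: float = 1.0  # tissue weights of the composite input
    w_T: float = 0.0
    w_V: float = 0.0

    def __post_init__(self) -> None:
        if self.structuring_radius < 1:
            raise ConfigurationError("structuring_radius must be >= 1")
        if min(self.w_B, self.w_T, self.w_V) < 0:
            raise ConfigurationError("tissue weights must be >= 0")


def estimate_class_stats(
    volume: Volume, labels: LabelMap, class_id: int, n_bins: int = 256
) -> ClassStats:
    """Mean, population sd, histogram, and maximum of one labeled class."""
    if volume.shape != labels.shape:
        raise ShapeMismatchError(f"volume {volume.shape} vs labels {labels.shape}")
    values = volume.data[labels.data == class_id]
    if values.size == 0:
        raise EmptyClassError(f"class {class_id} has no voxels")
    counts, edges = np.histogram(values, bins=n_bins)
    return ClassStats(
        class_id=class_id,
        n=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        bin_edges=edges,
        counts=counts,
        max_intensity=float(values.max()),
    )


def pdf_mode(volume: Volume, mask, n_bins: int = 256) -> float:
    """Center of the maximal histogram bin over the masked voxels.

    Ties are broken toward the lowest-intensity bin.
    """
    mask = as_bool_mask(mask)
    values = volume.data[mask]
    if values.size == 0:
        raise EmptyClassError("pdf_mode: empty mask")
    counts, edges = np.histogram(values, bins=n_bins)
    i = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
    return float(0.5 * (edges[i] + edges[i + 1]))


def transform_bounds(
    stats_T: ClassStats, stats_V: ClassStats, n_pdf: float, n_max_B: float
) -> TransformBounds:
    """Shifted contrast-stretch bounds.

    mu_T_new = N_PDF - N_max^B + mu_T (analogously for the vessel class);
    p_min = mu_T_new - 3 sigma_T, p_max = mu_V_new + 3 sigma_V.
    """
    shift = n_pdf - n_max_B
    mu_T_new = shift + stats_T.mean
    mu_V_new = shift + stats_V.mean
    p_min = mu_T_new - 3.0 * stats_T.sd
    p_max = mu_V_new + 3.0 * stats_V.sd
    if not p_min < p_max:
        raise DegenerateBoundsError(f"p_min={p_min} >= p_max={p_max}")
    return TransformBounds(p_min=p_min, p_max=p_max, mu_T_new=mu_T_new, mu_V_new=mu_V_new, n_pdf=n_pdf)


def piecewise_rescale(volume: Volume, bounds: TransformBounds) -> Volume:
    """Stretch [p_min, p_max] affinely to [1, 255]; everything else to 0."""
    data = volume.data.astype(np.float64)
    inside = (data >= bounds.p_min) & (data <= bounds.p_max)
    out = np.zeros_like(data)
    out[inside] = (data[inside] - bounds.p_min) / (bounds.p_max - bounds.p_min) * 254.0 + 1.0
    return volume.with_data(out)


def _gaussian_kernel_1d(sigma: float, truncate: float = 3.0) -> np.ndarray:
    radius = max(1, int(np.ceil(truncate * sigma)))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def denoise(
    volume: Volume, median_window: int = 3, gaussian_sigma: float | None = None
) -> Volume:
    """Cubic-neighbourhood median filter, then optional Gaussian smoothing.

    The discrete Gaussian kernel is normalized to unit sum and truncated at
    3 sigma; both filters replicate edges.
    """
    if median_window < 1 or median_window % 2 == 0:
        raise ConfigurationError(f"median_window must be odd and >= 1, got {median_window}")
    out = volume.data.astype(np.float64)
    if median_window > 1:
        out = ndimage.median_filter(out, size=median_window, mode="nearest")
    if gaussian_sigma is not None and gaussian_sigma > 0:
        k = _gaussian_kernel_1d(gaussian_sigma)
        for axis in range(3):  # separable 3-D Gaussian
            out = ndimage.correlate1d(out, k, axis=axis, mode="nearest")
    return volume.with_data(out)


def normalize(
    volume: Volume, mask, percentile_clip: tuple[float, float] | None = None
) -> Volume:
    """Z-score over the brain mask, then min-max scale the volume to [0, 1].

    With ``percentile_clip=(2, 95)``, mu_B and sigma_B are computed from the
    masked intensities restricted to that percentile band (the values
    themselves are not clipped).
    """
    mask = as_bool_mask(mask)
    values = volume.data[mask]
    if values.size == 0:
        raise EmptyClassError("normalize: empty mask")
    if percentile_clip is not None:
        lo, hi = np.percentile(values, percentile_clip)
        values = values[(values >= lo) & (values <= hi)]
    mu, sigma = float(values.mean()), float(values.std(ddof=0))
    if sigma == 0:
        raise ZeroVarianceError("normalize: constant masked region")
    z = (volume.data - mu) / sigma
    zmin, zmax = float(z.min()), float(z.max())
    if zmax == zmin:
        raise ZeroVarianceError("normalize: constant volume")
    return volume.with_data((z - zmin) / (zmax - zmin))


def candidate_wmh(volume: Volume, mask, k: float) -> np.ndarray:
    """Adaptive threshold: true where I >= mu_B + k*sigma_B, within the mask."""
    mask = as_bool_mask(mask)
    values = volume.data[mask]
    if values.size == 0:
        raise EmptyClassError("candidate_wmh: empty mask")
    threshold = float(values.mean()) + k * float(values.std(ddof=0))
    return (volume.data >= threshold) & mask


def split_definite_suspected(
    volume: Volume, mask, k_lo: float = 2.0, k_hi: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Default definite/suspected decomposition of a candidate field.

    Definite WMH: intensity >= mu_B + k_hi*sigma_B; suspected WMH: the
    [mu_B + k_lo*sigma_B, mu_B + k_hi*sigma_B) band, both within the mask.
    """
    if not k_lo < k_hi:
        raise ConfigurationError(f"need k_lo < k_hi, got ({k_lo}, {k_hi})")
    mask = as_bool_mask(mask)
    values = volume.data[mask]
    if values.size == 0:
        raise EmptyClassError("split_definite_suspected: empty mask")
    mu, sigma = float(values.mean()), float(values.std(ddof=0))
    definite = (volume.data >= mu + k_hi * sigma) & mask
    suspected = (volume.data >= mu + k_lo * sigma) & mask & ~definite
    return definite, suspected


def morph_open(mask, structuring_radius: int = 1, element: np.ndarray | None = None) -> np.ndarray:
    """Erosion then dilation; default element is a ball of the given voxel
    radius, or pass an explicit structuring element (e.g. a box)."""
    if structuring_radius < 1:
        raise ConfigurationError("structuring_radius must be >= 1")
    mask = as_bool_mask(mask)
    if element is None:
        element = ball(structuring_radius)
    return ndimage.binary_opening(mask, structure=element)


def lesion_volume(mask, spacing) -> float:
    """True-voxel count times the physical voxel volume (mm^3)."""
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ConfigurationError(f"spacing must be positive, got {spacing}")
    return float(np.count_nonzero(as_bool_mask(mask))) * float(np.prod(spacing))


def compose_input(i_m: Volume, i_wmh, i_vessel, params: SegmentationParams) -> Volume:
    """Pointwise w_B*I_m + w_T*I_WMH + w_V*I_vessel."""
    i_wmh = as_bool_mask(i_wmh).astype(np.float64)
    i_vessel = as_bool_mask(i_vessel).astype(np.float64)
    if not (i_m.shape == i_wmh.shape == i_vessel.shape):
        raise ShapeMismatchError(
            f"shapes differ: {i_m.shape}, {i_wmh.shape}, {i_vessel.shape}"
        )
    out = params.w_B * i_m.data + params.w_T * i_wmh + params.w_V * i_vessel
    return i_m.with_data(out)


def standardize_geometry(
    volume: Volume, target_inplane: int = 200, target_spacing: float = 0.5
) -> Volume:
    """Resample in-plane axes to ``target_spacing`` mm (linear interpolation),
    then center-crop or zero-pad each to ``target_inplane``; the z axis is
    untouched."""
    sx, sy, sz = volume.spacing
    nx = max(1, int(round(volume.shape[0] * sx / target_spacing)))
    ny = max(1, int(round(volume.shape[1] * sy / target_spacing)))
    data = volume.data.astype(np.float64)
    if (nx, ny) != volume.shape[:2]:
        data = resize(
            data,
            (nx, ny, volume.shape[2]),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )

    def _fit(arr: np.ndarray, axis: int, target: int) -> np.ndarray:
        size = arr.shape[axis]
        if size > target:  # center crop
            start = (size - target) // 2
            sl = [slice(None)] * arr.ndim
            sl[axis] = slice(start, start + target)
            return arr[tuple(sl)]
        if size < target:  # symmetric zero pad
            before = (target - size) // 2
            after = target - size - before
            pad = [(0, 0)] * arr.ndim
            pad[axis] = (before, after)
            return np.pad(arr, pad)
        return arr

    data = _fit(_fit(data, 0, target_inplane), 1, target_inplane)
    return Volume(data=data, spacing=(target_spacing, target_spacing, sz), affine=volume.affine)


def run_pipeline_stages(
    volume: Volume,
    brain_mask,
    bounds: TransformBounds,
    params: SegmentationParams,
    median_window: int = 3,
    gaussian_sigma: float | None = None,
    percentile_clip: tuple[float, float] | None = None,
) -> dict[str, object]:
    """Rescale -> denoise -> normalize -> threshold -> open, returning every
    intermediate stage keyed by name."""
    brain_mask = as_bool_mask(brain_mask)
    rescaled = piecewise_rescale(volume, bounds)
    denoised = denoise(rescaled, median_window=median_window, gaussian_sigma=gaussian_sigma)
    normalized = normalize(denoised, brain_mask, percentile_clip=percentile_clip)
    candidate = candidate_wmh(normalized, brain_mask, params.k)
    opened = morph_open(candidate, params.structuring_radius)
    return {
        "rescaled": rescaled,
        "denoised": denoised,
        "normalized": normalized,
        "candidate": candidate,
        "opened": opened,
    }
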