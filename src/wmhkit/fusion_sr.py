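"""Blockwise-DCT image fusion and a desk-scale super-resolution mapping.

Fusion partitions each source image into non-overlapping 8x8 blocks, measures
per-block quality as the ratio of high- to low-frequency AC energy (zigzag
indices 32-63 over 1-31, DC excluded), keeps the full coefficient set of the
winning source per block, smooths the decision map by a 3x3 majority vote
(consistency verification), and reconstructs via the inverse DCT.

The orthonormal 2-D DCT-II pair is used throughout so that reconstruction is
exact; fusion depends only on relative AC energies, so the choice of
normalization does not affect which block wins.

The super-resolution path routes 10x10 patches by variance (textured patches
to a three-block convolutional mapping, flat ones to bicubic upsampling) and
trains the tiny filter bank by particle-swarm search on a mean
sum-of-squared-residuals loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn
from scipy.signal import correlate2d
from skimage.transform import resize

from wmhkit.types import ConfigurationError, ShapeMismatchError

BLOCK = 8
#: BQ denominator regularizer and cap.
EPSILON = 1e-12
BQ_CAP = 1e12


def _zigzag_indices(n: int = BLOCK) -> np.ndarray:
    """(n*n, 2) row/col pairs in JPEG zigzag order (index 0 = DC)."""
    order = sorted(
        ((r, c) for r in range(n) for c in range(n)),
        key=lambda rc: (rc[0] + rc[1], rc[1] if (rc[0] + rc[1]) % 2 == 0 else rc[0]),
    )
    return np.array(order)


_ZIGZAG = _zigzag_indices()
_ZZ_ROWS = _ZIGZAG[:, 0]
_ZZ_COLS = _ZIGZAG[:, 1]


def dct2(block: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D DCT-II of a square block."""
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or block.shape[0] != block.shape[1]:
        raise ShapeMismatchError(f"dct2 expects a square 2-D block, got {block.shape}")
    return dctn(block, norm="ortho")


def idct2(coefficients: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dct2`."""
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if coefficients.ndim != 2 or coefficients.shape[0] != coefficients.shape[1]:
        raise ShapeMismatchError(f"idct2 expects a square 2-D block, got {coefficients.shape}")
    return idctn(coefficients, norm="ortho")


@dataclass
class BlockQuality:
    """Low/high AC energies and their quality ratio for one 8x8 block."""

    low_energy: float
    high_energy: float
    bq: float


def block_quality(coefficients: np.ndarray) -> BlockQuality:
    """Quality of one 8x8 coefficient block.

    DC zeroed; squared AC coefficients read in zigzag order; L = energies at
    zigzag indices 1-31, H = 32-63; BQ = H / (L + eps), capped.
    """
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if coefficients.shape != (BLOCK, BLOCK):
        raise ShapeMismatchError(f"expected ({BLOCK},{BLOCK}) coefficients, got {coefficients.shape}")
    zz = coefficients[_ZZ_ROWS, _ZZ_COLS] ** 2
    zz[0] = 0.0  # DC removed from the quality computation only
    low = float(zz[1:32].sum())
    high = float(zz[32:64].sum())
    bq = min(high / (low + EPSILON), BQ_CAP)
    return BlockQuality(low_energy=low, high_energy=high, bq=bq)


def _pad_to_blocks(image: np.ndarray) -> np.ndarray:
    """Replicate-pad so both dimensions are multiples of the block size."""
    rows, cols = image.shape
    pr = (-rows) % BLOCK
    pc = (-cols) % BLOCK
    if pr or pc:
        image = np.pad(image, ((0, pr), (0, pc)), mode="edge")
    return image


def _blockwise_dct(image: np.ndarray) -> np.ndarray:
    """(gr, gc, 8, 8) coefficient grid of a padded image."""
    gr, gc = image.shape[0] // BLOCK, image.shape[1] // BLOCK
    blocks = image.reshape(gr, BLOCK, gc, BLOCK).transpose(0, 2, 1, 3)
    return dctn(blocks, axes=(2, 3), norm="ortho")


def _blockwise_idct(coeffs: np.ndarray) -> np.ndarray:
    gr, gc = coeffs.shape[:2]
    blocks = idctn(coeffs, axes=(2, 3), norm="ortho")
    return blocks.transpose(0, 2, 1, 3).reshape(gr * BLOCK, gc * BLOCK)


def _bq_grid(coeffs: np.ndarray) -> np.ndarray:
    """Per-block quality ratio over a (gr, gc, 8, 8) coefficient grid."""
    zz = coeffs[:, :, _ZZ_ROWS, _ZZ_COLS] ** 2
    low = zz[:, :, 1:32].sum(axis=2)
    high = zz[:, :, 32:64].sum(axis=2)
    return np.minimum(high / (low + EPSILON), BQ_CAP)


def consistency_verify(decision: np.ndarray) -> np.ndarray:
    """3x3 majority vote over a boolean decision map (edges replicated)."""
    votes = ndimage.correlate(decision.astype(np.int64), np.ones((3, 3), dtype=np.int64), mode="nearest")
    return votes * 2 > 9


def fuse(
    image_a: np.ndarray, image_b: np.ndarray, return_decision: bool = False
):
    """Blockwise-DCT fusion of two equally shaped grayscale images.

    Per block the source with the greater quality ratio wins (ties go to
    image A); the decision map is smoothed by a 3x3 majority vote; the fused
    block keeps the winner's full coefficient set including its DC.
    """
    image_a = np.asarray(image_a, dtype=np.float64)
    image_b = np.asarray(image_b, dtype=np.float64)
    if image_a.shape != image_b.shape or image_a.ndim != 2:
        raise ShapeMismatchError(f"fuse: shapes {image_a.shape} vs {image_b.shape}")
    rows, cols = image_a.shape
    pa, pb = _pad_to_blocks(image_a), _pad_to_blocks(image_b)
    ca, cb = _blockwise_dct(pa), _blockwise_dct(pb)
    choose_a = _bq_grid(ca) >= _bq_grid(cb)  # ties -> A
    choose_a = consistency_verify(choose_a)
    fused_coeffs = np.where(choose_a[:, :, None, None], ca, cb)
    fused = _blockwise_idct(fused_coeffs)[:rows, :cols]
    if return_decision:
        return fused, choose_a
    return fused


def route_patches(
    image: np.ndarray, patch_size: int = 10, var_threshold: float = 0.0
) -> tuple[list[tuple[tuple[slice, slice], np.ndarray]], list[tuple[tuple[slice, slice], np.ndarray]]]:
    """Partition an image into patches and route them by content variance.

    Patches with variance strictly greater than the threshold go to the
    super-resolution path, the rest to the plain up-sampling path. Edge
    patches may be ragged; every pixel belongs to exactly one patch.
    """
    if var_threshold < 0:
        raise ConfigurationError("var_threshold must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    sr_list: list[tuple[tuple[slice, slice], np.ndarray]] = []
    up_list: list[tuple[tuple[slice, slice], np.ndarray]] = []
    for r in range(0, image.shape[0], patch_size):
        for c in range(0, image.shape[1], patch_size):
            sl = (slice(r, min(r + patch_size, image.shape[0])),
                  slice(c, min(c + patch_size, image.shape[1])))
            patch = image[sl]
            (sr_list if patch.var() > var_threshold else up_list).append((sl, patch))
    return sr_list, up_list


def sobel_enhance(patch: np.ndarray) -> np.ndarray:
    """Gradient-magnitude patch: hypot of horizontal and vertical Sobel responses."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2:
        raise ShapeMismatchError("sobel_enhance expects a 2-D patch")
    gx = ndimage.sobel(patch, axis=0, mode="nearest")
    gy = ndimage.sobel(patch, axis=1, mode="nearest")
    return np.hypot(gx, gy)


def bicubic_upsample(patch: np.ndarray, factor: float = 2.0) -> np.ndarray:
    """Plain up-sampling path (bicubic interpolation)."""
    patch = np.asarray(patch, dtype=np.float64)
    out_shape = tuple(max(1, int(round(s * factor))) for s in patch.shape)
    return resize(patch, out_shape, order=3, mode="edge", anti_aliasing=False, preserve_range=True)


@dataclass
class SRParams:
    """Filter banks and biases of the three-block super-resolution mapping.

    S1: (m, f1, f1, n1) representation filters with n1 biases V1;
    S2: (n1, 1, 1, n2) non-linear-mapping filters with n2 biases V2;
    S3: (n2, f3, f3, out) reconstruction filters with out biases V3.
    """

    s1: np.ndarray
    v1: np.ndarray
    s2: np.ndarray
    v2: np.ndarray
    s3: np.ndarray
    v3: np.ndarray

    def __post_init__(self) -> None:
        self.s1 = np.asarray(self.s1, dtype=np.float64)
        self.s2 = np.asarray(self.s2, dtype=np.float64)
        self.s3 = np.asarray(self.s3, dtype=np.float64)
        self.v1 = np.asarray(self.v1, dtype=np.float64)
        self.v2 = np.asarray(self.v2, dtype=np.float64)
        self.v3 = np.asarray(self.v3, dtype=np.float64)
        if self.s1.ndim != 4 or self.s2.ndim != 4 or self.s3.ndim != 4:
            raise ConfigurationError("filter banks must be 4-D (in, f, f, out)")
        if self.s1.shape[3] != self.v1.size or self.s1.shape[3] != self.s2.shape[0]:
            raise ConfigurationError("layer-1/2 channel chain inconsistent")
        if self.s2.shape[3] != self.v2.size or self.s2.shape[3] != self.s3.shape[0]:
            raise ConfigurationError("layer-2/3 channel chain inconsistent")
        if self.s3.shape[3] != self.v3.size:
            raise ConfigurationError("layer-3 bias size inconsistent")

    @property
    def n_free(self) -> int:
        return sum(a.size for a in (self.s1, self.v1, self.s2, self.v2, self.s3, self.v3))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in (self.s1, self.v1, self.s2, self.v2, self.s3, self.v3)])

    def with_vector(self, vec: np.ndarray) -> "SRParams":
        vec = np.asarray(vec, dtype=np.float64)
        parts = []
        i = 0
        for a in (self.s1, self.v1, self.s2, self.v2, self.s3, self.v3):
            parts.append(vec[i : i + a.size].reshape(a.shape))
            i += a.size
        if i != vec.size:
            raise ConfigurationError(f"vector length {vec.size} != parameter count {i}")
        return SRParams(*parts)


def _conv_layer(x: np.ndarray, filters: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Same-padded multi-channel 2-D correlation: x (cin, H, W) -> (cout, H, W)."""
    cin, f, _, cout = filters.shape
    if x.shape[0] != cin:
        raise ShapeMismatchError(f"expected {cin} input channels, got {x.shape[0]}")
    out = np.empty((cout, x.shape[1], x.shape[2]))
    for o in range(cout):
        acc = np.zeros(x.shape[1:])
        for i in range(cin):
            acc += correlate2d(x[i], filters[i, :, :, o], mode="same", boundary="symm")
        out[o] = acc + biases[o]
    return out


def sr_forward(patch: np.ndarray, params: SRParams) -> np.ndarray:
    """Three-block forward pass: ReLU conv, ReLU 1x1 mapping, linear reconstruction.

    Output spatial shape equals the input's (same-padding convolutions).
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim == 2:
        x = patch[None]
    elif patch.ndim == 3:
        x = patch
    else:
        raise ShapeMismatchError("patch must be 2-D or (channels, H, W)")
    f1 = np.maximum(0.0, _conv_layer(x, params.s1, params.v1))
    f2 = np.maximum(0.0, _conv_layer(f1, params.s2, params.v2))
    f = _conv_layer(f2, params.s3, params.v3)  # no final rectification
    return f[0] if (patch.ndim == 2 and f.shape[0] == 1) else f


def sr_loss(params: SRParams, pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Mean over pairs of the sum of squared residuals of the forward pass."""
    if not pairs:
        raise ConfigurationError("sr_loss requires at least one (input, target) pair")
    total = 0.0
    for x, target in pairs:
        residual = sr_forward(x, params) - np.asarray(target, dtype=np.float64)
        total += float(np.sum(residual**2))
    return total / len(pairs)


def train_sr(pairs, swarm_config, template: SRParams | None = None) -> tuple[SRParams, float, list[float]]:
    """Minimize :func:`sr_loss` by particle-swarm search over the flattened
    filter-bank vector. Only tiny parameterizations (<= 50 free parameters)
    are accepted; larger banks are out of scope for swarm search.

    Returns (best params, best loss, per-iteration best-loss history).
    """
    from wmhkit import pso

    if template is None:
        template = SRParams(
            s1=np.zeros((1, 3, 3, 2)), v1=np.zeros(2),
            s2=np.zeros((2, 1, 1, 2)), v2=np.zeros(2),
            s3=np.zeros((2, 3, 3, 1)), v3=np.zeros(1),
        )
    if template.n_free > 50:
        raise ConfigurationError(
            f"{template.n_free} free parameters exceed the desk-scale limit of 50; "
            "shrink the filter banks or use a gradient-based trainer"
        )
    result = pso.optimize(lambda v: sr_loss(template.with_vector(v), pairs), swarm_config)
    return template.with_vector(result.position), result.value, result.history
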