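"""Synthetic brain phantoms with known tissue labels, lesions, vessels, noise.

The phantom renders the intensity structure the preprocessing chain assumes:
per-class Gaussian intensities with white-matter-hyperintensity (WMH) lesions
hyperintense relative to brain tissue, vessels as the brightest class (the
piecewise contrast-stretch bounds use the lesion mean as the lower and the
vessel mean as the upper anchor), additive Gaussian noise, and a smooth
multiplicative bias field. No anatomical realism is attempted; the purpose is
a ground-truthed test bed for every downstream module.

Label codes: 0 background, 1 brain tissue (B), 2 vessel (V), 3 suspected WMH
(a 1-voxel rim of intermediate intensity around each definite lesion),
4 definite WMH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from wmhkit.types import ConfigurationError, LabelMap, Volume

BACKGROUND = 0
BRAIN = 1
VESSEL = 2
SUSPECTED = 3
DEFINITE = 4

CLASS_NAMES = {
    BACKGROUND: "background",
    BRAIN: "brain",
    VESSEL: "vessel",
    SUSPECTED: "suspected_wmh",
    DEFINITE: "definite_wmh",
}

#: Default per-class intensity means. Vessels brighter than definite WMH,
#: definite WMH brighter than brain: the contrast-stretch window runs from
#: (lesion mean - 3 sd) up to (vessel mean + 3 sd), so the vessel class must
#: sit at the top of the intensity scale for the window to be non-degenerate.
DEFAULT_CLASS_MEANS = {
    BACKGROUND: 0.0,
    BRAIN: 100.0,
    VESSEL: 170.0,
    SUSPECTED: 120.0,
    DEFINITE: 150.0,
}
DEFAULT_CLASS_SDS = {
    BACKGROUND: 0.0,
    BRAIN: 5.0,
    VESSEL: 5.0,
    SUSPECTED: 5.0,
    DEFINITE: 5.0,
}


@dataclass
class PhantomConfig:
    """Parameters of a synthetic brain volume.

    ``noise_sd`` is a global multiplier on the per-class standard deviations:
    the realized intensity of a voxel of class c is
    ``class_means[c] * bias + noise_sd * class_sds[c] * N(0, 1)``, so
    ``noise_sd=0`` renders every voxel exactly at its class mean and
    ``noise_sd=1`` reproduces the configured per-class spreads.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_means: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MEANS))
    class_sds: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_SDS))
    n_punctate: int = 4
    n_confluent: int = 2
    lesion_radius_range: tuple[float, float] = (1.5, 4.0)  # mm
    n_vessels: int = 3
    noise_sd: float = 1.0
    bias_amplitude: float = 0.05
    rician: bool = False
    require_hyperintense: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ConfigurationError(f"shape must be 3 positive ints, got {self.shape}")
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(sd < 0 for sd in self.class_sds.values()):
            raise ConfigurationError("class sds must be >= 0")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(f"invalid lesion_radius_range {self.lesion_radius_range}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_punctate < 0 or self.n_confluent < 0 or self.n_vessels < 0:
            raise ConfigurationError("lesion and vessel counts must be >= 0")
        if self.require_hyperintense and not (
            self.class_means[DEFINITE] > self.class_means[BRAIN]
        ):
            raise ConfigurationError(
                "definite-WMH mean must exceed brain mean (hyperintense lesions); "
                "set require_hyperintense=False to override"
            )


@dataclass
class Phantom:
    """A generated volume plus its ground truth."""

    volume: Volume
    labels: LabelMap
    config: PhantomConfig

    @property
    def truth_masks(self) -> dict[int, np.ndarray]:
        """Per-class boolean masks, keyed by label code."""
        return {c: self.labels.data == c for c in CLASS_NAMES}

    @property
    def true_lesion_volume(self) -> float:
        """Physical volume (mm^3) of definite-WMH voxels."""
        return float(np.count_nonzero(self.labels.data == DEFINITE)) * self.volume.voxel_volume


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Axis-aligned ellipsoid filling ~80% of each axis: the 'brain'."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.4 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _sphere_at(shape, center, radius_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radius_vox))
    return r2 <= 1.0


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * b, with b in [-1, 1].

    Built from a few random low-order cosine modes so it is smooth at any
    resolution and exactly reproducible from the generator state.
    """
    if amplitude == 0:
        return np.ones(shape)
    coords = [np.linspace(0, np.pi, s) for s in shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    b = np.zeros(shape)
    for _ in range(3):
        freq = rng.integers(1, 3, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        b += np.cos(freq[0] * xx + phase[0]) * np.cos(freq[1] * yy + phase[1]) * np.cos(
            freq[2] * zz + phase[2]
        )
    peak = np.max(np.abs(b))
    if peak > 0:
        b /= peak
    return 1.0 + amplitude * b


def _place_lesions(labels, brain, rng, config) -> None:
    """Rejection-sample lesion centers inside an eroded brain mask.

    Erosion margin = lesion radius + rim so lesions (and their suspected rims)
    never touch the brain boundary, keeping morphological tests unambiguous.
    """
    shape = labels.shape
    lo, hi = config.lesion_radius_range
    jobs = [("punctate", lo, min(hi, lo + 0.5 * (hi - lo)))] * config.n_punctate
    jobs += [("confluent", max(lo, hi - 0.5 * (hi - lo)), hi)] * config.n_confluent
    for kind, rlo, rhi in jobs:
        radius_mm = rng.uniform(rlo, rhi)
        radius_vox = [radius_mm / s for s in config.spacing]
        margin = int(np.ceil(max(radius_vox))) + 2  # +1 rim, +1 safety
        allowed = ndimage.binary_erosion(brain, iterations=margin)
        candidates = np.argwhere(allowed & (labels == BRAIN))
        if candidates.size == 0:
            continue
        placed = False
        for _ in range(50):  # rejection sampling against overlaps
            center = candidates[rng.integers(len(candidates))]
            sphere = _sphere_at(shape, center, radius_vox)
            if kind == "confluent":
                # a blobby union of 2-3 offset spheres
                for _ in range(rng.integers(1, 3)):
                    off = rng.integers(-2, 3, size=3)
                    sphere |= _sphere_at(shape, center + off, radius_vox)
            rim = ndimage.binary_dilation(sphere) & ~sphere
            if np.all(labels[sphere | rim] == BRAIN):
                labels[sphere] = DEFINITE
                labels[rim] = SUSPECTED
                placed = True
                break
        if not placed:
            continue


def _place_vessels(labels, brain, rng, n_vessels: int) -> None:
    """Thin curvilinear vessels: 1-voxel-wide random-walk polylines."""
    shape = labels.shape
    interior = ndimage.binary_erosion(brain, iterations=3)
    candidates = np.argwhere(interior & (labels == BRAIN))
    if candidates.size == 0:
        return
    for _ in range(n_vessels):
        pos = candidates[rng.integers(len(candidates))].astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.integers(10, 25)
        for _ in range(length):
            idx = tuple(np.clip(np.round(pos).astype(int), 0, np.array(shape) - 1))
            if not interior[idx]:
                break
            if labels[idx] == BRAIN:
                labels[idx] = VESSEL
            direction += 0.3 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos += direction


def make_phantom(config: PhantomConfig) -> Phantom:
    """Generate a phantom: ellipsoidal brain, lesions, vessels, bias, noise.

    Deterministic given ``config.seed``; a single seeded generator is threaded
    through all stochastic steps (placement, bias modes, noise).
    """
    rng = np.random.default_rng(config.seed)
    shape = config.shape

    labels = np.zeros(shape, dtype=np.int16)
    brain = _ellipsoid_mask(shape)
    labels[brain] = BRAIN
    _place_vessels(labels, brain, rng, config.n_vessels)
    _place_lesions(labels, brain, rng, config)

    data = np.zeros(shape, dtype=np.float64)
    for c, mean in config.class_means.items():
        data[labels == c] = mean
    data *= _bias_field(shape, config.bias_amplitude, rng)

    if config.noise_sd > 0:
        sd_map = np.zeros(shape)
        for c, sd in config.class_sds.items():
            sd_map[labels == c] = sd
        eps = rng.normal(size=shape)
        if config.rician:
            eps2 = rng.normal(size=shape)
            noisy = np.sqrt(
                (data + config.noise_sd * sd_map * eps) ** 2
                + (config.noise_sd * sd_map * eps2) ** 2
            )
            data = noisy
        else:
            data = data + config.noise_sd * sd_map * eps
    data[labels == BACKGROUND] = 0.0

    volume = Volume(data=data, spacing=config.spacing)
    return Phantom(volume=volume, labels=LabelMap(labels, spacing=config.spacing), config=config)


def brain_mask_of(phantom: Phantom) -> np.ndarray:
    """Union of all non-background classes: the skull-stripping stand-in."""
    return phantom.labels.data != BACKGROUND
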