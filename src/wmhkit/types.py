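"""Core containers and error types shared across the toolkit."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class WMHKitError(Exception):
    """Base class for all wmhkit errors."""


class ConfigurationError(WMHKitError):
    """Invalid configuration (bad shapes, spacings, parameter ranges)."""


class EmptyClassError(WMHKitError):
    """A tissue class or mask required to be non-empty has no voxels."""


class DegenerateBoundsError(WMHKitError):
    """Piecewise-rescale bounds collapsed (p_min >= p_max)."""


class ZeroVarianceError(WMHKitError):
    """Normalization requested on a constant region."""


class ShapeMismatchError(WMHKitError):
    """Arrays that must be voxel-aligned have different shapes."""


class UndefinedMetricError(WMHKitError):
    """A metric is mathematically undefined for the given inputs."""


@dataclass
class Volume:
    """A 3-D scalar intensity field with physical voxel spacing in mm.

    The affine (if any) is carried opaquely so NIfTI round-trips preserve
    orientation; no operation in this package interprets it.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigurationError(
                f"Volume data must be 3-D, got ndim={self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing must be 3 positive floats, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ConfigurationError("Volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume sharing this one's geometry."""
        return Volume(data=data, spacing=self.spacing, affine=self.affine)


@dataclass
class LabelMap:
    """Integer label field aligned to a Volume.

    Codes: 0 background, 1 brain tissue (B), 2 vessel (V), 3 suspected WMH,
    4 definite WMH (see :mod:`wmhkit.phantom`).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigurationError(f"LabelMap must be 3-D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ConfigurationError("LabelMap data must be integer-typed")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def mask_of(self, label: int) -> np.ndarray:
        """Boolean mask of voxels carrying ``label``."""
        return self.data == label


def as_bool_mask(mask) -> np.ndarray:
    """Coerce an array-like (or Volume/LabelMap) to a boolean ndarray."""
    if isinstance(mask, (Volume, LabelMap)):
        mask = mask.data
    return np.asarray(mask).astype(bool)
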