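"""Core domain types for 3D cartilage histomorphometry.

Coordinate convention used throughout the package: arrays are indexed
``(z, y, x)`` where ``z`` is the cutting depth (slice index, increasing into
the block), ``y`` is the anterior-posterior axis and ``x`` the
medial-lateral axis. All indices are 0-based and ranges are half-open.
Physical quantities carry micrometre (µm) units unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Channel",
    "TissueLabel",
    "Compartment",
    "Group",
    "PipelineError",
    "InputError",
    "FormatError",
    "ConfigError",
    "DegenerateDataError",
    "Calibration",
    "ChannelStack",
    "BinaryVolume",
    "VOISpec",
    "VOIBox",
    "ThicknessMap",
    "MeasurementRecord",
]


class Channel(str, Enum):
    """Fluorescence acquisition channel.

    ``UV`` excites strong subchondral-bone autofluorescence; in ``CY5``
    (near-infrared) articular cartilage is the darkest structure, below both
    bone and embedding background.
    """

    UV = "uv"
    CY5 = "cy5"


class TissueLabel(str, Enum):
    BONE = "bone"
    CARTILAGE = "cartilage"
    OTHER = "other"


class Compartment(str, Enum):
    MEDIAL = "medial"
    LATERAL = "lateral"


class Group(str, Enum):
    """Experimental group of a limb in the surgical osteoarthritis model."""

    NAIVE = "naive"
    CONTRALATERAL = "contralateral"
    DMM = "dmm"


# ---------------------------------------------------------------------------
# Errors. Exit codes: 1 input, 2 configuration, 3 degenerate data.
# ---------------------------------------------------------------------------


class PipelineError(Exception):
    exit_code = 1


class InputError(PipelineError):
    exit_code = 1


class FormatError(InputError):
    """Input exists but is structurally invalid (e.g. ragged slice sizes)."""


class ConfigError(PipelineError):
    exit_code = 2


class DegenerateDataError(PipelineError):
    """Data admits no meaningful result (constant stack, empty mask, ...)."""

    exit_code = 3


# ---------------------------------------------------------------------------
# Value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Calibration:
    """Acquisition geometry of a block-face image stack.

    Parameters
    ----------
    xy_resolution : float
        In-plane sampling, µm per pixel.
    z_step : float
        Microtome cutting thickness, µm per slice.
    target_voxel : float
        Edge length, µm, of the isotropic working grid used for analysis.
    """

    xy_resolution: float = 1.218
    z_step: float = 5.0
    target_voxel: float = 5.0

    def __post_init__(self) -> None:
        for name in ("xy_resolution", "z_step", "target_voxel"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"Calibration.{name} must be strictly positive")

    @property
    def is_isotropic(self) -> bool:
        return self.xy_resolution == self.z_step == self.target_voxel

    def slice_count(self, total_depth_um: float) -> int:
        """Number of sections cut over ``total_depth_um`` of depth."""
        if total_depth_um <= 0:
            raise ConfigError("total depth must be positive")
        return int(round(total_depth_um / self.z_step))


@dataclass
class ChannelStack:
    """One sample's 3D intensity grid for one fluorescence channel."""

    channel: Channel
    voxels: np.ndarray  # (z, y, x), nonnegative intensities
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise FormatError(
                f"stack must be 3D (z, y, x) with all dims >= 1, got shape "
                f"{self.voxels.shape}"
            )
        if self.voxels.size and self.voxels.min() < 0:
            raise FormatError("stack intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryVolume:
    """A two-valued 3D mask on an isotropic grid."""

    voxels: np.ndarray  # bool, (z, y, x)
    voxel_size: float
    label: TissueLabel = TissueLabel.OTHER

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != bool:
            uniq = np.unique(self.voxels)
            if not np.isin(uniq, (0, 1)).all():
                raise FormatError("mask voxels must be two-valued")
            self.voxels = self.voxels.astype(bool)
        if self.voxels.ndim != 3:
            raise FormatError("mask must be 3D (z, y, x)")
        if not self.voxel_size > 0:
            raise ConfigError("voxel_size must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class VOISpec:
    """Physical size of the fixed volume-of-interest on each plateau."""

    width_ml: float = 500.0  # medial-lateral (x) extent, µm
    length_ap: float = 800.0  # anterior-posterior (y) extent, µm

    def __post_init__(self) -> None:
        if not (self.width_ml > 0 and self.length_ap > 0):
            raise ConfigError("VOI dimensions must be strictly positive")


@dataclass(frozen=True)
class VOIBox:
    """An axis-aligned VOI in voxel indices (half-open ranges)."""

    compartment: Compartment
    x_range: tuple[int, int]
    y_range: tuple[int, int]
    z_range: tuple[int, int]

    def __post_init__(self) -> None:
        for rng in (self.x_range, self.y_range, self.z_range):
            if rng[1] <= rng[0] or rng[0] < 0:
                raise InputError(f"invalid half-open range {rng}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(*self.z_range),
            slice(*self.y_range),
            slice(*self.x_range),
        )

    def shape(self) -> tuple[int, int, int]:
        return (
            self.z_range[1] - self.z_range[0],
            self.y_range[1] - self.y_range[0],
            self.x_range[1] - self.x_range[0],
        )


@dataclass
class ThicknessMap:
    """Per-voxel local thickness (µm), defined on mask foreground only.

    ``values`` is 0 exactly where ``source_mask`` is background; every
    foreground voxel carries a strictly positive thickness.
    """

    values: np.ndarray
    source_mask: BinaryVolume

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        fg = self.source_mask.voxels
        if self.values.shape != fg.shape:
            raise InputError("thickness map and source mask shapes differ")
        if np.any(self.values[~fg] != 0):
            raise InputError("thickness defined outside the source mask")
        if fg.any() and not np.all(self.values[fg] > 0):
            raise InputError("thickness must be strictly positive on foreground")


@dataclass(frozen=True)
class MeasurementRecord:
    """Mean cartilage thickness in one compartment VOI of one sample."""

    sample_id: str
    group: Group
    compartment: Compartment
    mean_thickness_um: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.mean_thickness_um < 0 or self.n_voxels < 0:
            raise InputError("thickness and voxel count must be nonnegative")
        if (self.mean_thickness_um == 0) != (self.n_voxels == 0):
            raise InputError("mean thickness is zero exactly when the VOI is empty")
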