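"""Core value types carried between pipeline stages.

The carriers mirror what a confocal session produces: single-channel 2D
rasters (reflectance images, cell masks, gel silhouettes), Z-stacks
(zymography), intensity-versus-angle curves, and small result records.
All angles are in degrees, measured counter-clockwise from the image
x-axis and reduced modulo 180 (fiber orientation is axial).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "Image2D",
    "ImageStack3D",
    "AngularProfile",
    "AlignmentResult",
    "FluorObject",
    "ProteaseActivityResult",
    "CellMorphology",
    "PositiveFraction",
    "GelMeasurement",
    "ContractionResult",
    "GroupSummary",
    "ComparisonResult",
]


@dataclass
class Image2D:
    """Single-channel 2D intensity raster with a physical pixel size.

    Parameters
    ----------
    pixels : (H, W) ndarray
        Non-negative, finite intensities. H, W >= 32.
    pixel_size_um : float
        Physical edge length of one pixel, micrometres.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidInputError("Image2D requires a 2D array")
        if min(self.pixels.shape) < 32:
            raise InvalidInputError(
                f"Image2D requires H, W >= 32, got {self.pixels.shape}"
            )
        if not np.isfinite(self.pixels).all():
            raise InvalidInputError("Image2D pixels must be finite")
        if (self.pixels < 0).any():
            raise InvalidInputError("Image2D pixels must be non-negative")
        if not self.pixel_size_um > 0:
            raise InvalidParameterError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageStack3D:
    """Z x H x W intensity raster with anisotropic voxel dimensions."""

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise InvalidInputError("ImageStack3D requires a 3D array")
        if self.voxels.shape[0] < 1:
            raise InvalidInputError("ImageStack3D requires Z >= 1")
        if not np.isfinite(self.voxels).all():
            raise InvalidInputError("ImageStack3D voxels must be finite")
        vz, vy, vx = self.voxel_size_um
        if not (vz > 0 and vy > 0 and vx > 0):
            raise InvalidParameterError("voxel_size_um entries must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size_um
        return vz * vy * vx

    @property
    def image_volume_um3(self) -> float:
        return float(self.voxels.size) * self.voxel_volume_um3


@dataclass
class AngularProfile:
    """Intensity-versus-angle curve over [0, 180) at a uniform step.

    The curve is circular with period 180 degrees: fiber orientation and
    the magnitude spectrum are both axial quantities.
    """

    angles_deg: np.ndarray
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.angles_deg.ndim != 1 or self.angles_deg.size == 0:
            raise InvalidInputError("angles_deg must be a non-empty 1D array")
        if self.angles_deg.shape != self.intensities.shape:
            raise InvalidInputError("angles_deg and intensities must align")
        steps = np.diff(self.angles_deg)
        if self.angles_deg.size > 1:
            step = steps[0]
            if not np.allclose(steps, step) or step <= 0:
                raise InvalidInputError("angles_deg must increase uniformly")
            if not np.isclose(self.angles_deg[0], 0.0) or not np.isclose(
                self.angles_deg[-1] + step, 180.0
            ):
                raise InvalidInputError("angles_deg must tile [0, 180)")
        if (self.intensities < 0).any():
            raise InvalidInputError("profile intensities must be non-negative")

    @property
    def step_deg(self) -> float:
        if self.angles_deg.size == 1:
            return 180.0
        return float(self.angles_deg[1] - self.angles_deg[0])

    def with_intensities(self, values: np.ndarray, normalized: bool | None = None):
        return AngularProfile(
            self.angles_deg.copy(),
            np.asarray(values, dtype=float),
            self.normalized if normalized is None else normalized,
        )


@dataclass
class AlignmentResult:
    """Peak fiber axis plus the alignment index (area under the
    control-normalized angular curve within +/- ``window_deg`` of its peak)."""

    peak_angle_deg: float
    alignment_index: float
    window_deg: float = 10.0
    flat_profile: bool = False


@dataclass
class FluorObject:
    """One segmented fluorescent digestion object in a z-stack."""

    voxel_count: int
    volume_um3: float
    mean_intensity: float
    centroid: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.voxel_count <= 0:
            raise InvalidInputError("voxel_count must be positive")


@dataclass
class ProteaseActivityResult:
    """All terms of the total-protease-activity statistic:

    total_activity = MFI * total fluorescent volume / total image volume
    """

    mean_fluorescence_intensity: float
    total_volume_um3: float
    image_volume_um3: float
    total_activity: float = field(init=False)

    def __post_init__(self) -> None:
        if self.image_volume_um3 <= 0:
            raise InvalidInputError("image volume must be positive")
        if self.mean_fluorescence_intensity < 0 or self.total_volume_um3 < 0:
            raise InvalidInputError("MFI and total volume must be non-negative")
        self.total_activity = (
            self.mean_fluorescence_intensity
            * self.total_volume_um3
            / self.image_volume_um3
        )


@dataclass
class CellMorphology:
    """Shape readout of one segmented cell."""

    centroid: tuple[float, float]
    area_px: int
    perimeter_px: float
    roundness: float
    extension_lengths_px: list[float]

    @property
    def mean_extension_px(self) -> float:
        if not self.extension_lengths_px:
            return 0.0
        return float(np.mean(self.extension_lengths_px))

    @property
    def max_extension_px(self) -> float:
        if not self.extension_lengths_px:
            return 0.0
        return float(np.max(self.extension_lengths_px))


@dataclass
class PositiveFraction:
    """Percent of marker-positive cells per image and group-level mean."""

    per_image_percent: list[float]
    group_percent: float
    n_images: int


@dataclass
class GelMeasurement:
    """Area of a gel silhouette at one timepoint."""

    timepoint_h: float
    area_px: float
    area_fraction_of_baseline: float = 1.0


@dataclass
class ContractionResult:
    """Percent surface-area loss between baseline and follow-up."""

    percent_contraction: float
    residual_area_fraction: float
    normalized_to_control: float | None = None


@dataclass
class GroupSummary:
    group_label: str
    n: int
    mean: float
    sd: float


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    pairwise: "object | None" = None  # pandas.DataFrame of adjusted pairwise p

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidInputError("p_value must lie in [0, 1]")


def asdict(obj) -> dict:
    """JSON-ready dict view of any result dataclass."""
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d
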