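"""Core data containers for the segmentation pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageStack",
    "FusedImage",
    "AggregateObject",
    "FrameMeasurement",
]


@dataclass
class ImageStack:
    """One well at one time point: an ordered set of focal planes.

    ``planes`` is a ``(n_planes, H, W)`` array; all planes share shape and
    dtype by construction.
    """

    planes: np.ndarray
    pixel_size: float
    time_index: int = 0

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValueError(
                f"planes must be (n_planes, H, W) with >= 1 plane, got {self.planes.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


@dataclass
class FusedImage:
    """Single in-focus image produced by focus fusion (or later stages).

    ``provenance`` accumulates the parameters of every operation applied,
    so the pipeline order is auditable per frame.
    """

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class AggregateObject:
    """One retained connected component and its measurements.

    ``area_px`` excludes interior holes; ``perimeter_px`` is measured on
    the outer boundary only. ``circularity`` is capped at 1.0 (raster bias
    can push raw values above 1 for near-circular objects).
    """

    label: int
    area_px: int
    area_um2: float
    perimeter_px: float
    circularity: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]


@dataclass
class FrameMeasurement:
    """Per-frame segmentation output."""

    time_index: int
    n_aggregates: int
    total_area_px: int
    objects: list[AggregateObject] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_area_px != sum(o.area_px for o in self.objects):
            raise ValueError("total_area_px must equal the sum of object areas")
        if self.n_aggregates != len(self.objects):
            raise ValueError("n_aggregates must equal len(objects)")
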