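"""Aggregation-kinetics model and acquisition geometry.

The normalized projected area of an aggregating well is modelled as a
monotone decay to a plateau::

    A(t) = a_inf + (1 - a_inf) * exp(-k * max(0, t - lag))

so that ``A(0) = 1`` by construction and ``A(t) -> a_inf`` as ``t`` grows.
The functional form is a configuration choice: any monotone decay with a
plateau would serve the downstream parameter extraction equally well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["KineticsModel", "AcquisitionGeometry", "simulate_kinetics"]


@dataclass(frozen=True)
class KineticsModel:
    """Exponential decay-to-plateau model of the normalized area curve.

    Parameters
    ----------
    a_inf:
        Plateau of the normalized projected area, in ``(0, 1]``.
    k:
        Aggregation rate in 1/h (``k = 0`` means no decay).
    lag:
        Delay in hours before the decay starts.
    """

    a_inf: float
    k: float
    lag: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.a_inf <= 1.0):
            raise ValueError(f"a_inf must be in (0, 1], got {self.a_inf}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")

    def __call__(self, t: "float | np.ndarray") -> "float | np.ndarray":
        """Evaluate the normalized area at time ``t`` (hours)."""
        t = np.asarray(t, dtype=float)
        a = self.a_inf + (1.0 - self.a_inf) * np.exp(
            -self.k * np.maximum(0.0, t - self.lag)
        )
        return float(a) if a.ndim == 0 else a

    def auc(self, window_h: float) -> float:
        """Closed-form integral of the model over ``[0, window_h]`` hours."""
        if window_h < 0:
            raise ValueError("window_h must be >= 0")
        lag = min(self.lag, window_h)
        tail = window_h - lag
        if self.k == 0:
            decay_part = tail
        else:
            decay_part = (1.0 - math.exp(-self.k * tail)) / self.k
        return self.a_inf * window_h + (1.0 - self.a_inf) * (lag + decay_part)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Geometry of one time-lapse acquisition.

    Defaults mirror the bright-field assay setup: 0.645 um/px at 10x,
    z-planes every 20 um spanning 160 um (9 planes, both endpoints
    included), one frame every 15 min.
    """

    pixel_size: float = 0.645  # um per pixel
    plane_spacing: float = 20.0  # um
    depth_span: float = 160.0  # um
    frame_interval: float = 0.25  # hours
    duration: float = 24.0  # hours
    image_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.plane_spacing <= 0 or self.depth_span < 0:
            raise ValueError("pixel_size, plane_spacing must be > 0; depth_span >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if min(self.image_shape) < 8:
            raise ValueError("image_shape too small")

    @property
    def n_planes(self) -> int:
        """Number of focal planes, endpoints included."""
        return int(math.floor(self.depth_span / self.plane_spacing)) + 1

    @property
    def plane_z(self) -> np.ndarray:
        """Z position (um) of each focal plane."""
        return np.arange(self.n_planes) * self.plane_spacing

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration / self.frame_interval)) + 1

    def times(self) -> np.ndarray:
        """Frame times in hours, from 0 to duration inclusive."""
        return np.arange(self.n_frames) * self.frame_interval


def simulate_kinetics(
    model: KineticsModel, geometry: AcquisitionGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the model curve on the acquisition time grid.

    Returns
    -------
    times, values:
        ``times`` in hours starting at 0; ``values`` is the normalized
        area, with ``values[0] == 1`` and a non-increasing profile.
    """
    times = geometry.times()
    values = model(times)
    return times, np.asarray(values, dtype=float)
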