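"""Extended depth-of-field fusion of a focal stack.

Per pixel, planes are weighted by a smoothed local focus measure (the
energy of the Laplacian-of-Gaussian response) and blended; the sharpest
plane dominates where it is in focus.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import FusedImage, ImageStack

__all__ = ["fuse_focal_planes"]

_EPS = 1e-12


def fuse_focal_planes(
    stack: ImageStack, log_sigma: float = 2.0, blend_sigma: float = 8.0
) -> FusedImage:
    """Fuse a z-stack into one in-focus image.

    ``log_sigma`` sets the scale of the Laplacian-of-Gaussian focus
    detector; ``blend_sigma`` smooths the per-plane weights so regions
    from different planes blend without seams. Output intensities stay
    within the input range. A single-plane stack is returned unchanged.
    """
    planes = np.asarray(stack.planes, dtype=float)
    if planes.shape[0] == 1:
        return FusedImage(
            pixels=planes[0].copy(),
            provenance={"op": "fuse", "log_sigma": log_sigma,
                        "blend_sigma": blend_sigma, "n_planes": 1},
        )

    weights = np.empty_like(planes)
    for i, p in enumerate(planes):
        focus = ndimage.gaussian_laplace(p, log_sigma) ** 2
        weights[i] = ndimage.gaussian_filter(focus, blend_sigma)

    wsum = weights.sum(axis=0)
    flat = wsum < _EPS  # no focus contrast anywhere in the stack
    weights = weights + _EPS
    fused = (weights * planes).sum(axis=0) / weights.sum(axis=0)
    if flat.any():
        fused[flat] = planes.mean(axis=0)[flat]
    np.clip(fused, planes.min(), planes.max(), out=fused)
    return FusedImage(
        pixels=fused,
        provenance={"op": "fuse", "log_sigma": log_sigma,
                    "blend_sigma": blend_sigma, "n_planes": planes.shape[0]},
    )
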