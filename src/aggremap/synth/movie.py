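"""Synthetic bright-field time-lapse renderer with ground truth.

Cells are dark disks on a bright background. Each frame, cell centers are
contracted radially toward the well centroid (with per-cell jitter); the
contraction factor is solved numerically so that the rendered binary
footprint tracks the kinetics model's normalized-area curve. Each focal
plane sees each cell through a depth-dependent Gaussian blur, plus
additive camera noise and a mild illumination ramp.

Ground truth (per-frame union mask and footprint area) is emitted next to
the rendered stacks so segmentation recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from ..imaging.types import ImageStack
from .model import AcquisitionGeometry, KineticsModel, simulate_kinetics

__all__ = ["SyntheticWell", "MovieGroundTruth", "SyntheticMovie", "render_movie",
           "save_movie", "load_movie"]


@dataclass(frozen=True)
class SyntheticWell:
    """Parameters of one simulated well.

    ``initial_spread`` scales the seeding radius relative to the
    close-packing radius ``cell_radius_px * sqrt(n_cells)``; larger values
    mean a looser starting cluster.
    """

    n_cells: int = 500
    cell_radius_px: float = 5.0
    initial_spread: float = 1.5
    jitter_px: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cell_radius_px <= 0:
            raise ValueError("cell_radius_px must be > 0")


@dataclass
class MovieGroundTruth:
    """Per-frame union-of-disks masks and their pixel areas."""

    masks: list  # list of (H, W) bool arrays
    footprint_px: np.ndarray  # (n_frames,)
    times: np.ndarray  # hours
    target: np.ndarray  # kinetics model sampled on the same grid

    @property
    def normalized_footprint(self) -> np.ndarray:
        return self.footprint_px / self.footprint_px[0]


@dataclass
class SyntheticMovie:
    frames: list  # list[ImageStack]
    ground_truth: MovieGroundTruth
    geometry: AcquisitionGeometry
    well: SyntheticWell
    model: KineticsModel


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return dy[keep], dx[keep]


def _paint(shape, cy, cx, dy, dx) -> np.ndarray:
    """Union-of-disks boolean mask for integer centers (cy, cx)."""
    mask = np.zeros(shape, dtype=bool)
    yy = (cy[:, None] + dy[None, :]).ravel()
    xx = (cx[:, None] + dx[None, :]).ravel()
    np.clip(yy, 0, shape[0] - 1, out=yy)
    np.clip(xx, 0, shape[1] - 1, out=xx)
    mask[yy, xx] = True
    return mask


def _solve_contraction(
    offsets: np.ndarray,
    center: np.ndarray,
    target_px: float,
    shape: tuple[int, int],
    dy: np.ndarray,
    dx: np.ndarray,
    s_hi: float = 1.5,
    tol_px: float = 25.0,
    max_iter: int = 40,
) -> tuple[float, np.ndarray]:
    """Find scale ``s`` so the footprint of ``center + s*offsets`` hits target.

    Footprint area is monotone non-decreasing in ``s`` (disks separate as
    they spread), so bisection converges; if the target is below the fully
    merged floor the lower bracket is returned.
    """

    def footprint(s: float) -> np.ndarray:
        pos = center[None, :] + s * offsets
        cy = np.round(pos[:, 0]).astype(int)
        cx = np.round(pos[:, 1]).astype(int)
        return _paint(shape, cy, cx, dy, dx)

    # a constant target (no contraction) is hit exactly at s = 1
    mask_one = footprint(1.0)
    if abs(mask_one.sum() - target_px) <= tol_px:
        return 1.0, mask_one

    lo, hi = 0.01, s_hi
    mask_hi = footprint(hi)
    if mask_hi.sum() <= target_px:
        return hi, mask_hi
    best_s, best_mask, best_err = hi, mask_hi, abs(mask_hi.sum() - target_px)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = footprint(mid)
        err = abs(m.sum() - target_px)
        if err < best_err:
            best_s, best_mask, best_err = mid, m, err
        if err <= tol_px:
            break
        if m.sum() > target_px:
            hi = mid
        else:
            lo = mid
    return best_s, best_mask


def render_movie(
    well: SyntheticWell,
    model: KineticsModel,
    geometry: AcquisitionGeometry,
    seed: "int | None" = None,
    *,
    background_level: float = 0.8,
    absorption: float = 0.95,
    blur_base_px: float = 0.3,
    blur_px_per_um: float = 0.015,
    noise_sd: float = 0.015,
    illumination_ramp: float = 0.03,
    dtype=np.uint8,
) -> SyntheticMovie:
    """Render a deterministic synthetic aggregation movie.

    Parameters not stated by any acquisition protocol (bit depth, noise,
    blur profile) are declared defaults, chosen for plausible bright-field
    contrast; all are keyword-overridable.
    """
    if seed is None:
        seed = well.seed
    rng = np.random.default_rng(seed)
    shape = geometry.image_shape
    r0 = well.cell_radius_px * np.sqrt(well.n_cells) * well.initial_spread
    margin = well.cell_radius_px + 4
    if r0 + margin > min(shape) / 2:
        raise ValueError(
            f"image shape {shape} too small to seed {well.n_cells} cells of "
            f"radius {well.cell_radius_px} px without full overlap "
            f"(needs >= {int(2 * (r0 + margin))} px per side)"
        )

    center = np.array([shape[0] / 2.0, shape[1] / 2.0])
    # uniform seeding in a disk of radius r0
    theta = rng.uniform(0, 2 * np.pi, well.n_cells)
    rad = r0 * np.sqrt(rng.uniform(0, 1, well.n_cells))
    offsets = np.column_stack([rad * np.sin(theta), rad * np.cos(theta)])
    z_cells = rng.uniform(0.0, geometry.depth_span, well.n_cells)

    dy, dx = _disk_offsets(well.cell_radius_px)
    times, target = simulate_kinetics(model, geometry)

    # depth model: bin cells to their nearest focal plane for rendering
    plane_z = geometry.plane_z
    z_bin = np.argmin(np.abs(z_cells[:, None] - plane_z[None, :]), axis=1)

    # static illumination ramp (left-to-right)
    ramp = 1.0 + illumination_ramp * (
        np.linspace(-1, 1, shape[1])[None, :] * np.ones((shape[0], 1))
    )

    frames: list[ImageStack] = []
    masks: list[np.ndarray] = []
    areas = np.zeros(len(times))
    area0: "float | None" = None
    max_level = float(np.iinfo(dtype).max)

    for ti, t in enumerate(times):
        offsets = offsets + rng.normal(0.0, well.jitter_px, offsets.shape)
        if ti == 0:
            s = 1.0
            pos = center[None, :] + offsets
            cy = np.round(pos[:, 0]).astype(int)
            cx = np.round(pos[:, 1]).astype(int)
            mask = _paint(shape, cy, cx, dy, dx)
            area0 = float(mask.sum())
        else:
            tol = max(20.0, 0.002 * area0)
            s, mask = _solve_contraction(
                offsets, center, target[ti] * area0, shape, dy, dx, tol_px=tol
            )
        masks.append(mask)
        areas[ti] = mask.sum()

        pos = center[None, :] + s * offsets
        cy = np.round(pos[:, 0]).astype(int)
        cx = np.round(pos[:, 1]).astype(int)

        # per-z-bin opacity maps, blurred per plane, composed as transmittance
        opacity = {}
        for b in np.unique(z_bin):
            sel = z_bin == b
            opacity[b] = _paint(shape, cy[sel], cx[sel], dy, dx).astype(float) * absorption

        planes = np.empty((geometry.n_planes,) + shape, dtype=dtype)
        for j, zj in enumerate(plane_z):
            trans = np.ones(shape)
            for b, op in opacity.items():
                sigma = blur_base_px + blur_px_per_um * abs(plane_z[b] - zj)
                blurred = ndimage.gaussian_filter(op, sigma)
                trans *= 1.0 - np.clip(blurred, 0.0, 0.999)
            img = background_level * ramp * trans
            img = img + rng.normal(0.0, noise_sd, shape)
            planes[j] = np.clip(img * max_level, 0, max_level).astype(dtype)
        frames.append(
            ImageStack(planes=planes, pixel_size=geometry.pixel_size, time_index=ti)
        )

    gt = MovieGroundTruth(masks=masks, footprint_px=areas, times=times, target=target)
    return SyntheticMovie(frames=frames, ground_truth=gt, geometry=geometry,
                          well=well, model=model)


def save_movie(movie: SyntheticMovie, outdir: "str | Path", overwrite: bool = False) -> Path:
    """Write one multi-page TIFF per frame plus a JSON sidecar.

    The sidecar records geometry, generator parameters, and the
    ground-truth footprint series (masks are not serialized; re-render
    with the recorded seed to recover them).
    """
    import tifffile

    outdir = Path(outdir)
    sidecar = outdir / "movie.json"
    if sidecar.exists() and not overwrite:
        raise FileExistsError(f"{sidecar} exists; pass overwrite=True to replace")
    outdir.mkdir(parents=True, exist_ok=True)
    for i, stack in enumerate(movie.frames):
        tifffile.imwrite(outdir / f"frame_{i:04d}.tif", stack.planes)
    meta = {
        "geometry": asdict(movie.geometry),
        "well": asdict(movie.well),
        "model": asdict(movie.model),
        "times_h": movie.ground_truth.times.tolist(),
        "footprint_px": movie.ground_truth.footprint_px.tolist(),
        "target": movie.ground_truth.target.tolist(),
        "n_frames": len(movie.frames),
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_movie(indir: "str | Path") -> tuple[list, dict]:
    """Load a saved movie directory: (list of ImageStack, sidecar dict)."""
    import tifffile

    indir = Path(indir)
    sidecar = indir / "movie.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    pixel_size = meta["geometry"]["pixel_size"]
    frames = []
    for i in range(meta["n_frames"]):
        planes = tifffile.imread(indir / f"frame_{i:04d}.tif")
        if planes.ndim == 2:
            planes = planes[None]
        frames.append(ImageStack(planes=planes, pixel_size=pixel_size, time_index=i))
    return frames, meta
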