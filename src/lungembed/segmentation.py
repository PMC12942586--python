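"""Embeddedness-gated seeded region growing on a 6-connected voxel grid.

A candidate voxel ``p`` of arbitrary intensity is *embedded* in lung if, for
at least ``6 − M`` of the six signed axis directions, a ray cast from ``p``
and sampled up to ``R`` voxel steps encounters at least one voxel whose HU
lies in the lung witness interval ``[I_min, I_max]``.  Region growing is a
strict-FIFO breadth-first flood fill from a single tracheal seed: a dequeued
voxel is accepted iff it is embedded, accepted voxels keep their original HU
in the output (everything else is the fill sentinel), and neighbours are only
expanded from accepted voxels.  Each voxel is enqueued at most once, so the
accepted set is exactly the 6-connected component of the embedded set that
contains the seed, and runtime is linear in the number of voxels.

Default parameters: I_min = −1500 HU, I_max = −200 HU, R = 5 voxels, M = 2,
fill = −5000.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from lungembed.errors import ParameterError
from lungembed.histogram import HUHistogram, compute_histogram
from lungembed.volume import CTVolume, LabeledVolume, SeedPoint

_AXIS_DIRECTIONS = (
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
)


@dataclass(frozen=True)
class EmbeddednessParams:
    """Parameters of the embeddedness criterion.

    Attributes
    ----------
    lung_min, lung_max : int
        Lung witness HU interval [I_min, I_max]; voxels in this range count
        as evidence of surrounding lung tissue.
    max_ray_steps : int
        R — maximum probing distance along each axis ray, in voxel steps
        (deliberately not millimetres, even under anisotropic spacing).
    max_misses : int
        M — maximum number of ray directions allowed to find no witness
        (0..6; a voxel is embedded iff misses <= M).
    fill_value : int
        Sentinel written at non-segmented voxels of the output.
    include_self : bool
        Whether ray sampling starts at the candidate voxel itself (offset 0).
        With the default True, any witness-range voxel is trivially embedded,
        so lung-intensity structures are excluded only by connectivity.
    """

    lung_min: int = -1500
    lung_max: int = -200
    max_ray_steps: int = 5
    max_misses: int = 2
    fill_value: int = -5000
    include_self: bool = True

    def __post_init__(self) -> None:
        if self.lung_min >= self.lung_max:
            raise ParameterError(
                f"lung_min must be < lung_max, got [{self.lung_min}, {self.lung_max}]"
            )
        if self.max_ray_steps < 1:
            raise ParameterError(f"max_ray_steps must be >= 1, got {self.max_ray_steps}")
        if not (0 <= self.max_misses <= 6):
            raise ParameterError(f"max_misses must be in [0, 6], got {self.max_misses}")
        if self.fill_value >= self.lung_min:
            raise ParameterError(
                f"fill_value ({self.fill_value}) must be below lung_min ({self.lung_min})"
            )


@dataclass
class SegmentationResult:
    """Output of :func:`embedded_region_growing`.

    ``labeled`` carries the original HU at accepted voxels and
    ``params.fill_value`` everywhere else; ``visited_count`` is the number of
    voxels dequeued (the accepted component plus its rejected frontier).
    """

    labeled: LabeledVolume
    voxel_count: int
    histogram: HUHistogram
    visited_count: int
    elapsed_ms: float
    params: EmbeddednessParams
    seed: SeedPoint
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Scalar kernels (numba-compiled; the pure-python wrappers below delegate here)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ray_hits(data, x, y, z, dx, dy, dz, max_steps, lung_min, lung_max, start_offset):
    nx, ny, nz = data.shape
    for o in range(start_offset, max_steps + 1):
        cx = x + o * dx
        cy = y + o * dy
        cz = z + o * dz
        if cx < 0 or cx >= nx or cy < 0 or cy >= ny or cz < 0 or cz >= nz:
            return False  # ray left the volume; out-of-bounds never witnesses
        v = data[cx, cy, cz]
        if lung_min <= v <= lung_max:
            return True
    return False


@njit(cache=True)
def _is_embedded(data, x, y, z, max_steps, lung_min, lung_max, max_misses, start_offset):
    misses = 0
    for axis in range(3):
        for sgn in range(-1, 2, 2):
            dx = sgn if axis == 0 else 0
            dy = sgn if axis == 1 else 0
            dz = sgn if axis == 2 else 0
            if not _ray_hits(
                data, x, y, z, dx, dy, dz, max_steps, lung_min, lung_max, start_offset
            ):
                misses += 1
                if misses > max_misses:
                    return False
    return True


@njit(cache=True)
def _grow(data, sx, sy, sz, max_steps, lung_min, lung_max, max_misses, fill, start_offset):
    nx, ny, nz = data.shape
    n = nx * ny * nz
    out = np.full_like(data, fill)
    visited = np.zeros(n, dtype=np.uint8)
    queue = np.empty(n, dtype=np.int64)
    head = 0
    tail = 0
    idx0 = (sx * ny + sy) * nz + sz
    queue[tail] = idx0
    tail += 1
    visited[idx0] = 1
    accepted = 0
    while head < tail:
        idx = queue[head]
        head += 1
        z = idx % nz
        r = idx // nz
        y = r % ny
        x = r // ny
        if not _is_embedded(
            data, x, y, z, max_steps, lung_min, lung_max, max_misses, start_offset
        ):
            continue
        out[x, y, z] = data[x, y, z]
        accepted += 1
        for axis in range(3):
            for sgn in range(-1, 2, 2):
                cx = x + (sgn if axis == 0 else 0)
                cy = y + (sgn if axis == 1 else 0)
                cz = z + (sgn if axis == 2 else 0)
                if cx < 0 or cx >= nx or cy < 0 or cy >= ny or cz < 0 or cz >= nz:
                    continue
                nidx = (cx * ny + cy) * nz + cz
                if visited[nidx] == 0:
                    visited[nidx] = 1
                    queue[tail] = nidx
                    tail += 1
    return out, accepted, head


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _as_data(volume) -> np.ndarray:
    if isinstance(volume, (CTVolume, LabeledVolume)):
        return volume.data
    return np.asarray(volume)


def ray_hits_range(
    volume,
    start_voxel,
    direction,
    max_steps: int,
    lung_min: int,
    lung_max: int,
    include_self: bool = True,
) -> bool:
    """True iff a ray from ``start_voxel`` along a signed axis ``direction``
    finds an in-bounds voxel in [lung_min, lung_max] within ``max_steps``.

    Sampling covers offsets 0..max_steps (1..max_steps when ``include_self``
    is False) and stops at the volume boundary.
    """
    data = _as_data(volume)
    direction = tuple(int(d) for d in direction)
    if direction not in _AXIS_DIRECTIONS:
        raise ParameterError(
            f"direction must be a signed unit axis vector, got {direction}"
        )
    x, y, z = (int(c) for c in start_voxel)
    SeedPoint((x, y, z)).check_in_bounds(data.shape)
    if max_steps < 1:
        raise ParameterError(f"max_steps must be >= 1, got {max_steps}")
    dx, dy, dz = direction
    return bool(
        _ray_hits(
            data, x, y, z, dx, dy, dz, int(max_steps), int(lung_min), int(lung_max),
            0 if include_self else 1,
        )
    )


def is_embedded(volume, voxel, params: EmbeddednessParams | None = None) -> bool:
    """Apply the embeddedness criterion at one voxel.

    Casts one ray per direction in {±x, ±y, ±z}; a direction misses iff the
    ray finds no witness.  Returns True iff misses <= params.max_misses.
    """
    params = params or EmbeddednessParams()
    data = _as_data(volume)
    x, y, z = (int(c) for c in voxel)
    SeedPoint((x, y, z)).check_in_bounds(data.shape)
    return bool(
        _is_embedded(
            data, x, y, z, params.max_ray_steps, params.lung_min, params.lung_max,
            params.max_misses, 0 if params.include_self else 1,
        )
    )


def embedded_region_growing(
    volume: CTVolume,
    seed: SeedPoint | tuple[int, int, int],
    params: EmbeddednessParams | None = None,
) -> SegmentationResult:
    """Segment the lung by BFS flood fill gated by the embeddedness criterion.

    The result is the 6-connected component, containing the seed, of the set
    of embedded voxels (empty if the seed itself is not embedded).  Accepted
    voxels keep their input HU; all others carry ``params.fill_value``.

    A warning (not an error) is emitted when the seed HU lies outside the
    lung witness interval — the expected workflow seeds in tracheal air — and
    when the result is empty.
    """
    params = params or EmbeddednessParams()
    if not isinstance(seed, SeedPoint):
        seed = SeedPoint(tuple(seed))
    data = volume.data if isinstance(volume, CTVolume) else np.asarray(volume)
    seed.check_in_bounds(data.shape)

    notes: list[str] = []
    seed_hu = int(data[seed.index])
    if not (params.lung_min <= seed_hu <= params.lung_max):
        msg = (
            f"seed HU {seed_hu} is outside the lung witness interval "
            f"[{params.lung_min}, {params.lung_max}]; expected a tracheal air seed"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    data = np.ascontiguousarray(data)
    t0 = time.perf_counter()
    out, accepted, visited_count = _grow(
        data,
        seed.index[0], seed.index[1], seed.index[2],
        params.max_ray_steps, params.lung_min, params.lung_max, params.max_misses,
        params.fill_value, 0 if params.include_self else 1,
    )
    elapsed_ms = (time.perf_counter() - t0) * 1000.0

    spacing = volume.spacing_mm if isinstance(volume, CTVolume) else (1.0, 1.0, 1.0)
    origin = volume.origin_mm if isinstance(volume, CTVolume) else (0.0, 0.0, 0.0)
    labeled = LabeledVolume(
        data=out, background_value=params.fill_value,
        spacing_mm=spacing, origin_mm=origin,
    )
    if accepted == 0:
        msg = "seed is not embedded: segmentation is empty; choose a seed inside the trachea"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    hist = compute_histogram(labeled)
    return SegmentationResult(
        labeled=labeled,
        voxel_count=int(accepted),
        histogram=hist,
        visited_count=int(visited_count),
        elapsed_ms=elapsed_ms,
        params=params,
        seed=seed,
        warnings=notes,
    )


def morphological_closing(
    labeled: LabeledVolume,
    radius_voxels: int,
    source: CTVolume | None = None,
) -> LabeledVolume:
    """Binary closing of the foreground mask (optional refinement, off by default).

    Dilation then erosion with the 6-connected cross structuring element,
    iterated ``radius_voxels`` times.  Voxels newly added to the foreground
    receive their original HU from ``source``; if holes are filled and no
    source volume is supplied, this is an error.
    """
    radius_voxels = int(radius_voxels)
    if radius_voxels < 1:
        raise ParameterError(f"closing radius must be >= 1, got {radius_voxels}")
    mask = labeled.foreground
    structure = ndimage.generate_binary_structure(3, 1)
    # pad so border voxels are not eroded away by the implicit zero boundary
    pad = radius_voxels
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    closed = ndimage.binary_closing(padded, structure=structure, iterations=radius_voxels)
    closed = closed[pad:-pad, pad:-pad, pad:-pad]

    new_voxels = closed & ~mask
    out = labeled.data.copy()
    if new_voxels.any():
        if source is None:
            raise ParameterError(
                "closing added voxels but no source volume was given to supply their HU"
            )
        if source.dims != labeled.dims:
            raise ParameterError(
                f"source dims {source.dims} do not match labeled dims {labeled.dims}"
            )
        out[new_voxels] = source.data[new_voxels]
    return LabeledVolume(
        data=out,
        background_value=labeled.background_value,
        spacing_mm=labeled.spacing_mm,
        origin_mm=labeled.origin_mm,
    )
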