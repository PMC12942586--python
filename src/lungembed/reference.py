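"""Exhaustive reference evaluation of the embeddedness criterion.

This module recomputes the segmentation by a deliberately different route
from :mod:`lungembed.segmentation`: the embeddedness predicate is evaluated
at *every* voxel with vectorised array shifts, and the accepted set is the
seed's 6-connected component of that embedded mask, extracted with
``scipy.ndimage.label``.  It shares no code with the BFS/ray-casting kernel
and serves as the independent check in tests and as the generation-time
certifier of the synthetic phantom's ground truth.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from lungembed.segmentation import EmbeddednessParams
from lungembed.volume import CTVolume, LabeledVolume, SeedPoint

_DIRECTIONS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _shift_bool(mask: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """mask translated by ``offset``; positions shifted in from outside are False."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for k, o in enumerate(offset):
        n = mask.shape[k]
        if abs(o) >= n:
            return out
        if o > 0:
            dst[k] = slice(o, n)
            src[k] = slice(0, n - o)
        elif o < 0:
            dst[k] = slice(0, n + o)
            src[k] = slice(-o, n)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def embedded_mask(volume, params: EmbeddednessParams | None = None) -> np.ndarray:
    """Boolean mask of voxels satisfying the embeddedness criterion, everywhere.

    For each direction d, a voxel's ray hits iff a witness lies at offset
    o·d for some o in {0..R} (or {1..R} without include_self); shifting the
    witness mask by −o·d brings that evidence onto the voxel itself.
    """
    params = params or EmbeddednessParams()
    data = volume.data if isinstance(volume, (CTVolume, LabeledVolume)) else np.asarray(volume)
    witness = (data >= params.lung_min) & (data <= params.lung_max)
    offsets = range(0 if params.include_self else 1, params.max_ray_steps + 1)
    misses = np.zeros(data.shape, dtype=np.int8)
    for d in _DIRECTIONS:
        hit = np.zeros(data.shape, dtype=bool)
        for o in offsets:
            hit |= _shift_bool(witness, (-o * d[0], -o * d[1], -o * d[2]))
        misses += ~hit
    return misses <= params.max_misses


def embedded_component(
    volume,
    seed: SeedPoint | tuple[int, int, int],
    params: EmbeddednessParams | None = None,
) -> np.ndarray:
    """The 6-connected component of the embedded mask containing the seed.

    Returns an all-False mask when the seed is not embedded.  This is, by
    definition, what the seeded BFS must produce.
    """
    params = params or EmbeddednessParams()
    if not isinstance(seed, SeedPoint):
        seed = SeedPoint(tuple(seed))
    emb = embedded_mask(volume, params)
    seed.check_in_bounds(emb.shape)
    if not emb[seed.index]:
        return np.zeros_like(emb)
    labels, _ = ndimage.label(emb, structure=ndimage.generate_binary_structure(3, 1))
    return labels == labels[seed.index]
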