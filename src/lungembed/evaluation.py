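"""Dice overlap evaluation between labeled volumes.

Foreground masks are derived from labeled volumes via their background
sentinels: −3000 for references exported by external tools, −5000 for this
tool's own outputs.  Volumes of unequal dimensions are rejected, never
resampled.
"""

from __future__ import annotations

import numpy as np

from lungembed.errors import GeometryError, ParameterError
from lungembed.volume import LabeledVolume

REFERENCE_BACKGROUND = -3000
OWN_BACKGROUND = -5000


def mask_from_labeled(labeled, background_value: int) -> np.ndarray:
    """Boolean foreground mask: every voxel not equal to the sentinel."""
    data = labeled.data if isinstance(labeled, LabeledVolume) else np.asarray(labeled)
    return data != background_value


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) of two binary masks.

    Raises
    ------
    GeometryError
        Masks of different dimensions (reported with both sizes).
    ParameterError
        Both masks empty (the coefficient is undefined).
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise GeometryError(
            f"images have different sizes: {mask_a.shape} vs {mask_b.shape}"
        )
    a = int(mask_a.sum())
    b = int(mask_b.sum())
    if a + b == 0:
        raise ParameterError("Dice is undefined: both masks are empty")
    return 2.0 * int(np.logical_and(mask_a, mask_b).sum()) / (a + b)


def dice_labeled(
    reference: LabeledVolume,
    test: LabeledVolume,
    reference_background: int = REFERENCE_BACKGROUND,
    test_background: int = OWN_BACKGROUND,
) -> float:
    """Dice between two labeled volumes given their background sentinels."""
    return dice(
        mask_from_labeled(reference, reference_background),
        mask_from_labeled(test, test_background),
    )
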