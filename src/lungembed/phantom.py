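"""Synthetic thoracic CT phantom with exact, certified ground truth.

The phantom realises a "theoretical lungs" model: two lung-attenuation
ellipsoids with flat bases inside a soft-tissue block, joined by an air-filled
tracheal tree entering the top face, with high-intensity vessel cylinders
(one fully internal, one protruding well beyond the lung base) and a
lung-attenuation decoy ball that is face-disconnected from the lungs.  The
ground-truth segmentation is the lungs plus the tracheal tree plus internal
structures clipped to the geometric lung boundary: the protruding vessel
segment outside the lung and the decoy ball are excluded.

Truth is defined geometrically but *certified* at generation time against the
independent exhaustive embeddedness oracle (:mod:`lungembed.reference`) run
with default parameters; generation fails loudly on any disagreement, so a
perfect-overlap validation against this phantom is well-posed by
construction.

Geometry notes (in fractions of the cubic grid size N):

* lungs: ellipsoids centred at (0.28, 0.50, 0.40)·N and (0.72, 0.50, 0.40)·N
  with semi-axes (0.15, 0.22, 0.28)·N, clipped to z >= 0.25·N.  The flat base
  gives the protruding vessel a locally flat exit patch, which keeps the
  geometric truncation unambiguous at voxel resolution (an ellipsoid pole is
  narrower than the vessel in its bottommost voxel layer).  The mediastinal
  gap (0.14·N) exceeds R, and the vertical gap between the lung tops and the
  carina connector (0.22·N minus the tube radius) exceeds 2R, at the minimum
  grid size.  Those clearances matter: a soft-tissue voxel outside the truth
  region can then collect witnesses from at most one convex structure plus,
  near a bronchus, the two diagonal tube rays — at most 3 satisfied
  directions, below the 6 − M = 4 the criterion requires.
* trachea: air tube (radius 2.5 voxels) down the grid centre from the top
  face to a carina at z = 0.90·N, a horizontal connector over the mediastinum,
  and one bronchus descending through the top pole of each lung.
* vessels: radius-1.4 cylinders; the protruding one extends R + 2 voxels
  below the lung base.
* decoy: lung-HU sphere (radius ≈ 0.06·N) in the upper anterior corner,
  far from every other structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from lungembed.errors import ParameterError, PhantomSpecError, PhantomValidationError
from lungembed.segmentation import EmbeddednessParams
from lungembed.volume import CTVolume, LabeledVolume, SeedPoint


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------

def _grid_coords(shape):
    return np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij", sparse=True,
    )


def ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    """Voxels whose centres satisfy sum(((v_k - c_k)/a_k)^2) <= 1."""
    if any(a <= 0 for a in semi_axes):
        raise ParameterError(f"ellipsoid semi-axes must be > 0, got {semi_axes}")
    x, y, z = _grid_coords(shape)
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return (
        ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    ) <= 1.0


def sphere_mask(shape, center, radius) -> np.ndarray:
    return ellipsoid_mask(shape, center, (radius, radius, radius))


def cylinder_mask(shape, axis: int, center, radius, span) -> np.ndarray:
    """Axis-aligned cylinder: axis coordinate in [span[0], span[1]] (inclusive,
    voxel indices) and lateral distance from ``center`` at most ``radius``."""
    if radius <= 0:
        raise ParameterError(f"cylinder radius must be > 0, got {radius}")
    if axis not in (0, 1, 2):
        raise ParameterError(f"axis must be 0, 1 or 2, got {axis}")
    lo, hi = int(span[0]), int(span[1])
    if lo > hi:
        raise ParameterError(f"empty cylinder span {span}")
    coords = _grid_coords(shape)
    lateral = [k for k in range(3) for _ in [None] if k != axis]
    u, v = coords[lateral[0]], coords[lateral[1]]
    cu, cv = center[lateral[0]], center[lateral[1]]
    mask = ((u - cu) ** 2 + (v - cv) ** 2) <= radius**2
    along = (coords[axis] >= lo) & (coords[axis] <= hi)
    return mask & along


def paint(data: np.ndarray, mask: np.ndarray, hu: int) -> np.ndarray:
    """Paint ``hu`` into ``data`` where ``mask``; returns the mask painted."""
    data[mask] = hu
    return mask


# ---------------------------------------------------------------------------
# Phantom specification and output
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parametric description of the theoretical lungs model.

    HU defaults place the lungs/trachea inside the default witness interval
    [−1500, −200] and everything else outside it.  ``noise_sigma`` adds
    uniform integer noise in ±sigma (off by default; certification may then
    legitimately fail and can be disabled with ``validate=False``).
    """

    n: int = 512
    spacing_mm: float = 0.5
    body_hu: int = 40
    lung_hu: int = -900
    air_hu: int = -1000
    vessel_hu: int = 200
    include_vessels: bool = True
    include_decoy: bool = True
    noise_sigma: int = 0
    rng_seed: int = 0
    validate: bool = True
    params: EmbeddednessParams = field(default_factory=EmbeddednessParams)

    def __post_init__(self) -> None:
        if self.n < 64:
            raise PhantomSpecError(
                f"grid size must be >= 64 to honour all clearance invariants, got {self.n}"
            )
        if self.spacing_mm <= 0:
            raise PhantomSpecError(f"spacing must be > 0, got {self.spacing_mm}")
        lo, hi = self.params.lung_min, self.params.lung_max
        for name in ("lung_hu", "air_hu"):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise PhantomSpecError(
                    f"{name}={v} must lie inside the witness interval [{lo}, {hi}]"
                )
        for name in ("body_hu", "vessel_hu"):
            v = getattr(self, name)
            if lo <= v <= hi:
                raise PhantomSpecError(
                    f"{name}={v} must lie outside the witness interval [{lo}, {hi}]"
                )
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be >= 0")
        max_noise_ok = min(
            self.lung_hu - lo, hi - self.lung_hu, self.air_hu - lo, hi - self.air_hu,
        )
        if self.noise_sigma > max_noise_ok:
            raise PhantomSpecError(
                f"noise_sigma={self.noise_sigma} would push lung/air HU out of the "
                f"witness interval (max admissible {max_noise_ok})"
            )


@dataclass
class PhantomOutput:
    """Realised phantom: the CT volume, its certified truth mask, the tracheal
    seed, and per-primitive voxel counts (geometric sets, before overpainting)."""

    volume: CTVolume
    truth_mask: LabeledVolume
    seed: SeedPoint
    component_volumes: dict[str, int]

    @property
    def truth_foreground(self) -> np.ndarray:
        return self.truth_mask.foreground


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomOutput:
    """Deterministically realise ``spec`` and certify its ground truth.

    Painting order (later wins): body background, trachea, lungs, vessels,
    decoy.  The only randomness (decoy/vessel jitter) comes from
    ``spec.rng_seed``.
    """
    spec = spec or PhantomSpec()
    n = spec.n
    rng = np.random.default_rng(spec.rng_seed)
    shape = (n, n, n)
    data = np.full(shape, spec.body_hu, dtype=np.int16)
    R = spec.params.max_ray_steps

    z_base = round(0.25 * n)
    z_carina = round(0.90 * n)
    lung_centers = ((0.28 * n, 0.50 * n, 0.40 * n), (0.72 * n, 0.50 * n, 0.40 * n))
    semi_axes = (0.15 * n, 0.22 * n, 0.28 * n)
    tube_r = 2.5
    vessel_r = 1.4

    # --- trachea: main tube, carina connector, two bronchi -----------------
    cx = 0.5 * n
    main = cylinder_mask(shape, 2, (cx, cx, 0), tube_r, (z_carina, n - 1))
    connector = cylinder_mask(
        shape, 0, (0, 0.5 * n, z_carina), tube_r,
        (round(0.28 * n), round(0.72 * n)),
    )
    bronchi = np.zeros(shape, dtype=bool)
    for c in lung_centers:
        bronchi |= cylinder_mask(
            shape, 2, (c[0], c[1], 0), tube_r, (round(0.58 * n), z_carina)
        )
    trachea = main | connector | bronchi
    paint(data, trachea, spec.air_hu)

    # --- lungs: ellipsoids with a flat base --------------------------------
    zs = np.arange(n).reshape(1, 1, n)
    lungs = np.zeros(shape, dtype=bool)
    lung_parts = {}
    for name, c in zip(("left_lung", "right_lung"), lung_centers):
        part = ellipsoid_mask(shape, c, semi_axes) & (zs >= z_base)
        lung_parts[name] = part
        lungs |= part
    paint(data, lungs, spec.lung_hu)

    # --- vessels ------------------------------------------------------------
    vessels = np.zeros(shape, dtype=bool)
    vessel_parts: dict[str, np.ndarray] = {}
    if spec.include_vessels:
        jx, jy = rng.integers(-round(0.03 * n), round(0.03 * n) + 1, size=2)
        internal = cylinder_mask(
            shape, 2, (lung_centers[0][0] + jx, lung_centers[0][1] + jy, 0),
            vessel_r, (round(0.35 * n), round(0.55 * n)),
        )
        protruding = cylinder_mask(
            shape, 2, (lung_centers[1][0], lung_centers[1][1], 0),
            vessel_r, (z_base - (R + 2), round(0.55 * n)),
        )
        vessel_parts = {"internal_vessel": internal, "protruding_vessel": protruding}
        vessels = internal | protruding
        paint(data, vessels, spec.vessel_hu)

    # --- decoy ball ----------------------------------------------------------
    decoy = np.zeros(shape, dtype=bool)
    if spec.include_decoy:
        jitter = rng.integers(-round(0.015 * n), round(0.015 * n) + 1, size=3)
        center = tuple(0.16 * n + j for j in jitter[:2]) + (0.84 * n + jitter[2],)
        decoy = sphere_mask(shape, center, max(4.0, 0.06 * n))
        paint(data, decoy, spec.lung_hu)

    if spec.noise_sigma > 0:
        data = (
            data.astype(np.int32)
            + rng.integers(-spec.noise_sigma, spec.noise_sigma + 1, size=shape)
        ).astype(np.int16)

    # --- invariants ---------------------------------------------------------
    interior = lungs | vessels | decoy
    bbox = ndimage.find_objects(interior.astype(np.int8))[0]
    for k, sl in enumerate(bbox):
        if sl.start < R or sl.stop > n - R:
            raise PhantomSpecError(
                f"lung-interior structures reach within {R} voxels of the border "
                f"along axis {k}"
            )
    if spec.include_decoy:
        cross = ndimage.generate_binary_structure(3, 1)
        touch = ndimage.binary_dilation(decoy, structure=cross) & (lungs | trachea | vessels)
        if touch.any():
            raise PhantomSpecError("decoy ball shares a face with lung/trachea voxels")

    # --- ground truth --------------------------------------------------------
    truth = lungs | trachea | (vessels & lungs)
    truth_data = np.where(truth, data, np.int16(spec.params.fill_value)).astype(np.int16)

    seed = SeedPoint((n // 2, n // 2, n - 3))
    spacing = (spec.spacing_mm,) * 3
    volume = CTVolume(data=data, spacing_mm=spacing)
    truth_mask = LabeledVolume(
        data=truth_data, background_value=spec.params.fill_value, spacing_mm=spacing
    )

    # --- generation-time self-validation -------------------------------------
    if spec.validate:
        from lungembed.reference import embedded_component

        oracle = embedded_component(volume, seed, spec.params)
        if not np.array_equal(oracle, truth):
            diff = int(np.logical_xor(oracle, truth).sum())
            raise PhantomValidationError(
                f"geometric truth disagrees with the exhaustive embeddedness oracle "
                f"at {diff} voxels (truth {int(truth.sum())}, oracle {int(oracle.sum())})"
            )

    component_volumes = {
        name: int(mask.sum())
        for name, mask in {
            **lung_parts,
            "trachea": trachea,
            **vessel_parts,
            **({"decoy_ball": decoy} if spec.include_decoy else {}),
        }.items()
    }
    return PhantomOutput(
        volume=volume,
        truth_mask=truth_mask,
        seed=seed,
        component_volumes=component_volumes,
    )
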