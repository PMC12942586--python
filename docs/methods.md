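# Methods

## The segmentation model

`lungembed` segments the lung from a thoracic CT volume in Hounsfield units
(HU) starting from a single user-supplied seed voxel placed in the trachea.
The difficulty it addresses is specific to diseased lungs: a pure intensity
criterion either loses high-attenuation structures that belong inside the
lung (vessels, fibrosis, reticulation) or leaks through the lung surface into
mediastinum and chest wall, and both failure modes corrupt any downstream
histogram biomarker.

The accept/reject rule is therefore geometric rather than intensity-based.
A candidate voxel *p* of arbitrary HU is **embedded** in lung when, for
enough of the six signed axis directions D = {±x, ±y, ±z}, a ray cast from
*p* and sampled at integer voxel offsets up to a probing distance R contains
at least one *witness*: a voxel whose HU lies in the lung witness interval
[I_min, I_max].  With miss budget M, *p* is embedded iff at most M of the six
rays find no witness.  Defaults are I_min = −1500 HU, I_max = −200 HU,
R = 5 voxel steps, M = 2, so a voxel needs witnesses in at least 4 of the
6 directions.  Any voxel inside lung parenchyma — whatever its own HU — is
flanked by parenchyma or air within a few voxels in most directions, while a
voxel outside the lung surface can see lung in at most a half-space of
directions.

The region is grown by strict-FIFO breadth-first search on the 6-connected
voxel grid.  A voxel is marked visited when enqueued and each voxel is
enqueued at most once; a dequeued voxel is tested with the criterion, and
only accepted voxels expand their face neighbours.  Consequently:

* the accepted set is exactly the 6-connected component of the embedded set
  that contains the seed — a pure function of (volume, seed, parameters),
  independent of queue order;
* structures of lung-like HU that are not connected to the
  tracheobronchial tree (e.g. bowel gas, or the phantom's decoy ball) are
  excluded purely by connectivity;
* runtime is linear in the number of voxels, with a constant number of ray
  samples per visited voxel.

Accepted voxels keep their original HU in the output; everything else is the
fill sentinel −5000.  No smoothing touches output values, so the output
histogram is an exact sub-multiset of the input intensities.

### Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| I_min, I_max | −1500, −200 | HU | witness interval: what counts as evidence of surrounding lung (air ≈ −1000, parenchyma ≈ −900…−700) |
| R | 5 | voxel steps | probing distance per ray; measured in voxels, not mm, even on anisotropic grids |
| M | 2 | directions | miss budget; embedded iff ≥ 6 − M rays find a witness |
| fill | −5000 | HU-like | background sentinel of the output (references exported by other tools use −3000) |
| include_self | true | — | rays sample offset 0 first, so witness-range voxels are trivially embedded |

`include_self = true` is a deliberate choice: with it, exclusion of
disconnected lung-intensity structures is purely a connectivity effect, and
lung-surface voxels at high-curvature points are not spuriously rejected.
The alternative convention (offsets 1..R) is available via
`include_self=False`.

Out-of-bounds ray samples never count as witnesses and sampling stops at the
volume border; this truncates conservatively at the edge of the field of
view rather than auto-accepting border voxels.

A seed whose HU lies outside the witness interval triggers a warning, not an
error, and a non-embedded seed yields an empty result with a warning: the
workflow is semi-automated and the user simply corrects the seed.

### Optional steps, off by default

Median/Gaussian prefilters (edge-replicated; Gaussian sigma given in mm and
converted per axis) and a morphological closing of the output mask
(6-connected cross element, dilation then erosion, iterated; filled voxels
take their HU from the source volume) are provided but disabled unless
requested — the algorithm is specified on raw HU and applies no
post-processing by itself.

## Histogram biomarkers

The histogram is an exact integer-HU frequency map over segmented voxels —
no binning, smoothing or density normalisation.  The report derives:

* the **modal 100-HU bin** (left-closed, edges aligned to multiples of 100;
  ties go to the lowest bin) — healthy lungs peak in [−900, −800);
* **fraction below −950 HU** (strict `<`) — low-attenuation burden,
  emphysema-like destruction shifts it up;
* **fraction above −200 HU** (strict `>`) — high-attenuation burden,
  fibrosis/ground-glass shifts it up.

Strictness of the thresholds is a documented convention chosen to make the
numbers reproducible; no phenotype classification rule is implemented.

## Dice evaluation

Overlap is 2|A∩B| / (|A| + |B|) on binary masks derived from labeled
volumes via their background sentinels (−3000 for external references,
−5000 for this tool's outputs).  Volumes of unequal dimensions are rejected
outright — never resampled — and two empty masks are an error, not a score.

## The synthetic phantom and what it shows

`lungembed.phantom` generates a cubic "theoretical lungs" volume (default
512³ at 0.5 mm; tests and the acceptance script use 128³ and 64³ to keep
runs in seconds) containing: two lung-HU ellipsoids with flat base planes, an
air-HU tracheal tree entering the top face and bifurcating into both lungs, a
vessel-HU cylinder fully inside one lung, a vessel-HU cylinder protruding
R + 2 voxels beyond the other lung's base, and a lung-HU decoy ball
face-disconnected from everything.  Ground truth is the lungs plus the
tracheal tree plus internal structures clipped to the geometric lung
boundary.

Two geometric choices make the ground truth exact at voxel resolution:

* the protruding vessel exits through a **flat** base plane, because at an
  ellipsoid pole the bottommost lung layer is narrower than the vessel and
  the geometric boundary would be ambiguous relative to the criterion;
* every pair of distinct structures is separated by more than R voxels
  (the mediastinal gap is 0.14·N, the lung-top-to-carina gap exceeds 2R at
  the minimum grid size N = 64), so no soft-tissue voxel can assemble four
  witness directions from two different structures; outside the truth
  region a single convex structure can satisfy at most three axis rays.

Generation always ends with **self-validation**: the geometric truth must
equal, voxel for voxel, the output of an independent exhaustive evaluation
of the criterion (vectorised shifts over the whole grid + 6-connected
component labelling, `lungembed.reference`) run with default parameters.
Generation fails loudly otherwise, so the perfect-overlap test is well-posed
by construction rather than by assumption.

What the phantom does *not* emulate: noise and reconstruction-kernel
texture (an optional bounded uniform noise field exists but is off by
default), anatomically realistic airway trees, partial-volume effects at
tissue interfaces, pleural effusion or consolidation touching the surface.
Passing the phantom validation therefore certifies the algorithm's selection
mechanism (truncation of protrusions, connectivity exclusion, preservation
of internal intensities), not clinical performance on real scans.

## Numerical and implementation choices

* Voxel arrays are indexed (x, y, z), 0-based, z the slice axis; all readers
  permute into this convention.
* Non-integer HU arising from file scale factors are rounded
  half-away-from-zero once at read time; all internal arithmetic is integer.
* The BFS kernel is a single-threaded, numba-compiled scalar loop with a
  preallocated FIFO; the visited set is marked at enqueue time, so a
  rejected frontier voxel is never re-tested (harmless: the criterion is a
  pure function of the static input).
* The independent reference route shares no code with the BFS kernel; the
  two are compared voxel-for-voxel on randomized volumes in the test suite
  and at every phantom generation.
* Determinism: identical inputs and parameters produce bit-identical labeled
  volumes, histograms and phantom files; the only randomness in the phantom
  (structure jitter) is driven by an explicit integer seed.
* Problem sizes: the validation suite runs the phantom at 64³ and 128³ and
  the oracle-equivalence battery at ≤ 32³ with 50 random draws — sizes at
  which the exhaustive reference route is itself cheap to compute.

## Known limitations

* R is counted in voxel steps; on strongly anisotropic grids the effective
  probing distance differs per axis.  An mm-based variant is deliberately
  not implemented.
* Single seed only; no automatic seeding, no airway exclusion, no surface
  distance metrics, 6-connectivity only.
* The criterion can accept thin soft-tissue bridges that are genuinely
  flanked by lung within R in ≥ 4 directions (e.g. fissure-adjacent vessels
  in real data); this is by design — such voxels are anatomically inside
  the lung envelope.
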