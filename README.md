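# lungembed

Semi-automated lung segmentation for thoracic CT, built for quantitative
analysis of interstitial lung disease (ILD) and emphysema, where classic
threshold-based region growing either drops in-lung pathology (fibrosis,
vessels) or leaks through the lung surface.

From a single seed voxel placed in the trachea, a breadth-first flood fill on
the 6-connected voxel grid accepts a voxel of **any** Hounsfield intensity
provided it is *embedded* in lung: for each of the six signed axis
directions, a ray is sampled up to R voxel steps, a direction is *satisfied*
if some sampled voxel has HU in the lung witness interval [I_min, I_max], and
the voxel is accepted iff at least 6 − M directions are satisfied.  Defaults:
I_min = −1500 HU, I_max = −200 HU, R = 5, M = 2.  Accepted voxels keep their
original HU (background is the sentinel −5000), so the post-segmentation HU
histogram supports attenuation biomarkers: the fraction of voxels below
−950 HU (emphysema) and above −200 HU (fibrosis, ground-glass).

The package also provides:

* readers/writers for DICOM series, NIfTI, MetaImage and NRRD
  (`lungembed.volume`), with optional median/Gaussian prefilters and
  morphological closing (all off by default);
* a synthetic "theoretical lungs" phantom with exact, generation-time
  certified ground truth (`lungembed.phantom`) — two lung ellipsoids, a
  tracheal tree, an internal vessel, a vessel protruding beyond the lung
  surface, and a disconnected lung-intensity decoy ball;
* exact HU histograms and report metrics (`lungembed.histogram`);
* Dice overlap evaluation with sentinel-based masks, −3000 for external
  references and −5000 for this tool's outputs (`lungembed.evaluation`);
* an independent exhaustive re-evaluation of the criterion used as a
  cross-check (`lungembed.reference`);
* a CLI: `lungembed segment | phantom | histogram | dice`.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

```python
from lungembed import (PhantomSpec, generate_phantom,
                       embedded_region_growing, dice, histogram_report)

phantom = generate_phantom(PhantomSpec(n=128, rng_seed=1))
result = embedded_region_growing(phantom.volume, phantom.seed)
score = dice(phantom.truth_mask.foreground, result.labeled.foreground)
report = histogram_report(result.histogram)
print(f"accepted voxels : {result.voxel_count}")
print(f"visited voxels  : {result.visited_count}")
print(f"Dice vs truth   : {score}")
print(f"modal HU bin    : {report.modal_bin}")
print(f"frac < -950 HU  : {report.frac_below_low:.4f}")
print(f"frac > -200 HU  : {report.frac_above_high:.4f}")
```

prints

```
accepted voxels : 143835
visited voxels  : 161586
Dice vs truth   : 1.0
modal HU bin    : (-900, -800)
frac < -950 HU  : 0.0177
frac > -200 HU  : 0.0032
```

The segmentation reproduces the phantom's ground truth exactly (Dice 1.0):
the protruding vessel is truncated at the lung surface, the decoy ball is
excluded by connectivity, and the in-lung vessel voxels (HU 200) survive —
they are the `frac > -200 HU` mass.  The modal bin sits in [−900, −800)
because the parenchyma is painted at −900 HU; the `frac < -950` mass is the
tracheal air at −1000 HU.

The same pipeline from the shell:

```sh
lungembed phantom --size 128 --rng-seed 1 --out-volume p.mha \
    --out-truth t.mha --out-json p.json
lungembed segment p.mha --seed 64,64,125 --out-volume seg.mha \
    --out-histogram h.csv --out-report r.json
lungembed dice --ref t.mha --test seg.mha --ref-background -5000
```

For a real scan, pass a DICOM directory or a NIfTI/MetaImage/NRRD file to
`lungembed segment` and give `--seed x,y,z` (0-based voxel indices) inside
the trachea.

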