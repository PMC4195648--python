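# adipoquant

Automatic segmentation and quantification of **subcutaneous (SAT)** and
**visceral (VAT)** adipose tissue in transverse abdominal MR images of
rodents. The package is aimed at preclinical obesity and weight-loss
studies, where repeated MRI of the same animals (e.g. across the L1–L5
lumbar range) is used to track how exercise or calorie restriction moves
fat between depots — measurements that would otherwise require dissection.

On fast-spin-echo images both fat depots appear hyper-intense, the
abdominal muscle wall separating them is iso-intense, and the organs are
hypo- to iso-intense. The pipeline exploits exactly this contrast:

1. **Preprocessing** (per slice): robust percentile min–max normalization to
   [0, 1], background suppression, Perona–Malik anisotropic diffusion
   (`∂I/∂t = div(g(|∇I|)∇I)` with `g(s) = exp(−(s/κ)²)`), and unsharp-mask
   edge enhancement.
2. **Body mask**: Otsu thresholding of the nonzero pixels, largest connected
   component, hole filling.
3. **Initial contour**: the boundary chain of the body mask is shrunk about
   its centroid by a factor in [0.75, 0.85] (derived per slice from the
   size of the binary mask) and placed at the slice centre, then embedded
   as a signed distance field `φ` (negative inside).
4. **Hybrid geodesic/local-region evolution**: the curve `{φ = 0}` expands
   with outward normal speed

   ```
   F(x) = g(x)·[β + R(x)] − ω·g(x)·κ(x)
   R(x) = ((I(x) − v_x)² − (I(x) − u_x)²) / ((u_x − v_x)² + ε)
   ```

   where `g = 1/(1 + |∇(G_σ∗I)|²)` is the geodesic edge-stopping factor,
   `u_x`/`v_x` are the mean intensities of the local interior/exterior
   neighbourhoods of radius *r* straddling the curve, `β` is the balloon
   pressure, and `κ = div(∇φ/|∇φ|)` the curvature. The curve comes to rest
   at the muscle wall; evolution stops when the enclosed area changes by
   fewer than 10 pixels between checks.
5. **Fuzzy C-means clustering**: the subcutaneous side (outside the curve,
   3 classes) and visceral side (inside, 5 classes) are clustered on
   intensity; classes within 0.15 of the brightest class's mean *and*
   touching its region are merged into the fat mask. Skin and wall bands
   are stripped from the SAT mask.
6. **Quantification**: volume = voxel count × pixel area × slice thickness;
   mass = volume × 0.9 g/ml (adipose tissue density). Pre/post scans are
   compared as 100·(post − pre)/pre per depot.

Because no animal data ship with the package, a synthetic phantom
generator reproduces the assumed imaging geometry (bright skin line and
SAT ring, iso-intense wall, organ interior with VAT lining the wall,
multiplicative bias field, Rician noise) with voxel-exact ground-truth
labels, so the entire pipeline is testable end to end.

## Worked example

Generate a default phantom (224×224, 3 slices, 0.2×0.2×1.6 mm voxels) and
segment it:

```sh
$ adipoquant phantom --spec spec.json --out demo/phantom   # spec.json: {"seed": 0}
phantom written to demo/phantom
$ adipoquant segment demo/phantom/phantom.npy --out demo/seg
SAT 0.570 ml (0.513 g), VAT 0.414 ml (0.372 g)
```

The run writes `labels.nii.gz` (0 background, 1 SAT, 2 VAT, 3 skin/wall,
4 organ), `quantification.csv` (one row per slice plus a summary row) and
`run_manifest.json` (every parameter actually used). The summary row of the
CSV reads:

```
slice,sat_voxels,vat_voxels,...,sat_volume_ml,vat_volume_ml,sat_mass_g,vat_mass_g
total,8901,6464,...,0.5696...,0.4136...,0.5126...,0.3723...
```

i.e. 8 901 SAT voxels × 0.2·0.2·1.6 mm³ = 0.570 ml, times 0.9 g/ml =
0.513 g of subcutaneous fat. Against this phantom's ground-truth labels the
segmentation scores a Dice overlap of ≥ 0.98 for SAT and ≥ 0.99 for VAT
(`adipoquant.dice`). Paired series with programmed depot changes are
generated with `--sat-change/--vat-change` and compared with
`adipoquant compare pre_labels.nii.gz post_labels.nii.gz`.

In Python the same pipeline is three calls:

```python
from adipoquant import PhantomSpec, make_phantom, segment_volume, quantify, dice

volume, truth = make_phantom(PhantomSpec(seed=0))
result = segment_volume(volume)
print(quantify(result.labels).sat_mass_g)   # 0.5126...
print(dice(result.labels, truth))           # {'sat': 0.98..., 'vat': 0.99...}
```

Library volumes are `(rows, cols, slices)` arrays, row-major and 0-based,
with the slice axis last; DICOM series directories, `.npy` + JSON-sidecar
arrays and NIfTI files are all accepted as input.

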