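# orbct

CBCT densitometry of spherical orbital implants.

After enucleation (surgical removal of the eye), the lost volume is
replaced by a porous ceramic sphere — hydroxyapatite (HA) or aluminium
oxide (AO), 16–20 mm nominal diameter — buried in the orbital soft
tissues. Cone-beam CT (CBCT) is attractive for long-term follow-up of
these implants because of its low radiation dose and high isometric
resolution (0.25 mm voxels), but CBCT intensity values are only
*HU-like*: unlike medical multi-slice CT (MSCT), the scanner is not
water-calibrated, so the affine relationship between attenuation and
reported value drifts per acquisition.

`orbct` implements the full analysis pipeline for this setting, for
researchers evaluating implanted porous scaffolds with CBCT:

- **Hounsfield definition** — HU = 1000·(μ_X − μ_water)/(μ_water − μ_air),
  with water ≡ 0 HU and air ≡ −1000 HU.
- **Per-scan two-point calibration** — each scan contains two reference
  objects of known MSCT-scale density: the contralateral corpus vitreum
  (CV, water-like; MSCT control value 5.93 ± 3.97 HU) and the maximum of
  the dedicated orbital volume (DV, dense bone; 2024.67 ± 103.49 HU).
  The unique affine map sending the scan's anchors onto those reference
  values corrects any value x measured on that scan:

      HU_corr = (x − CV_scan) / (DV_scan − CV_scan) · (DV_ref − CV_ref) + CV_ref

  exposed as scalar, per-record, and voxelwise (NIfTI) transforms.
- **Region statistics & geometry** — mean/SD/max/volume over masked
  regions, world-mm cropping of the dedicated volume, sphere fitting
  (exact 3-point circumsphere and least-squares Kåsa fit) for implant
  diameter estimation, and classification of implant voxels inside vs
  beyond the manufacturer's nominal sphere (marginal "spikes").
- **Longitudinal trends** — OLS of implant density against implant
  lifespan (days since implantation), raw or corrected, pooled or per
  group, with closed-form slope standard errors.
- **Synthetic ground truth** — digital phantoms (porous implant sphere,
  water globe, bone slab, affine miscalibration, Gaussian noise) and
  synthetic cohorts whose raw values are back-computed through their own
  anchors, so every stage is testable end to end.
- **The published 30-scan cohort** ships as a packaged, checksummed
  fixture (`orbct.load_study_table()`).

## Worked example

Record 1.3 of the packaged cohort has an uncalibrated implant mean of
496 HU, a corpus-vitreum mean of −344 HU and a dedicated-volume maximum
of 3071 HU. Calibrating that scan against the MSCT reference and
correcting the implant mean:

```bash
$ orbct calibrate --cv -344 --dvmax 3071 --value 496
{
  "gain": 0.5911390922401172,
  "offset_hu": 209.2818477306003,
  "corrected": {
    "496.0": 502.48683748169844
  }
}
```

The gain < 1 says this scan's HU axis was stretched relative to the MSCT
scale; the corrected implant mean (502.5 HU) lands within ~1.3% of the
value published for that record (496 HU). The same map applied in Python:

```python
from orbct import build_calibration, correct_hu, load_study_table

rec = {r.id_label: r for r in load_study_table()}["1.3"]
cal = build_calibration(rec.cv_mean_hu, rec.dv_max_hu)
print(correct_hu(rec.oi_mean_hu, cal))   # 502.48683748169844
```

The pooled corrected density-vs-lifespan trend over all 30 records:

```bash
$ orbct trend --use-corrected
...
  "pooled": {
    "slope_hu_per_year": 42.166050464941975,
    "r_squared": 0.15311639318564318,
    "n": 30,
    ...
  }
```

i.e. a weak *positive* pooled slope of +42 HU/yr (R² = 0.15). Note this
sign is opposite to the qualitative per-material decline reported for
the source cohort; the per-material grouping needed to reproduce those
fits is not recoverable from the published table (see
`docs/methods.md`). Per-group analyses take a `--group-map` CSV.

The full report bundle (per-record corrected-vs-published comparison,
cohort summary, raw and corrected trends, provenance block) comes from:

```bash
orbct reanalyze --out report/
```

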