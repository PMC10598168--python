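# jsmap — 3-D joint space mapping

Joint space width (JSW), the distance between the opposing subchondral bone
surfaces of a joint, is the standard imaging surrogate for cartilage loss in
osteoarthritis. Measuring it at single landmarks throws away where a joint is
narrowing; measuring it from segmented surface meshes caps the accuracy at
the segmentation, which CT blur corrupts precisely at the edges being
measured. `jsmap` implements *joint space mapping*: JSW is measured at every
vertex of an articular surface mesh directly from the CT intensities, by
fitting a blurred two-edge model along each surface normal, giving sub-voxel
3-D JSW maps together with the statistics needed to trust them —
inter-operator reproducibility and test–retest repeatability as vertex-wise
Bland–Altman maps, and the relationship between joint angulation and JSW as
permutation-corrected statistical parametric maps (SPM).

It is aimed at musculoskeletal imaging researchers working with
(weight-bearing) CT of small joints such as the ankle, and at anyone needing
a tested, synthetic-ground-truth harness for surface-based measurement
statistics.

## The measurement

For a reference vertex with outward normal, the intensity profile `y(t)`
sampled along the normal across the joint space is modelled as

    y(t) = b + (A1 − b)·Φ((e1 − t)/s) + (A2 − b)·Φ((t − e2)/s)

where Φ is the standard normal CDF, `A1`, `A2` are the two bone plateau
intensities, `b` the joint-space background, `e1`, `e2` the blurred edge
positions and `s` the point-spread blur. The vertex's JSW is `e2 − e1`.
Because the model uses the whole profile, the edges — and hence JSW — are
localised well below the voxel size (per-vertex RMSE ≈ 0.03 mm at 0.37 mm
voxels on known-truth phantoms). The articulating region itself is found by
casting each vertex's normal ray against the opposing bone ("shadow"
casting); per-subject maps are rigidly registered to a template
(point-to-surface ICP) and transferred by closest-point barycentric
interpolation for group analysis.

Since clinical repeat-imaging data cannot be shipped, the package includes a
first-class phantom generator: articulating surface pairs with an exact
per-vertex gap field, rasterized into CT-like volumes (partial-volume
occupancy, Gaussian PSF, intensity noise), plus cohort simulation with
visit, operator-perimeter and angulation effects — every measurement and
statistic in the package is validated against this ground truth.

## Worked example

```python
import numpy as np
from jsmap import (GapField, PhantomSpec, make_joint_phantom, rasterize_ct,
                   map_jsw, patch_mean, ScalarField, cohort_summary,
                   load_ankle_cohort)

# phantom with a known gap ramp 1.9 -> 2.9 mm across a 20 mm patch
spec = PhantomSpec(geometry="parallel-slabs", extent=20.0, mesh_resolution=1.0,
                   gap_field=GapField(kind="ramp", lo=1.9, hi=2.9))
phantom = make_joint_phantom(spec)
volume = rasterize_ct(phantom, spacing=0.37, psf_sigma=0.5, noise_sd=20.0, seed=0)

patch = phantom.patch("ramp")
jsw = map_jsw(volume, patch, phantom.opposing)

truth = phantom.truth.values[patch.parent_index]
valid = jsw.field.mask
rmse = np.sqrt(np.mean((jsw.field.values[valid] - truth[valid]) ** 2))
print(f"measured {valid.sum()}/{patch.n_vertices} vertices")
print(f"patch-mean JSW  {patch_mean(jsw.field, patch):.3f} mm "
      f"(truth {patch_mean(ScalarField(truth), patch):.3f} mm)")
print(f"per-vertex RMSE {rmse:.3f} mm at 0.37 mm voxels")

summary = cohort_summary(load_ankle_cohort())
print(f"cohort: n={summary['n']}, age {summary['age_years']['mean']:.1f} y "
      f"({summary['age_years']['min']:.0f}-{summary['age_years']['max']:.0f}), "
      f"interval {summary['interval_days']['mean']:.1f} d")
```

prints

```
measured 441/441 vertices
patch-mean JSW  2.421 mm (truth 2.400 mm)
per-vertex RMSE 0.027 mm at 0.37 mm voxels
cohort: n=23, age 52.7 y (23-74), interval 74.0 d
```

The map recovers the ramp's mean gap to 0.02 mm and each vertex to better
than a tenth of the voxel size; the last line summarises the shipped
23-participant repeat-imaging demographic table (`load_ankle_cohort`).

## Command line

`jsmap demo --out runs/demo` executes the full synthetic study — four
articular facets, 23 subjects, two visits, two operators — through simulate,
measure, register, stats and report, writing per-facet VTK maps (mean JSW,
SD, reproducibility and repeatability LOA, F and corrected p), a Table-style
`report.csv`, and a manifest with checksums for every artefact. The
individual stage verbs (`simulate`, `measure`, `register`, `stats`,
`report`) run the same pipeline from a TOML config, and
`jsmap measure --volume vol.nii --reference ref.ply --opposing opp.ply
--patch mask.csv --out map.vtk` measures a user-supplied volume/mesh pair
directly.

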