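# condylar

Quantification of mandibular condylar remodelling after orthognathic
surgery from paired 3D imaging.

After bimaxillary osteotomies the temporomandibular joint adapts to the
new loading regime: the condyle can lose ramus height, rotate, change
volume, lose bone density and remodel its articular surface.  Most of
this is benign adaptation, but a ramus-height loss greater than 6 % of
the pre-surgical value signals pathological condylar resorption.  This
package implements the digital measurement workflow that tracks six
parameters per condyle between a pre-operative CT/CBCT (T0) and a
follow-up scan (T1):

| parameter | definition |
|---|---|
| ramus height | ‖apex − gonion‖ (mm) |
| intercondylar angle | angle at the foramen-magnum vertex between the two condylar centres |
| condylar axis inclination | coronal-plane angle between the transverse condylar diameter and the ramus axis |
| condylar volume | segmented bone from the apex to 15 mm down the condylar axis (mm³) |
| mean bone density | mean HU over the same region |
| surface change | per-region mean signed distance (mm) between registered T0/T1 surfaces, positive = apposition |

It is written for imaging researchers and maxillofacial units who want
the measurements to be reproducible operators on explicit inputs
(volume, segmentation mask, surface mesh, landmark set) instead of
clicks in planning software.  A fully ground-truthed synthetic condyle
phantom stands in for patient data, and a cohort-statistics stage
(divisor-explicit summaries and SPSS-convention Wilcoxon signed-rank
tests, `z = (W − n(n+1)/4)/√(n(n+1)(2n+1)/24 − Σ(t³−t)/48)`, plus an
exact enumeration variant) reproduces the published statistics of a
12-patient reference cohort whose per-patient tables ship with the
package.

## Worked example

Generate a phantom condyle, prescribe a remodelling (a +6.9° coronal
rotation of the head, 0.2 mm anterior apposition, 0.2 mm posterior
resorption, a 30 % density drop), and measure it end-to-end:

```python
from condylar import (PhantomSpec, RemodelSpec, generate_phantom,
                      apply_remodeling, compare_pair)

spec = PhantomSpec(voxel_spacing_mm=0.5, seed=3)
pre, truth = generate_phantom(spec)
remodel = RemodelSpec(
    axis_rotation_deg=6.9,
    surface_offsets_mm={"anterior": 0.2, "posterior": -0.2},
    density_scale=0.7,
    hu_noise_sd=5.0,
)
post, truth = apply_remodeling(pre, truth, remodel, spec)
m = compare_pair(pre, post)
print(f"axis inclination change: {m.axis_delta_deg:+.2f} deg")
print(f"mean density: {m.pre.roi_mean_hu:.1f} -> {m.post.roi_mean_hu:.1f} HU "
      f"({m.density_delta_pct:+.1f} %)")
for region, mean in m.surface_means_mm.items():
    print(f"  {region:9s} {mean:+.2f} mm")
print(f"resorption (height loss > 6 %): {m.resorption}")
```

prints

```
axis inclination change: +6.90 deg
mean density: 905.3 -> 634.2 HU (-29.9 %)
  anterior  +0.18 mm
  posterior -0.19 mm
  medial    -0.00 mm
  lateral   -0.00 mm
  superior  +0.00 mm
resorption (height loss > 6 %): False
```

The prescribed rotation is recovered exactly (landmarks are analytic),
the density drop to within 0.1 percentage point, and the surface offsets
to within a few hundredths of a millimetre (the 10° blend band at region
borders dilutes sector means slightly; see `docs/methods.md`).

The analysis drivers run the same machinery at study scale:

* `analysis/01_simulate_phantoms.py` — seeded 12-patient phantom cohort,
  truth table to `results/phantom_truth.csv`;
* `analysis/02_measure_phantoms.py` — full pipeline on every pair,
  measurements to `results/phantom_measurements.csv` plus a recovery
  report;
* `analysis/03_cohort_tables.py` — cohort statistics of the bundled
  reference tables to `results/summary.csv` / `results/tests.csv`
  (bone density p = 0.002 per side, right condylar axis p = 0.023,
  intercondylar change −10.81 ± 8.22°, density decrease 33.75 ± 4.45 %,
  18/24 condyles losing height, …).

A thin CLI mirrors the stages: `condylar simulate|measure|volumetrics|compare|cohort`
(see `condylar --help`).

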