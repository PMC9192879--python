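"""Run the full measurement pipeline on the simulated cohort.

Regenerates the seeded phantom cohort of 01_simulate_phantoms.py,
measures every pre/post pair end-to-end (landmark morphometry, 15 mm ROI
volumetry/densitometry, ICP registration + per-region signed surface
distances), writes the tidy per-condyle deltas to
``results/phantom_measurements.csv`` and reports how well the pipeline
recovers the prescribed ground truth.
"""

from pathlib import Path

import numpy as np

from condylar import pipeline
from condylar.synthetic_phantom import generate_cohort

SEED = 7
N_PATIENTS = 12
SPACING_MM = 0.5

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

patients, truth = generate_cohort(
    n_patients=N_PATIENTS, seed=SEED, sides=("right",), voxel_spacing_mm=SPACING_MM
)
deltas = pipeline.measure_cohort(patients, surfaces=True)
deltas.to_csv(out_dir / "phantom_measurements.csv", index=False, float_format="%.4f")

wide = deltas.pivot_table(index="patient", columns="variable", values="delta")
merged = truth.merge(wide, on="patient")
print(f"measured {N_PATIENTS} pre/post pairs -> {out_dir / 'phantom_measurements.csv'}\n")
print("parameter recovery (measured vs prescribed, mean absolute error):")
pairs = [
    ("height", "height_delta_mm", "height_mm", "mm"),
    ("axis inclination", "axis_delta_deg", "axis_deg", "deg"),
    ("intercondylar", "intercondylar_delta_deg", "intercondylar_deg", "deg"),
    ("density", "density_delta_pct", "density_pct", "%"),
]
for label, tcol, mcol, unit in pairs:
    err = np.abs(merged[mcol] - merged[tcol])
    print(f"  {label:16s} {err.mean():7.4f} {unit} (max {err.max():.4f})")

print(
    "\nper-region surface change vs prescribed radial offset (mean abs difference):\n"
    "  note: the measured signed distances correctly superimpose the rigid head\n"
    "  displacement caused by the height change onto the radial offsets, so the\n"
    "  difference below is dominated by |height delta| (largest superiorly);\n"
    "  isolated offset recovery (height delta = 0) is exercised by the test suite."
)
for region in ("anterior", "posterior", "medial", "lateral", "superior"):
    err = np.abs(merged[f"surface_{region}_mm"] - merged[f"offset_{region}_mm"])
    print(f"  surface {region:9s} {err.mean():7.4f} mm (max {err.max():.4f})")
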