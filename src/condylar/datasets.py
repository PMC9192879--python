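"""Bundled reference-cohort tables and tidy accessors.

The package ships the per-patient outcome tables of a published
12-patient bimaxillary-osteotomy cohort (24 condyles, CBCT at T0 and 12
months): per-side ramus-height change, intercondylar-angle change,
condylar-axis change, per-patient condylar-volume change, per-side
pre/post mean bone density (HU) with the printed percent change, and the
five per-side mean surface-distance values.  Values are transcribed *as
printed* — including a handful of internally inconsistent cells — so the
cohort-statistics stage can be validated against the published numbers;
:func:`flag_density_pct_inconsistencies` reports cells whose printed
percent change disagrees with their own pre/post values.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_demographics",
    "load_outcomes",
    "outcome_deltas",
    "density_abs_pct",
    "flag_density_pct_inconsistencies",
]

_SURFACES = ("anterior", "posterior", "medial", "lateral", "superior")


def _read(name: str) -> pd.DataFrame:
    with resources.files("condylar.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_demographics() -> pd.DataFrame:
    """Per-patient age, sex, malocclusion class and surgical movements."""
    return _read("cohort_demographics.csv")


def load_outcomes() -> pd.DataFrame:
    """Per-patient printed outcome values, wide (one row per patient)."""
    return _read("cohort_outcomes.csv")


def outcome_deltas(outcomes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy per-condyle deltas: columns patient, side, variable, delta.

    Density enters twice: as the HU difference (``density_hu``, the
    quantity the signed-rank test is run on) and as the printed percent
    change (``density_pct``).  The intercondylar angle and volume are
    single per-patient values (side ``both`` / ``n/a``).
    """
    df = load_outcomes() if outcomes is None else outcomes
    rows = []
    for _, r in df.iterrows():
        p = int(r["patient"])
        for side in ("right", "left"):
            rows.append((p, side, "height_mm", r[f"height_{side}_mm"]))
            rows.append((p, side, "axis_deg", r[f"axis_{side}_deg"]))
            rows.append(
                (p, side, "density_hu", r[f"density_{side}_post_hu"] - r[f"density_{side}_pre_hu"])
            )
            rows.append((p, side, "density_pct", r[f"density_{side}_pct"]))
            for s in _SURFACES:
                rows.append((p, side, f"surface_{s}_mm", r[f"surface_{s}_{side}_mm"]))
        rows.append((p, "both", "intercondylar_deg", r["intercondylar_deg"]))
        rows.append((p, "n/a", "volume_mm3", r["volume_mm3"]))
        rows.append((p, "n/a", "volume_pct", r["volume_pct"]))
    return pd.DataFrame(rows, columns=["patient", "side", "variable", "delta"])


def density_abs_pct(with_metadata: bool = False) -> pd.DataFrame:
    """|printed density Δ%| per condyle, optionally joined with demographics."""
    df = load_outcomes()
    rows = []
    for _, r in df.iterrows():
        for side in ("right", "left"):
            rows.append((int(r["patient"]), side, abs(float(r[f"density_{side}_pct"]))))
    out = pd.DataFrame(rows, columns=["patient", "side", "value"])
    if with_metadata:
        meta = load_demographics()[["patient", "sex", "angle_class"]]
        out = out.merge(meta, on="patient", validate="many_to_one")
    return out


def flag_density_pct_inconsistencies(tol: float = 0.1) -> pd.DataFrame:
    """Cells whose printed density Δ% disagrees with their own pre/post HU.

    ``tol`` is one printed ULP, so cells that differ only by
    rounding/truncation of the 1-decimal print are not flagged.  The
    printed values are kept either way; this only documents the
    discrepancies (patient 1 left prints −36.1 where the cells imply
    −38.1; patient 7 left prints −38.9 where they imply −40.0).
    """
    df = load_outcomes()
    rows = []
    for _, r in df.iterrows():
        for side in ("right", "left"):
            pre, post = float(r[f"density_{side}_pre_hu"]), float(r[f"density_{side}_post_hu"])
            implied = 100.0 * (post - pre) / pre
            printed = float(r[f"density_{side}_pct"])
            if abs(implied - printed) > tol:
                rows.append((int(r["patient"]), side, printed, float(np.round(implied, 1))))
    return pd.DataFrame(rows, columns=["patient", "side", "printed_pct", "implied_pct"])
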