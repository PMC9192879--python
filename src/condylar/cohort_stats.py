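"""Cohort-level paired statistics for condylar remodelling studies.

Aggregates per-condyle measurements into the study-level analysis: means
and SDs with an explicit divisor, event counts, subgroup means, and the
Wilcoxon signed-rank test per variable and side.

The Wilcoxon implementation follows the SPSS defaults the cohort tables
were produced with: zero differences dropped, average ranks for tied
|differences|, tie-corrected variance, no continuity correction,
two-sided p from the normal approximation

    z = (W − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 − Σ(t³−t)/48)

with W the sum of positive ranks.  An exact variant enumerates the null
distribution of W over the observed rank multiset with the shift
algorithm (feasible for n ≤ 25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TestResult",
    "SummaryRow",
    "wilcoxon_signed_rank",
    "summarize",
    "count_events",
    "subgroup_means",
    "build_cohort_report",
]


@dataclass(frozen=True)
class PairedSample:
    """Signed within-pair differences for one variable (and side)."""

    differences: np.ndarray
    variable: str = ""
    side: str = "n/a"  # left | right | both | n/a

    def __post_init__(self):
        d = np.asarray(self.differences, float).reshape(-1)
        if len(d) < 1 or not np.isfinite(d).all():
            raise ValueError("differences must be a nonempty finite vector")
        object.__setattr__(self, "differences", d)


@dataclass(frozen=True)
class TestResult:
    n: int  # pairs used after dropping zeros
    w: float  # sum of positive ranks
    z: float | None  # asymptotic z, None for exact method
    p: float  # two-sided
    method: str  # "normal" | "exact"

    def __post_init__(self):
        if not (0 <= self.w <= self.n * (self.n + 1) / 2 + 1e-9):
            raise ValueError("W outside [0, n(n+1)/2]")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


@dataclass(frozen=True)
class SummaryRow:
    variable: str
    side: str
    n: int
    mean: float
    sd: float  # NaN when undefined
    sd_divisor: str  # "n" | "n-1"
    n_negative: int
    n_positive: int


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(d, float)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("no nonzero pairs")
    return d, sps.rankdata(np.abs(d))


def _exact_pvalue(w: float, ranks: np.ndarray) -> float:
    """Two-sided exact p by shift-algorithm enumeration over the rank multiset.

    Average ranks can be half-integers, so everything is doubled to work
    on an integer lattice.  p = 2·min(P(W ≤ w), P(W ≥ w)), capped at 1 —
    the usual doubling convention for a possibly asymmetric (tied) null.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r].copy()
    counts /= counts.sum()  # 2^n subsets
    w2 = int(np.rint(2.0 * w))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    sample: PairedSample | np.ndarray,
    method: str = "normal",
    tie_correction: bool = True,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences."""
    d = sample.differences if isinstance(sample, PairedSample) else np.asarray(sample, float)
    d, ranks = _signed_ranks(d)
    n = len(d)
    w = float(ranks[d > 0].sum())
    if method == "exact":
        if n > 25:
            raise ValueError("exact method supported for n <= 25")
        return TestResult(n=n, w=w, z=None, p=_exact_pvalue(w, ranks), method="exact")
    if method != "normal":
        raise ValueError("method must be 'normal' or 'exact'")
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if tie_correction:
        _, t = np.unique(np.abs(d), return_counts=True)
        var -= float((t**3 - t).sum()) / 48.0
    if var <= 0:
        raise ValueError("degenerate variance: all differences tied at one value")
    z = (w - mu) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(n=n, w=w, z=float(z), p=p, method="normal")


def summarize(
    values: np.ndarray,
    sd_divisor: str = "n-1",
    variable: str = "",
    side: str = "n/a",
) -> SummaryRow:
    """Mean, SD (explicit divisor) and sign counts of a value vector.

    The divisor is explicit because published tables mix conventions:
    population (``n``) and sample (``n-1``) SDs both occur.
    """
    v = np.asarray(values, float).reshape(-1)
    if len(v) < 1 or not np.isfinite(v).all():
        raise ValueError("values must be a nonempty finite vector")
    if sd_divisor not in ("n", "n-1"):
        raise ValueError("sd_divisor must be 'n' or 'n-1'")
    ddof = 0 if sd_divisor == "n" else 1
    sd = float(v.std(ddof=ddof)) if len(v) > ddof else float("nan")
    return SummaryRow(
        variable=variable,
        side=side,
        n=len(v),
        mean=float(v.mean()),
        sd=sd,
        sd_divisor=sd_divisor,
        n_negative=int((v < 0).sum()),
        n_positive=int((v > 0).sum()),
    )


def count_events(values: np.ndarray, predicate) -> tuple[int, float]:
    """Count of values satisfying ``predicate`` and the percentage of n.

    ``predicate`` is a vectorisable callable, e.g. ``lambda v: v < 0``.
    Returns ``(0, 0.0)`` for empty input.
    """
    v = np.asarray(values, float).reshape(-1)
    if len(v) == 0:
        return 0, 0.0
    count = int(np.asarray(predicate(v)).sum())
    return count, 100.0 * count / len(v)


def subgroup_means(values: pd.DataFrame, by: str, value_col: str = "value") -> dict[str, float]:
    """Mean of ``value_col`` per group label in column ``by``."""
    if by not in values.columns:
        raise KeyError(f"unknown grouping column {by!r}")
    if values[by].isna().any():
        raise ValueError(f"unknown (missing) group label in {by!r}")
    return {str(k): float(g[value_col].mean()) for k, g in values.groupby(by, sort=True)}


# ---------------------------------------------------------------------------
# cohort report


#: variable -> (side-resolved, sd divisor used in the summary table).
#: The intercondylar angle is a single bilateral measurement per patient
#: and its published SD matches the population (n) divisor; the other
#: summaries use the sample (n-1) divisor.
_REPORT_VARIABLES = {
    "height_mm": ("per-side", "n-1"),
    "intercondylar_deg": ("both", "n"),
    "axis_deg": ("per-side", "n-1"),
    "volume_mm3": ("n/a", "n-1"),
    "volume_pct": ("n/a", "n-1"),
    "density_hu": ("per-side", "n-1"),
    "density_pct": ("per-side", "n-1"),
    "surface_anterior_mm": ("per-side", "n-1"),
    "surface_posterior_mm": ("per-side", "n-1"),
    "surface_medial_mm": ("per-side", "n-1"),
    "surface_lateral_mm": ("per-side", "n-1"),
    "surface_superior_mm": ("per-side", "n-1"),
}


def build_cohort_report(
    deltas: pd.DataFrame,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary and Wilcoxon tables from tidy per-condyle deltas.

    ``deltas`` columns: ``patient``, ``side`` (left/right/both/n-a),
    ``variable`` (see keys above), ``delta``.  Rows with missing deltas
    are flagged and excluded from testing.  Output is deterministic:
    identical inputs give byte-identical CSVs.
    """
    required = {"patient", "side", "variable", "delta"}
    if not required.issubset(deltas.columns):
        raise ValueError(f"deltas must have columns {sorted(required)}")
    incomplete = deltas["delta"].isna()
    if incomplete.any():
        for _, row in deltas[incomplete].iterrows():
            print(
                f"cohort: patient {row['patient']} {row['variable']}/{row['side']} "
                "incomplete; excluded from tests"
            )
        deltas = deltas[~incomplete]
    summary_rows, test_rows = [], []
    for variable, (sided, divisor) in _REPORT_VARIABLES.items():
        sub = deltas[deltas["variable"] == variable]
        if sub.empty:
            continue
        sides = sorted(sub["side"].unique()) if sided == "per-side" else [sided]
        for side in sides:
            vals = sub["delta"] if sided != "per-side" else sub.loc[sub["side"] == side, "delta"]
            vals = vals.to_numpy(float)
            if len(vals) == 0:
                continue
            s = summarize(vals, sd_divisor=divisor, variable=variable, side=side)
            summary_rows.append(s.__dict__)
            try:
                t = wilcoxon_signed_rank(PairedSample(vals, variable, side))
                test_rows.append(
                    {
                        "variable": variable,
                        "side": side,
                        "n": t.n,
                        "W": t.w,
                        "z": t.z,
                        "p": t.p,
                        "p_report": float(np.round(t.p, 3)),
                        "method": t.method,
                        "note": "",
                    }
                )
            except ValueError as exc:
                test_rows.append(
                    {
                        "variable": variable,
                        "side": side,
                        "n": 0,
                        "W": np.nan,
                        "z": np.nan,
                        "p": np.nan,
                        "p_report": np.nan,
                        "method": "normal",
                        "note": f"not computable: {exc}",
                    }
                )
    summary = pd.DataFrame(summary_rows)
    tests = pd.DataFrame(test_rows)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False, float_format="%.6g", lineterminator="\n")
        tests.to_csv(out / "tests.csv", index=False, float_format="%.6g", lineterminator="\n")
    return summary, tests
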